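"""Read counting over TERRA regions and downstream summary statistics.

Three counting modes mirror the three quantification questions:

* ``arm_specific`` -- which chromosome end produced the read? Requires
  unique mappings (MAPQ >= 30 for paired-end, MAPQ == 255 for single-end)
  and counts only the subtelomeric sub-interval of each region, because
  reads inside the pure telomeric repeat cannot be assigned to an arm.
* ``total`` -- how much TERRA overall? Primary alignments with MAPQ >= 1,
  duplicates removed, both subtelomeric and telomeric sub-intervals
  counted.
* ``capture`` -- enrichment bookkeeping for capture vs control libraries:
  MAPQ >= 30 over whole regions.

Overlap semantics: a fragment (read pair counted once, interval = union
of mate spans) overlapping a feature by >= 1 bp counts; a fragment
overlapping several features counts once per feature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from terrakit.annotate import TYPE_I, TYPE_II, TerraRegion
from terrakit.repeatscan import AlignmentRecord

MODES = ("arm_specific", "total", "capture")


@dataclass
class CountMatrix:
    """Features x samples integer counts with per-feature metadata.

    ``features`` is a DataFrame indexed by feature id with columns
    region_id, region_type, subregion (subtelomeric / telomeric / gene /
    region) and tss_rank; ``counts`` is an integer DataFrame with the
    same index and one column per sample.
    """

    features: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.counts.index):
            raise ValueError("features and counts must share the same index")
        if self.features.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def merged(self, other: "CountMatrix") -> "CountMatrix":
        """Column-wise merge of two matrices over identical features."""
        if not self.features.index.equals(other.features.index):
            raise ValueError("cannot merge matrices with different features")
        return CountMatrix(self.features, pd.concat([self.counts, other.counts], axis=1))


def region_features(
    regions: Sequence[TerraRegion], feature_level: str = "subregion"
) -> pd.DataFrame:
    """Feature table for a counting mode.

    With ``feature_level='subregion'`` the subtelomeric and telomeric
    sub-intervals are separate features (``<region_id>:subtelomeric`` /
    ``:telomeric``); with ``'region'`` there is one feature per whole
    region (a fragment then counts once per region however it overlaps).
    Empty sub-intervals are skipped.
    """
    rows = []
    for r in regions:
        if feature_level == "region":
            rows.append((r.region_id, r.seq_id, r.start, r.end, r.strand,
                         r.region_id, r.type, "region", r.tss_rank))
        else:
            for name, (s, e) in (("subtelomeric", r.subtelomeric),
                                 ("telomeric", r.telomeric)):
                if e > s:
                    rows.append((f"{r.region_id}:{name}", r.seq_id, s, e,
                                 r.strand, r.region_id, r.type, name, r.tss_rank))
    df = pd.DataFrame(
        rows,
        columns=["feature_id", "seq_id", "start", "end", "strand",
                 "region_id", "region_type", "subregion", "tss_rank"],
    ).set_index("feature_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate feature ids derived from regions")
    return df


def _fragments(
    records: Sequence[AlignmentRecord], library_layout: str
) -> list[tuple[str, str, int, int, str, bool, int]]:
    """Collapse alignment records into fragments.

    Returns (read_id, seq_id, start, end, strand, duplicate, mapq) with
    a properly paired fragment counting once using the union of mate
    spans; fragment strand is the strand of the first-in-pair mate (or
    the single read). MAPQ of a fragment is the minimum over its mates.
    """
    frags = []
    if library_layout == "paired":
        by_read: dict[str, list[AlignmentRecord]] = {}
        for r in records:
            by_read.setdefault(r.read_id, []).append(r)
        for read_id, group in by_read.items():
            primaries = [r for r in group if r.primary]
            if not primaries:
                continue
            mates = [r for r in primaries if not r.paired or r.proper_pair]
            if not mates:
                mates = primaries
            same_seq = {r.seq_id for r in mates}
            if len(same_seq) != 1:
                mates = [mates[0]]
            start = min(r.start for r in mates)
            end = max(r.end for r in mates)
            first = next((r for r in mates if r.first_in_pair), mates[0])
            frags.append(
                (read_id, mates[0].seq_id, start, end, first.strand,
                 any(r.duplicate for r in mates), min(r.mapq for r in mates))
            )
    else:
        for r in records:
            if not r.primary:
                continue
            frags.append(
                (r.read_id, r.seq_id, r.start, r.end, r.strand, r.duplicate, r.mapq)
            )
    frags.sort(key=lambda f: (f[1], f[2], f[3], f[0]))
    return frags


def _dedup(frags: list[tuple]) -> list[tuple]:
    """Duplicate removal: flag-based when duplicate flags are present,
    else positional (identical seq/start/end/strand collapse to one)."""
    if any(f[5] for f in frags):
        return [f for f in frags if not f[5]]
    seen: set[tuple] = set()
    out = []
    for f in frags:
        key = (f[1], f[2], f[3], f[4])
        if key in seen:
            continue
        seen.add(key)
        out.append(f)
    return out


def count_reads(
    alignments: Sequence[AlignmentRecord],
    regions: Sequence[TerraRegion],
    mode: str = "total",
    library_layout: str = "paired",
    strandedness: str = "none",
    sample: str = "sample",
    feature_level: str | None = None,
) -> CountMatrix:
    """Count fragments over region features under mode-specific filters.

    See the module docstring for mode semantics. ``strandedness``:
    'none' counts regardless of orientation; 'forward' requires the
    fragment strand to match the region strand; 'reverse' the opposite.
    ``feature_level`` defaults to whole regions in capture mode and the
    subtelomeric/telomeric sub-intervals otherwise. Counting is
    invariant to input record order.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if strandedness not in ("none", "forward", "reverse"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    if library_layout not in ("paired", "single"):
        raise ValueError(f"unknown library_layout {library_layout!r}")
    if feature_level is None:
        feature_level = "region" if mode == "capture" else "subregion"
    if feature_level not in ("region", "subregion"):
        raise ValueError(f"unknown feature_level {feature_level!r}")
    features = region_features(regions, feature_level)
    frags = _fragments(alignments, library_layout)

    if mode == "arm_specific":
        if library_layout == "paired":
            frags = [f for f in frags if f[6] >= 30]
        else:
            frags = [f for f in frags if f[6] == 255]
        countable = features[features["subregion"] == "subtelomeric"]
    elif mode == "total":
        frags = _dedup([f for f in frags if f[6] >= 1])
        countable = features
    else:  # capture
        frags = [f for f in frags if f[6] >= 30]
        countable = features

    counts = pd.Series(0, index=features.index, dtype=int)
    feat_rows = list(countable.itertuples())
    for _rid, f_seq, f_start, f_end, f_strand, dup, _mapq in frags:
        for feat in feat_rows:
            if feat.seq_id != f_seq:
                continue
            if f_start < feat.end and feat.start < f_end:
                if strandedness == "forward" and f_strand != feat.strand:
                    continue
                if strandedness == "reverse" and f_strand == feat.strand:
                    continue
                counts[feat.Index] += 1
    return CountMatrix(features, counts.to_frame(sample))


def total_terra(counts: CountMatrix, regions: Sequence[TerraRegion] | None = None) -> pd.Series:
    """Per-sample total TERRA: the sum over features of Type I and Type II
    regions with proximal TSSs (both subtelomeric and telomeric
    sub-features); Type III and distal-TSS regions are excluded.
    """
    meta = counts.features
    keep = meta["region_type"].isin([TYPE_I, TYPE_II]) & (meta["tss_rank"] == "proximal")
    return counts.counts.loc[keep].sum(axis=0)


def cpm(counts: CountMatrix, library_sizes: pd.Series | dict) -> pd.DataFrame:
    """Counts per million mapped fragments.

    ``library_sizes`` gives the total mapped fragments per sample (the
    full library, not the TERRA subtotal).
    """
    sizes = pd.Series(library_sizes, dtype=float)
    missing = set(counts.samples) - set(sizes.index)
    if missing:
        raise ValueError(f"missing library sizes for samples: {sorted(missing)}")
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.counts * 1e6 / sizes[counts.samples]


@dataclass(frozen=True)
class PolyAResult:
    """Poly(A)+/- partitioning of one region's TERRA reads.

    ``frac_plus``/``frac_minus`` are the region's share of total TERRA
    reads within each fraction; ``log2_ratio`` is log2(frac_plus /
    frac_minus), NaN (defined=False) when either share is zero.
    """

    region_id: str
    frac_plus: float
    frac_minus: float
    log2_ratio: float
    defined: bool


def polya_enrichment(
    counts_plus: CountMatrix,
    counts_minus: CountMatrix,
    sample_plus: str | None = None,
    sample_minus: str | None = None,
) -> list[PolyAResult]:
    """Per-region poly(A)+ vs poly(A)- partitioning.

    Reads mapped to all TERRA regions (Types I, II and III) within a
    fraction are its total TERRA reads; each region's proportion is its
    count over that total, and the enrichment is the log2 ratio of the
    plus proportion over the minus proportion.
    """
    sp = sample_plus or counts_plus.samples[0]
    sm = sample_minus or counts_minus.samples[0]
    plus = counts_plus.counts[sp].groupby(counts_plus.features["region_id"]).sum()
    minus = counts_minus.counts[sm].groupby(counts_minus.features["region_id"]).sum()
    regions = sorted(set(plus.index) | set(minus.index))
    plus = plus.reindex(regions, fill_value=0)
    minus = minus.reindex(regions, fill_value=0)
    if plus.sum() == 0 or minus.sum() == 0:
        raise ValueError("a fraction has zero total TERRA reads")
    frac_plus = plus / plus.sum()
    frac_minus = minus / minus.sum()
    results = []
    for rid in regions:
        fp, fm = float(frac_plus[rid]), float(frac_minus[rid])
        if fp > 0 and fm > 0:
            results.append(PolyAResult(rid, fp, fm, math.log2(fp / fm), True))
        else:
            results.append(PolyAResult(rid, fp, fm, float("nan"), False))
    return results


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
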