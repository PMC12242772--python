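"""Calling and classification of TERRA transcription regions.

A TERRA transcription region is the genomic unit producing a TERRA
transcript: a transcription start site (TSS) in the subtelomere, a
subtelomeric interval, and the telomeric repeat tract the transcript runs
into. Three types are distinguished:

* Type I   -- chromosome-end region whose promoter contains at least one
              of the 61/29/37 bp repeat elements;
* Type II  -- chromosome-end region lacking all three elements;
* Type III -- region transcribed from an interstitial telomeric sequence.

Regions are called per telomeric tract from up to three evidence classes:
a capture/control log2 enrichment coverage track, long-read 5' end
positions, and CAGE tag clusters. The historical assignment of these
regions was manual curation over the same three evidence classes; here the
procedure is algorithmic: an enriched run of bins must reach the tract,
and the TSS is placed by CAGE first, long-read 5' ends second, and the
enrichment run boundary last.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from terrakit.promoter_elements import PromoterSignature
from terrakit.repeatscan import (
    INTERSTITIAL,
    TERMINAL_P,
    TERMINAL_Q,
    RepeatTract,
)

TYPE_I = "I"
TYPE_II = "II"
TYPE_III = "III"


@dataclass
class CoverageTrack:
    """Binned coverage (or log2-ratio) values along one sequence."""

    seq_id: str
    seq_len: int
    values: np.ndarray
    bin_size: int = 30
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = math.ceil(self.seq_len / self.bin_size)
        if len(self.values) != expected:
            raise ValueError(
                f"{self.seq_id}: expected {expected} bins for length "
                f"{self.seq_len} at bin size {self.bin_size}, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.seq_id}: coverage values must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_of(self, pos: int) -> int:
        return min(pos // self.bin_size, self.n_bins - 1)


@dataclass(frozen=True)
class TagCluster:
    """A cluster of CAGE 5' tags marking a candidate TSS."""

    seq_id: str
    position: int
    strand: str
    tag_count: int

    def __post_init__(self) -> None:
        if self.tag_count < 1:
            raise ValueError("tag_count must be >= 1")


@dataclass
class TerraRegion:
    """An annotated TERRA transcription unit.

    ``strand`` is the direction of transcription (toward the telomeric
    tract). ``subtelomeric`` and ``telomeric`` are disjoint 0-based
    half-open intervals whose union is [start, end); ``tss`` is the
    transcription-proximal boundary of the region.
    """

    region_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    tss: int
    subtelomeric: tuple[int, int]
    telomeric: tuple[int, int]
    type: str = ""
    signature: PromoterSignature = field(default_factory=PromoterSignature)
    tss_rank: str = "proximal"
    tract_category: str = ""

    def validate(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.region_id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"{self.region_id}: bad strand")
        sub, telo = self.subtelomeric, self.telomeric
        intervals = sorted([sub, telo])
        if intervals[0][1] != intervals[1][0]:
            raise ValueError(f"{self.region_id}: sub/telomeric intervals not adjacent")
        if intervals[0][0] != self.start or intervals[1][1] != self.end:
            raise ValueError(
                f"{self.region_id}: sub+telomeric union != [start, end)"
            )
        expected_tss = self.start if self.strand == "+" else self.end
        if self.tss != expected_tss:
            raise ValueError(f"{self.region_id}: tss not at transcription-proximal boundary")
        if self.tss_rank not in ("proximal", "distal"):
            raise ValueError(f"{self.region_id}: bad tss_rank")
        if self.type:
            if (self.type == TYPE_III) != (self.tract_category == INTERSTITIAL):
                raise ValueError(f"{self.region_id}: Type III <-> interstitial violated")
            if self.type == TYPE_I and not self.signature.any:
                raise ValueError(f"{self.region_id}: Type I requires promoter elements")
            if self.type == TYPE_II and self.signature.any:
                raise ValueError(f"{self.region_id}: Type II requires empty signature")


def log2_enrichment(
    capture: CoverageTrack, control: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin log2((capture + p) / (control + p)) track.

    Both tracks must share the sequence and bin grid. The pseudocount
    damps ratios in low-coverage bins.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (
        capture.seq_id != control.seq_id
        or capture.bin_size != control.bin_size
        or capture.seq_len != control.seq_len
    ):
        raise ValueError("capture and control tracks are on different bin grids")
    vals = np.log2((capture.values + pseudocount) / (control.values + pseudocount))
    return CoverageTrack(
        seq_id=capture.seq_id,
        seq_len=capture.seq_len,
        values=vals,
        bin_size=capture.bin_size,
        normalization="log2ratio",
    )


def cluster_cage_tags(
    tags: Iterable[tuple[str, int, str]], window: int = 50
) -> list[TagCluster]:
    """Single-linkage clustering of CAGE tag positions per sequence/strand.

    Tags on the same sequence and strand within ``window`` bp of their
    nearest neighbor form one cluster; the cluster peak is the modal
    position, ties resolved toward the transcription-5' side (smaller
    coordinate on '+', larger on '-').
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    by_key: dict[tuple[str, str], list[int]] = {}
    for seq_id, pos, strand in tags:
        by_key.setdefault((seq_id, strand), []).append(pos)
    clusters: list[TagCluster] = []
    for (seq_id, strand), positions in sorted(by_key.items()):
        positions.sort()
        group = [positions[0]]
        for p in positions[1:]:
            if p - group[-1] <= window:
                group.append(p)
            else:
                clusters.append(_finish_cluster(seq_id, strand, group))
                group = [p]
        clusters.append(_finish_cluster(seq_id, strand, group))
    clusters.sort(key=lambda c: (c.seq_id, c.position, c.strand))
    return clusters


def _finish_cluster(seq_id: str, strand: str, positions: list[int]) -> TagCluster:
    counts = Counter(positions)
    top = max(counts.values())
    modal = [p for p, n in counts.items() if n == top]
    peak = min(modal) if strand == "+" else max(modal)
    return TagCluster(seq_id=seq_id, position=peak, strand=strand, tag_count=len(positions))


def _enriched_runs(
    track: CoverageTrack, lo: int, hi: int, threshold: float
) -> list[tuple[int, int]]:
    """Maximal runs of bins >= threshold within [lo, hi), as bp intervals."""
    b_lo = lo // track.bin_size
    b_hi = math.ceil(hi / track.bin_size)
    mask = track.values[b_lo:b_hi] >= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, on in enumerate(mask):
        if on and start is None:
            start = i
        elif not on and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return [
        (
            (b_lo + a) * track.bin_size,
            min((b_lo + b) * track.bin_size, track.seq_len),
        )
        for a, b in runs
    ]


def _pick_tss(
    inner_boundary: int,
    strand: str,
    window: tuple[int, int],
    cage: Sequence[TagCluster],
    five_prime_ends: Sequence[int],
    slack: int = 500,
) -> tuple[int, str]:
    """TSS placement: CAGE peak first, then modal 5' end, then the boundary.

    "Upstream" is relative to transcription direction: smaller coordinates
    on '+', larger on '-'. CAGE peaks within the search window compete by
    distance to the enrichment-run boundary, upstream peaks preferred on
    ties.
    """
    w_lo, w_hi = window
    peaks = [c.position for c in cage if w_lo - slack <= c.position < w_hi + slack]
    if peaks:
        upstream_sign = -1 if strand == "+" else 1

        def rank(p: int) -> tuple[int, int]:
            upstream = (p - inner_boundary) * upstream_sign >= 0
            return (abs(p - inner_boundary), 0 if upstream else 1)

        return min(peaks, key=rank), "cage"
    ends = [p for p in five_prime_ends if w_lo - slack <= p < w_hi + slack]
    if ends:
        counts = Counter(ends)
        top = max(counts.values())
        modal = [p for p, n in counts.items() if n == top]
        peak = min(modal) if strand == "+" else max(modal)
        return peak, "long_read"
    return inner_boundary, "boundary"


def call_terra_regions(
    tracts: Sequence[RepeatTract],
    enrichment: dict[str, CoverageTrack] | None,
    long_read_5p_ends: Sequence[tuple[str, int, str]] = (),
    cage: Sequence[TagCluster] = (),
    seq_lengths: dict[str, int] | None = None,
    end_window: int = 100_000,
    enr_threshold: float = 1.0,
    min_evidence: int = 2,
    min_region_len: int = 200,
) -> list[TerraRegion]:
    """Call TERRA transcription regions from classified tracts and evidence.

    For each tract, the ``end_window`` adjacent to its subtelomeric side
    is searched for a contiguous run of log2-enrichment bins >=
    ``enr_threshold`` that reaches the tract; the TSS is placed at the
    nearest CAGE cluster peak to the run's inner boundary if any, else at
    the modal long-read 5' end, else at the boundary itself. A region
    spans TSS -> distal edge of the telomeric tract. A second,
    telomere-distal enriched run with its own TSS evidence yields a
    second region with tss_rank='distal'. Interstitial tracts are
    searched on both flanks under the same rules. An arm with fewer than
    ``min_evidence`` of the three evidence classes yields no region, as
    do candidate regions shorter than ``min_region_len`` bp.

    Returned regions are unclassified (type='') -- see classify_region.
    """
    if seq_lengths is None:
        seq_lengths = {}
    regions: list[TerraRegion] = []
    its_counter: dict[str, int] = {}
    for tract in sorted(tracts, key=lambda t: (t.seq_id, t.start)):
        seq_len = seq_lengths.get(tract.seq_id)
        if seq_len is None and enrichment and tract.seq_id in enrichment:
            seq_len = enrichment[tract.seq_id].seq_len
        if seq_len is None:
            seq_len = tract.end
        track = (enrichment or {}).get(tract.seq_id)
        sides: list[str]
        if tract.category == TERMINAL_Q:
            sides = ["left"]
        elif tract.category == TERMINAL_P:
            sides = ["right"]
        elif tract.category == INTERSTITIAL:
            sides = ["left", "right"]
        else:
            continue
        best: list[TerraRegion] = []
        best_evidence = -1
        for side in sides:
            made, n_evidence = _call_one_side(
                tract, side, track, long_read_5p_ends, cage, seq_len,
                end_window, enr_threshold, min_evidence, min_region_len,
                its_counter,
            )
            if made and n_evidence > best_evidence:
                best, best_evidence = made, n_evidence
        regions.extend(best)
    for r in regions:
        r.validate()
    return regions


def _call_one_side(
    tract: RepeatTract,
    side: str,
    track: CoverageTrack | None,
    long_read_5p_ends: Sequence[tuple[str, int, str]],
    cage: Sequence[TagCluster],
    seq_len: int,
    end_window: int,
    enr_threshold: float,
    min_evidence: int,
    min_region_len: int,
    its_counter: dict[str, int],
) -> tuple[list[TerraRegion], int]:
    """Evaluate one subtelomeric flank of a tract; returns (regions, n_evidence)."""
    # 'left' flank: transcription rightward into the tract, '+' strand;
    # 'right' flank: transcription leftward, '-' strand.
    strand = "+" if side == "left" else "-"
    if side == "left":
        w_lo, w_hi = max(0, tract.start - end_window), tract.start
    else:
        w_lo, w_hi = tract.end, min(seq_len, tract.end + end_window)
    if w_lo >= w_hi:
        return [], 0

    cage_here = [
        c for c in cage
        if c.seq_id == tract.seq_id and c.strand == strand and w_lo <= c.position < w_hi
    ]
    ends_here = [
        p for (sid, p, st) in long_read_5p_ends
        if sid == tract.seq_id and st == strand and w_lo <= p < w_hi
    ]
    runs = _enriched_runs(track, w_lo, w_hi, enr_threshold) if track else []
    # the proximal run must reach the tract: its tract-side edge lies
    # within one bin of the flank's tract boundary
    touch = tract.start if side == "left" else tract.end
    bin_slack = track.bin_size if track else 0
    if side == "left":
        proximal_runs = [r for r in runs if touch - r[1] <= bin_slack]
    else:
        proximal_runs = [r for r in runs if r[0] - touch <= bin_slack]
    n_evidence = sum([bool(proximal_runs), bool(ends_here), bool(cage_here)])
    if n_evidence < min_evidence:
        return [], n_evidence

    if proximal_runs:
        run = max(proximal_runs, key=lambda r: r[1] - r[0])
        inner = run[0] if side == "left" else run[1]
    else:
        # no enrichment evidence: anchor on the most upstream 5'-end/CAGE signal
        candidates = [c.position for c in cage_here] + ends_here
        inner = min(candidates) if side == "left" else max(candidates)
        run = None

    regions = []
    proximal = _build_region(
        tract, side, strand, inner, (w_lo, w_hi), cage_here, ends_here,
        seq_len, "proximal", its_counter, min_region_len,
    )
    if proximal is not None:
        regions.append(proximal)

    # a distal second run, separated from the proximal one, with its own
    # TSS evidence (only meaningful for terminal tracts)
    if run is not None and tract.category in (TERMINAL_P, TERMINAL_Q):
        distal_runs = [
            r for r in runs
            if (r[1] < run[0] if side == "left" else r[0] > run[1])
        ]
        for d in sorted(distal_runs, key=lambda r: r[0] if side == "left" else -r[1]):
            d_inner = d[0] if side == "left" else d[1]
            local = (max(w_lo, d[0] - 1000), min(w_hi, d[1] + 1000))
            d_cage = [c for c in cage_here if local[0] <= c.position < local[1]]
            d_ends = [p for p in ends_here if local[0] <= p < local[1]]
            if not d_cage and not d_ends:
                continue
            distal = _build_region(
                tract, side, strand, d_inner, local, d_cage, d_ends,
                seq_len, "distal", its_counter, min_region_len,
            )
            if distal is not None:
                regions.append(distal)
                break
    return regions, n_evidence


def _build_region(
    tract: RepeatTract,
    side: str,
    strand: str,
    inner_boundary: int,
    window: tuple[int, int],
    cage_here: Sequence[TagCluster],
    ends_here: Sequence[int],
    seq_len: int,
    tss_rank: str,
    its_counter: dict[str, int],
    min_region_len: int,
) -> TerraRegion | None:
    tss, _source = _pick_tss(inner_boundary, strand, window, cage_here, ends_here)
    tss = max(0, min(tss, seq_len))
    if side == "left":
        tss = min(tss, tract.start)
        start, end = tss, tract.end
        sub = (tss, tract.start)
    else:
        tss = max(tss, tract.end)
        start, end = tract.start, tss
        sub = (tract.end, tss)
    if end - start < min_region_len:
        return None
    if tract.category == TERMINAL_Q:
        region_id = f"{tract.seq_id}q"
    elif tract.category == TERMINAL_P:
        region_id = f"{tract.seq_id}p"
    else:
        n = its_counter.get(tract.seq_id, 0) + 1
        its_counter[tract.seq_id] = n
        region_id = f"ITS_{tract.seq_id}_{n}"
    if tss_rank == "distal":
        region_id += "_distal"
    return TerraRegion(
        region_id=region_id,
        seq_id=tract.seq_id,
        start=start,
        end=end,
        strand=strand,
        tss=tss,
        subtelomeric=sub,
        telomeric=(tract.start, tract.end),
        tss_rank=tss_rank,
        tract_category=tract.category,
    )


def classify_region(region: TerraRegion, signature: PromoterSignature) -> str:
    """Type assignment: interstitial tract -> III; terminal with at least
    one promoter element -> I; terminal with empty signature -> II.

    The region is updated in place (type and signature) and the type
    returned. Pure in its inputs: permutation of callers never changes
    the outcome.
    """
    if region.tract_category == INTERSTITIAL:
        rtype = TYPE_III
    elif signature.any:
        rtype = TYPE_I
    else:
        rtype = TYPE_II
    region.type = rtype
    region.signature = signature
    region.validate()
    return rtype


# --- export / import -------------------------------------------------------

_GTF_SOURCE = "terrakit"


def export_regions_bed(regions: Sequence[TerraRegion]) -> str:
    """BED6 text: one line per region, name=region_id, score=0."""
    _check_unique(regions)
    lines = []
    for r in sorted(regions, key=lambda r: (r.seq_id, r.start, r.region_id)):
        lines.append(
            f"{r.seq_id}\t{r.start}\t{r.end}\t{r.region_id}\t0\t{r.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def export_regions_gtf(regions: Sequence[TerraRegion]) -> str:
    """GTF text (1-based inclusive): a transcript feature per region plus
    subtelomeric and telomeric child features."""
    _check_unique(regions)
    lines = []
    for r in sorted(regions, key=lambda r: (r.seq_id, r.start, r.region_id)):
        sig = "".join("1" if f else "0" for f in r.signature.as_tuple())
        attrs = (
            f'gene_name "{r.region_id}"; region_type "{r.type}"; '
            f'tss "{r.tss}"; tss_rank "{r.tss_rank}"; '
            f'tract_category "{r.tract_category}"; signature "{sig}";'
        )
        lines.append(
            f"{r.seq_id}\t{_GTF_SOURCE}\ttranscript\t{r.start + 1}\t{r.end}\t.\t"
            f"{r.strand}\t.\t{attrs}"
        )
        for name, (s, e) in (
            ("subtelomeric", r.subtelomeric),
            ("telomeric", r.telomeric),
        ):
            if e > s:
                lines.append(
                    f"{r.seq_id}\t{_GTF_SOURCE}\t{name}\t{s + 1}\t{e}\t.\t"
                    f"{r.strand}\t.\t{attrs}"
                )
    return "\n".join(lines) + ("\n" if lines else "")


def import_regions_gtf(text: str) -> list[TerraRegion]:
    """Parse regions back from export_regions_gtf output (round-trip exact)."""
    import re as _re

    transcripts: dict[str, TerraRegion] = {}
    children: dict[str, dict[str, tuple[int, int]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"GTF line {lineno}: expected 9 fields")
        seq_id, _src, feature, start1, end1, _score, strand, _frame, attrs = parts
        attr = dict(_re.findall(r'(\w+) "([^"]*)"', attrs))
        rid = attr["gene_name"]
        start, end = int(start1) - 1, int(end1)
        if feature == "transcript":
            sig = attr.get("signature", "000")
            transcripts[rid] = TerraRegion(
                region_id=rid,
                seq_id=seq_id,
                start=start,
                end=end,
                strand=strand,
                tss=int(attr["tss"]),
                subtelomeric=(start, start),
                telomeric=(start, end),
                type=attr.get("region_type", ""),
                signature=PromoterSignature(sig[0] == "1", sig[1] == "1", sig[2] == "1"),
                tss_rank=attr.get("tss_rank", "proximal"),
                tract_category=attr.get("tract_category", ""),
            )
        elif feature in ("subtelomeric", "telomeric"):
            children.setdefault(rid, {})[feature] = (start, end)
    regions = []
    for rid, r in transcripts.items():
        kids = children.get(rid, {})
        telo = kids.get("telomeric", (r.start, r.end))
        if "subtelomeric" in kids:
            sub = kids["subtelomeric"]
        else:
            # empty subtelomeric intervals are not emitted; reconstruct at
            # the tss-side boundary
            sub = (r.tss, r.tss)
        r.telomeric = telo
        r.subtelomeric = sub
        r.validate()
        regions.append(r)
    regions.sort(key=lambda r: (r.seq_id, r.start, r.region_id))
    return regions


def _check_unique(regions: Sequence[TerraRegion]) -> None:
    seen: set[str] = set()
    for r in regions:
        if r.region_id in seen:
            raise ValueError(f"duplicate region_id {r.region_id!r}")
        seen.add(r.region_id)
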