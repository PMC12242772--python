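"""Format readers and writers.

BED and bedGraph are 0-based half-open; GTF is 1-based inclusive (handled
in :mod:`terrakit.annotate`). Writers order their output deterministically
so runs are diffable. Malformed records raise with the offending line
number.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from terrakit.annotate import CoverageTrack, TerraRegion
from terrakit.promoter_elements import ElementArray, ElementConsensus, PromoterSignature
from terrakit.quantify import CountMatrix
from terrakit.repeatscan import (
    AlignmentRecord,
    ReadTractMeasurement,
    RepeatTract,
    SequenceRecord,
)
from terrakit import simdata


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                name = line[1:].split()[0]
                if not name:
                    raise ValueError(f"{path}:{lineno}: empty FASTA record name")
                chunks = []
            elif line:
                if name is None:
                    raise ValueError(f"{path}:{lineno}: sequence before header")
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_consensus_fasta(path: str | Path, min_identity: float = 0.8) -> list[ElementConsensus]:
    """Element consensus FASTA with records named e61/e29/e37."""
    return [
        ElementConsensus(rec.id, rec.sequence, min_identity)
        for rec in read_fasta(path)
    ]


# --- SAM / BAM -------------------------------------------------------------

def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read alignments into the minimal AlignmentRecord abstraction.

    Unmapped records are skipped. Flags follow SAM semantics.
    """
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_start is None:
                continue
            end = seg.reference_end
            if end is None or end <= seg.reference_start:
                end = seg.reference_start + (seg.query_length or 1)
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    seq_id=seg.reference_name,
                    start=seg.reference_start,
                    end=end,
                    mapq=seg.mapping_quality,
                    paired=seg.is_paired,
                    proper_pair=seg.is_proper_pair,
                    reverse_strand=seg.is_reverse,
                    primary=not (seg.is_secondary or seg.is_supplementary),
                    supplementary=seg.is_supplementary,
                    secondary=seg.is_secondary,
                    duplicate=seg.is_duplicate,
                    first_in_pair=seg.is_read1 or not seg.is_paired,
                    mate_seq_id=seg.next_reference_name if seg.is_paired else None,
                    mate_start=seg.next_reference_start if seg.is_paired else None,
                )
            )
    return records


def write_sam(
    records: Sequence[AlignmentRecord],
    seq_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Emit coordinate-sorted SAM with generative coordinates.

    CIGAR is the reference span as a single match run; SEQ is omitted
    ('*') since downstream counting uses coordinates only.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sid, "LN": seq_lengths[sid]} for sid in sorted(seq_lengths)],
    }
    ordered = sorted(records, key=lambda r: (r.seq_id, r.start, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        tid = {sid: i for i, sid in enumerate(sorted(seq_lengths))}
        for r in ordered:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            seg.reference_id = tid[r.seq_id]
            seg.reference_start = r.start
            seg.mapping_quality = r.mapq
            seg.cigartuples = [(0, r.end - r.start)]
            seg.is_paired = r.paired
            seg.is_proper_pair = r.proper_pair
            seg.is_reverse = r.reverse_strand
            seg.is_secondary = r.secondary
            seg.is_supplementary = r.supplementary
            seg.is_duplicate = r.duplicate
            if r.paired:
                seg.is_read1 = r.first_in_pair
                seg.is_read2 = not r.first_in_pair
                seg.mate_is_reverse = not r.reverse_strand
                if r.mate_seq_id is not None:
                    seg.next_reference_id = tid[r.mate_seq_id]
                    seg.next_reference_start = r.mate_start
            fh.write(seg)


# --- BED -------------------------------------------------------------------

def write_bed(
    rows: Iterable[tuple[str, int, int, str, int, str]], path: str | Path
) -> None:
    """BED6 writer; rows are (seq_id, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for row in sorted(rows):
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval [{start},{end})")
            name = parts[3] if len(parts) > 3 else "."
            score = int(float(parts[4])) if len(parts) > 4 and parts[4] != "." else 0
            strand = parts[5] if len(parts) > 5 else "+"
            rows.append((parts[0], start, end, name, score, strand))
    return rows


def tracts_to_bed(tracts: Iterable[RepeatTract]) -> list[tuple[str, int, int, str, int, str]]:
    """Tract BED6 rows: name = category, score = round(1000 x purity)."""
    return [
        (t.seq_id, t.start, t.end, t.category, round(1000 * t.purity), t.strand)
        for t in tracts
    ]


def arrays_to_bed(arrays: Iterable[ElementArray]) -> list[tuple[str, int, int, str, int, str]]:
    return [
        (a.seq_id, a.start, a.end, a.element, round(1000 * a.mean_identity), a.strand)
        for a in arrays
    ]


def read_tags_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """CAGE tags / 5' ends: BED rows collapsed to (seq_id, position, strand)."""
    return [(seq_id, start, strand) for seq_id, start, _e, _n, _s, strand in read_bed(path)]


# --- bedGraph --------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            start = i * track.bin_size
            end = min(start + track.bin_size, track.seq_len)
            fh.write(f"{track.seq_id}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph(
    path: str | Path, bin_size: int = 30, normalization: str = "raw"
) -> dict[str, CoverageTrack]:
    """Read per-bin bedGraph tracks (one per sequence).

    Intervals must tile each sequence on the ``bin_size`` grid; the last
    interval of a sequence may be short and defines the sequence length.
    """
    values: dict[str, dict[int, float]] = {}
    seq_len: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs 4 fields")
            seq_id, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if start % bin_size:
                raise ValueError(f"{path}:{lineno}: interval off the {bin_size} bp grid")
            values.setdefault(seq_id, {})[start // bin_size] = val
            seq_len[seq_id] = max(seq_len.get(seq_id, 0), end)
    tracks = {}
    for seq_id, binmap in values.items():
        n_bins = math.ceil(seq_len[seq_id] / bin_size)
        arr = np.zeros(n_bins)
        for b, v in binmap.items():
            if b >= n_bins:
                raise ValueError(f"{path}: bin beyond sequence end for {seq_id}")
            arr[b] = v
        tracks[seq_id] = CoverageTrack(seq_id, seq_len[seq_id], arr, bin_size, normalization)
    return tracks


# --- TSV tables ------------------------------------------------------------

def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    out = cm.features.join(cm.counts)
    out.sort_index().to_csv(path, sep="\t", index_label="feature_id")


def read_count_matrix(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    meta_cols = ["seq_id", "start", "end", "strand", "region_id",
                 "region_type", "subregion", "tss_rank"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    features = df[meta_cols]
    counts = df.drop(columns=meta_cols).astype(int)
    return CountMatrix(features, counts)


def write_read_measurements(
    measurements: Iterable[ReadTractMeasurement], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(m.read_id, m.bulk_len, m.telo_len, m.telo_touches_3prime)
         for m in measurements],
        columns=["read_id", "bulk_len", "telo_len", "telo_touches_3prime"],
    ).sort_values("read_id")
    df.to_csv(path, sep="\t", index=False)


# --- truth JSON ------------------------------------------------------------

def write_truth_json(truth: simdata.SimTruth, path: str | Path) -> None:
    payload = {
        "seq_lengths": truth.seq_lengths,
        "tracts": [dataclasses.asdict(t) for t in truth.tracts],
        "arrays": [list(a) for a in truth.arrays],
        "regions": [_region_to_dict(r) for r in truth.regions],
        "region_expression": truth.region_expression,
        "polya_prob": truth.polya_prob,
        "read_origin": truth.read_origin,
        "read_tract_len": truth.read_tract_len,
        "read_polya": truth.read_polya,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path: str | Path) -> simdata.SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth = simdata.SimTruth()
    truth.seq_lengths = payload["seq_lengths"]
    truth.tracts = [RepeatTract(**t) for t in payload["tracts"]]
    truth.arrays = [tuple(a) for a in payload["arrays"]]
    truth.regions = [_region_from_dict(d) for d in payload["regions"]]
    truth.region_expression = payload["region_expression"]
    truth.polya_prob = payload["polya_prob"]
    truth.read_origin = payload["read_origin"]
    truth.read_tract_len = payload["read_tract_len"]
    truth.read_polya = payload["read_polya"]
    return truth


def _region_to_dict(r: TerraRegion) -> dict:
    d = dataclasses.asdict(r)
    d["signature"] = list(r.signature.as_tuple())
    d["subtelomeric"] = list(r.subtelomeric)
    d["telomeric"] = list(r.telomeric)
    return d


def _region_from_dict(d: dict) -> TerraRegion:
    d = dict(d)
    sig = d.pop("signature")
    return TerraRegion(
        signature=PromoterSignature(*sig),
        subtelomeric=tuple(d.pop("subtelomeric")),
        telomeric=tuple(d.pop("telomeric")),
        **d,
    )
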