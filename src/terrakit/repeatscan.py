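"""Detection and measurement of telomeric repeat tracts.

The telomere of every human chromosome ends in a tandem array of the
hexamer TTAGGG (read on the G-rich strand). This module finds such tracts
in arbitrary DNA sequences -- genome assemblies, where tracts are terminal
(true telomeres) or interstitial (ITS sites), and long sequencing reads,
where the tract length per read measures the telomeric repeat content of a
TERRA transcript. It also applies the long-read alignment filters used for
chromosome-end-specific read counting: mapping quality at least 1, primary
or supplementary alignments only, and removal of supplementary alignments
whose read already has a surviving primary alignment.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

TELOMERE_MOTIF = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: categories a tract can take once placed on a sequence
TERMINAL_P = "terminal_p"
TERMINAL_Q = "terminal_q"
INTERSTITIAL = "interstitial"
READ_INTERNAL = "read_internal"

_DNA_RE = re.compile(r"^[ACGTN]*$")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class SequenceFormatError(ValueError):
    """Raised when a sequence contains characters outside A/C/G/T/N."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA (or DNA-encoded RNA) sequence.

    The sequence is uppercased on construction; any character outside
    {A, C, G, T, N} is rejected. N never matches the telomeric motif and
    counts against tract purity.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not _DNA_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise SequenceFormatError(
                f"sequence {self.id!r} contains non-DNA characters: {bad}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatTract:
    """A detected run of telomeric repeats.

    ``strand`` is '+' when the G-rich motif (TTAGGG) reads on the given
    sequence as written, '-' when its reverse complement (CCCTAA) does.
    ``purity`` is the fraction of the tract span covered by exact motif
    copies: 6 * unit_count / (end - start), in (0, 1].
    """

    seq_id: str
    start: int
    end: int
    strand: str
    unit_count: int
    category: str = READ_INTERNAL

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid tract interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def purity(self) -> float:
        return 6 * self.unit_count / self.span


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal alignment abstraction over which filtering rules are defined.

    Mirrors the SAM fields the counting and filtering rules depend on;
    exactly one of primary/supplementary/secondary is true.
    """

    read_id: str
    seq_id: str
    start: int
    end: int
    mapq: int
    paired: bool = False
    proper_pair: bool = False
    reverse_strand: bool = False
    primary: bool = True
    supplementary: bool = False
    secondary: bool = False
    duplicate: bool = False
    first_in_pair: bool = True
    mate_seq_id: str | None = None
    mate_start: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"alignment {self.read_id!r}: start {self.start} >= end {self.end}"
            )
        if sum((self.primary, self.supplementary, self.secondary)) != 1:
            raise ValueError(
                f"alignment {self.read_id!r}: exactly one of primary/"
                "supplementary/secondary must be set"
            )

    @property
    def strand(self) -> str:
        return "-" if self.reverse_strand else "+"


def _motif_occurrences(seq: str, motif: str) -> list[int]:
    """Start positions of every exact occurrence of ``motif`` in ``seq``."""
    starts = []
    i = seq.find(motif)
    while i != -1:
        starts.append(i)
        i = seq.find(motif, i + 1)
    return starts


def _chain_occurrences(
    starts: Sequence[int], motif_len: int, max_gap: int
) -> list[tuple[int, int, int]]:
    """Partition sorted occurrence starts into maximal chains.

    Two consecutive occurrences belong to the same chain when the gap
    between the end of one and the start of the next is at most max_gap.
    Returns (start, end, unit_count) per chain; overlapping occurrences
    cannot arise for motifs without self-overlap (TTAGGG has none), so
    unit_count counts disjoint motif copies.
    """
    chains: list[tuple[int, int, int]] = []
    if not starts:
        return chains
    chain_start = starts[0]
    prev_end = starts[0] + motif_len
    count = 1
    for s in starts[1:]:
        if s - prev_end <= max_gap:
            count += 1
        else:
            chains.append((chain_start, prev_end, count))
            chain_start = s
            count = 1
        prev_end = s + motif_len
    chains.append((chain_start, prev_end, count))
    return chains


def find_repeat_tracts(
    seq: SequenceRecord,
    motif: str = TELOMERE_MOTIF,
    min_tract: int = 200,
    max_gap: int = 24,
    min_purity: float = 0.8,
) -> list[RepeatTract]:
    """Find telomeric repeat tracts on both strands of ``seq``.

    Exact occurrences of ``motif`` (and, for the '-' strand, of its
    reverse complement) separated by at most ``max_gap`` bp are chained
    into candidate tracts; candidates spanning at least ``min_tract`` bp
    with purity at least ``min_purity`` are returned sorted by start.
    Tract boundaries are trimmed to the outermost exact motif match, so a
    reported tract always begins and ends with a full motif copy.

    Parameters
    ----------
    motif:
        The G-rich repeat unit, 6 bp (default TTAGGG).
    min_tract:
        Minimum tract span in bp (span >= min_tract passes). The
        interstitial-telomeric-sequence convention of tracts longer than
        200 bp corresponds to the default of 200.
    max_gap:
        Maximum non-motif gap (bp) bridged within one tract.
    min_purity:
        Minimum fraction of the span covered by exact motif copies.
    """
    if len(motif) != 6:
        raise ValueError("motif must be a 6-mer")
    if min_tract < 6:
        raise ValueError("min_tract must be >= 6")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not 0 < min_purity <= 1:
        raise ValueError("min_purity must be in (0, 1]")
    motif = motif.upper()
    s = seq.sequence
    if not s:
        return []
    tracts: list[RepeatTract] = []
    for strand, m in (("+", motif), ("-", reverse_complement(motif))):
        starts = _motif_occurrences(s, m)
        candidates = _chain_occurrences(starts, 6, max_gap)
        candidates = _merge_overlapping(candidates)
        for c_start, c_end, n_units in candidates:
            span = c_end - c_start
            if span < min_tract:
                continue
            if 6 * n_units / span < min_purity:
                continue
            tracts.append(
                RepeatTract(
                    seq_id=seq.id,
                    start=c_start,
                    end=c_end,
                    strand=strand,
                    unit_count=n_units,
                )
            )
    tracts.sort(key=lambda t: (t.start, t.end, t.strand))
    return tracts


def _merge_overlapping(
    chains: list[tuple[int, int, int]],
) -> list[tuple[int, int, int]]:
    # maximal chains are separated by > max_gap by construction; kept as a
    # guard for externally supplied candidate lists
    merged: list[tuple[int, int, int]] = []
    for c in sorted(chains):
        if merged and c[0] < merged[-1][1]:
            prev = merged[-1]
            merged[-1] = (prev[0], max(prev[1], c[1]), prev[2] + c[2])
        else:
            merged.append(c)
    return merged


def classify_tracts(
    tracts: Sequence[RepeatTract],
    seq_len: int,
    end_window: int = 100_000,
) -> list[RepeatTract]:
    """Assign terminal/interstitial categories to all tracts of one sequence.

    The tract closest to coordinate 0 is ``terminal_p`` if it starts within
    ``end_window`` of the sequence start; the tract closest to the sequence
    end is ``terminal_q`` if it ends within ``end_window`` of it; every
    other tract is ``interstitial``. Exact distance ties are broken in
    favor of the longer tract.
    """
    if end_window <= 0:
        raise ValueError("end_window must be > 0")
    for t in tracts:
        if t.end > seq_len:
            raise ValueError(
                f"tract [{t.start}, {t.end}) exceeds sequence length {seq_len}"
            )
    if not tracts:
        return []
    # distance tie -> longer tract wins
    p_candidate = min(tracts, key=lambda t: (t.start, -t.span))
    q_candidate = min(tracts, key=lambda t: (seq_len - t.end, -t.span))
    out = []
    for t in tracts:
        category = INTERSTITIAL
        is_p = t is p_candidate and t.start < end_window
        is_q = t is q_candidate and seq_len - t.end < end_window
        if is_p and is_q:
            # a single tract near both ends of a short sequence: take the
            # nearer end, p on an exact tie
            category = TERMINAL_P if t.start <= seq_len - t.end else TERMINAL_Q
        elif is_p:
            category = TERMINAL_P
        elif is_q:
            category = TERMINAL_Q
        out.append(replace(t, category=category))
    return out


def classify_tract(
    tract: RepeatTract,
    seq_len: int,
    end_window: int = 100_000,
    others: Sequence[RepeatTract] = (),
) -> str:
    """Category of a single tract, considering ``others`` on the same sequence."""
    all_tracts = [tract, *others]
    classified = classify_tracts(all_tracts, seq_len, end_window)
    return classified[0].category


@dataclass(frozen=True)
class ReadTractMeasurement:
    """Per-read bulk length and telomeric tract length."""

    read_id: str
    bulk_len: int
    telo_len: int
    telo_touches_3prime: bool


def measure_read_tract(
    read: SequenceRecord,
    motif: str = TELOMERE_MOTIF,
    min_tract: int = 30,
    max_gap: int = 48,
    min_purity: float = 0.5,
    three_prime_margin: int = 30,
) -> ReadTractMeasurement:
    """Measure the telomeric repeat content of one long read.

    ``telo_len`` is the span of the longest G-rich (motif-orientation)
    tract in the read, 0 when none passes the thresholds. The default
    chaining parameters are looser than for genome scans to tolerate
    Nanopore substitution/indel error while still rejecting chance hexamer
    hits. ``telo_touches_3prime`` is true when that tract ends within
    ``three_prime_margin`` nt of the read's 3' terminus -- the expected
    architecture of a TERRA transcript read in the 5'->3' direction.
    """
    if len(read) == 0:
        raise ValueError("read must be non-empty")
    tracts = [
        t
        for t in find_repeat_tracts(
            read, motif=motif, min_tract=min_tract, max_gap=max_gap,
            min_purity=min_purity,
        )
        if t.strand == "+"
    ]
    if not tracts:
        return ReadTractMeasurement(read.id, len(read), 0, False)
    best = max(tracts, key=lambda t: (t.span, -t.start))
    touches = len(read) - best.end <= three_prime_margin
    return ReadTractMeasurement(read.id, len(read), best.span, touches)


def filter_long_read_alignments(
    records: Iterable[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Unique-read filtering for long-read (Nanopore) alignments.

    Keeps records with MAPQ >= 1 whose flags are one of: primary forward,
    primary reverse, supplementary forward, supplementary reverse (i.e.
    unpaired, non-secondary, non-duplicate). Then, per read id, if a
    primary record survives all supplementary records of that read are
    dropped, and at most one record per read id is retained (the
    highest-MAPQ, leftmost supplementary when no primary survives).
    Idempotent by construction.
    """
    passing = [
        r
        for r in records
        if r.mapq >= 1
        and (r.primary or r.supplementary)
        and not r.paired
        and not r.duplicate
    ]
    by_read: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for r in passing:
        if r.read_id not in by_read:
            order.append(r.read_id)
        by_read.setdefault(r.read_id, []).append(r)
    kept: list[AlignmentRecord] = []
    for read_id in order:
        group = by_read[read_id]
        primaries = [r for r in group if r.primary]
        if primaries:
            kept.append(
                min(primaries, key=lambda r: (-r.mapq, r.seq_id, r.start))
            )
        else:
            kept.append(min(group, key=lambda r: (-r.mapq, r.seq_id, r.start)))
    return kept
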