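"""Detection of subtelomeric 61/29/37 bp promoter repeat elements.

Human subtelomeric TERRA promoters are built from tandem arrays of three
repeat element families, 61, 29 and 37 bp long, that are GC-rich and
shared between many chromosome ends. The presence of at least one of these
element arrays upstream of a transcription start site is what defines a
Type I TERRA transcription region. The element consensus sequences diverge
between chromosome arms, so detection is a similarity search (banded edit
distance) rather than exact matching.

Consensus sequences are supplied by the caller (config FASTA with records
named e61/e29/e37); the simulator ships synthetic stand-in consensuses so
the whole pipeline is testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from terrakit.repeatscan import SequenceRecord, reverse_complement

ELEMENT_LENGTHS = {"e61": 61, "e29": 29, "e37": 37}


@dataclass(frozen=True)
class ElementConsensus:
    """Consensus sequence of one promoter element family."""

    name: str
    sequence: str
    min_identity: float = 0.8

    def __post_init__(self) -> None:
        if self.name not in ELEMENT_LENGTHS:
            raise ValueError(f"element name must be one of {set(ELEMENT_LENGTHS)}")
        if len(self.sequence) != ELEMENT_LENGTHS[self.name]:
            raise ValueError(
                f"{self.name} consensus must be {ELEMENT_LENGTHS[self.name]} bp, "
                f"got {len(self.sequence)}"
            )
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class ElementArray:
    """A tandem array of one element family on a sequence."""

    seq_id: str
    start: int
    end: int
    element: str
    copies: int
    mean_identity: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("array start must be < end")
        if self.copies < 1:
            raise ValueError("array must contain at least one copy")


@dataclass(frozen=True)
class PromoterSignature:
    """Which element families overlap a promoter interval."""

    has61: bool = False
    has29: bool = False
    has37: bool = False

    @property
    def any(self) -> bool:
        return self.has61 or self.has29 or self.has37

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.has61, self.has29, self.has37)


def _seed_positions(seq: str, consensus: str, k: int) -> list[int]:
    """Candidate element start positions from exact k-mer seeding.

    Every exact occurrence of any consensus k-mer votes for the element
    start position implied by the k-mer's offset within the consensus.
    With up to 20% divergence at least one clean k-mer almost always
    survives per copy; at divergence 0 every copy seeds exactly.
    """
    kmer_offsets: dict[str, list[int]] = {}
    for off in range(len(consensus) - k + 1):
        kmer_offsets.setdefault(consensus[off : off + k], []).append(off)
    votes: set[int] = set()
    for kmer, offsets in kmer_offsets.items():
        i = seq.find(kmer)
        while i != -1:
            for off in offsets:
                pos = i - off
                if pos >= 0:
                    votes.add(pos)
            i = seq.find(kmer, i + 1)
    return sorted(votes)


def _scan_one_strand(
    seq: str,
    consensus: str,
    min_identity: float,
    band: int,
    seed_k: int,
) -> list[tuple[int, int, float]]:
    """Greedy left-to-right tiling of element copies on one strand.

    Returns (start, end, identity) hits. Each candidate position is
    verified by aligning the consensus to a window around it (edit
    distance with up to ``band`` boundary slack); accepted copies must not
    overlap a previously accepted copy by more than half an element.
    """
    L = len(consensus)
    max_edits = int((1 - min_identity) * L) + band

    def verify(pos: int) -> tuple[int, int, float] | None:
        lo = max(0, pos - band)
        hi = min(len(seq), pos + L + band)
        window = seq[lo:hi]
        if len(window) < L - band:
            return None
        aln = edlib.align(consensus, window, mode="HW", task="locations",
                          k=max_edits)
        if aln["editDistance"] < 0:
            return None
        identity = 1 - aln["editDistance"] / L
        if identity < min_identity:
            return None
        w_start, w_end = aln["locations"][0]
        return (lo + w_start, lo + w_end + 1, identity)

    hits: list[tuple[int, int, float]] = []
    last_end = -1
    for pos in _seed_positions(seq, consensus, seed_k):
        if pos < last_end - L // 4:
            continue
        hit = verify(pos)
        if hit is None or hit[0] < last_end - L // 4:
            continue
        hits.append(hit)
        last_end = hit[1]
        # tandem extension: probe the expected next-copy position directly,
        # so a diverged copy without a clean seed k-mer is not missed
        while True:
            nxt = verify(last_end)
            if nxt is None or nxt[0] < last_end - L // 4:
                break
            hits.append(nxt)
            last_end = nxt[1]
    return hits


def _chain_hits(
    hits: Sequence[tuple[int, int, float]],
    element_len: int,
    min_copies: int,
) -> list[tuple[int, int, int, float]]:
    """Chain per-copy hits into tandem arrays.

    Consecutive hits whose starts are within 1.5 x element length belong
    to the same array. Returns (start, end, copies, mean_identity).
    """
    arrays: list[tuple[int, int, int, float]] = []
    if not hits:
        return arrays
    group: list[tuple[int, int, float]] = [hits[0]]
    for h in hits[1:]:
        if h[0] - group[-1][0] <= 1.5 * element_len:
            group.append(h)
        else:
            if len(group) >= min_copies:
                arrays.append(_finish_group(group))
            group = [h]
    if len(group) >= min_copies:
        arrays.append(_finish_group(group))
    return arrays


def _finish_group(group: list[tuple[int, int, float]]) -> tuple[int, int, int, float]:
    start = group[0][0]
    end = group[-1][1]
    mean_id = sum(h[2] for h in group) / len(group)
    return (start, end, len(group), mean_id)


def find_element_arrays(
    seq: SequenceRecord,
    consensus: ElementConsensus,
    min_copies: int = 2,
    band: int = 5,
    seed_k: int = 11,
) -> list[ElementArray]:
    """Find tandem arrays of one promoter element family on both strands.

    The consensus is slid over both strands with a similarity search
    permitting substitutions and single-base indels (edit distance).
    Copies with identity >= consensus.min_identity whose starts fall
    within 1.5 x element length of the previous copy are chained into
    arrays; arrays with at least ``min_copies`` copies are returned
    sorted by start. Overlapping arrays of different element families
    are all reported independently.
    """
    if min_copies < 1:
        raise ValueError("min_copies must be >= 1")
    s = seq.sequence
    L = len(consensus.sequence)
    if L > len(s):
        return []
    seed_k = min(seed_k, L)
    arrays: list[ElementArray] = []
    for strand in "+-":
        target = s if strand == "+" else reverse_complement(s)
        hits = _scan_one_strand(
            target, consensus.sequence, consensus.min_identity, band, seed_k
        )
        for start, end, copies, mean_id in _chain_hits(hits, L, min_copies):
            if strand == "-":
                start, end = len(s) - end, len(s) - start
            arrays.append(
                ElementArray(
                    seq_id=seq.id,
                    start=start,
                    end=end,
                    element=consensus.name,
                    copies=copies,
                    mean_identity=mean_id,
                    strand=strand,
                )
            )
    arrays.sort(key=lambda a: (a.start, a.end, a.strand))
    return arrays


def promoter_signature(
    promoter: tuple[int, int],
    arrays: Iterable[ElementArray],
) -> PromoterSignature:
    """Which element families overlap a promoter interval by >= 1 bp.

    ``promoter`` is a 0-based half-open interval, conventionally the 3 kb
    upstream of a region's transcription start site, oriented with the
    region's transcription direction by the caller.
    """
    p_start, p_end = promoter
    if p_start >= p_end:
        raise ValueError("promoter interval must be non-empty")
    present = {"e61": False, "e29": False, "e37": False}
    for a in arrays:
        if a.start < p_end and p_start < a.end:
            present[a.element] = True
    return PromoterSignature(
        has61=present["e61"], has29=present["e29"], has37=present["e37"]
    )
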