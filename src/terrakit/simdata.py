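"""Synthetic mini-genomes, reads and evidence tracks with full ground truth.

The simulator emulates the data-generating conditions of a TERRA capture
sequencing study at desk scale: multi-arm mini-genomes whose arms carry
terminal telomeric tracts, 61/29/37 bp promoter element arrays upstream of
a planted TSS, interstitial telomeric sequences (some expressed), short
paired-end fragments and error-bearing long reads with known origins, CAGE
tags jittered around each TSS, capture/control coverage tracks, and a
poly(A)+/- split with per-region polyadenylation probabilities.

Everything is a pure function of the configuration and its seed: each
generator derives an independent random stream from (seed, op-id), so
outputs are byte-identical across runs and independent of call order.
Background sequence is i.i.d. uniform ACGT scrubbed of chance telomeric
hexamers outside planted tracts, so planted truth is exact.

The default configuration is the study condition used throughout the test
suite: a six-arm genome with three Type I regions of varying promoter
signatures (one lacking the 29 bp element), one Type II region, two
expressed interstitial (Type III) regions, and two silent chromosome ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from terrakit.annotate import CoverageTrack, TerraRegion, classify_region
from terrakit.promoter_elements import ElementConsensus, PromoterSignature
from terrakit.repeatscan import (
    INTERSTITIAL,
    TERMINAL_P,
    TERMINAL_Q,
    AlignmentRecord,
    RepeatTract,
    SequenceRecord,
    TELOMERE_MOTIF,
    reverse_complement,
)

# Synthetic stand-in consensus sequences for the three promoter element
# families (fixed, GC-rich, free of telomeric hexamers). Real consensuses
# can be supplied as a FASTA with records named e61/e29/e37.
SYNTHETIC_CONSENSUS = {
    "e61": "ACGAGGTCGTGCGAGTGCGGGCCCCTCAAAGGCGGCCTCAAACCGGCGGTGCAGTCGTACC",
    "e29": "CCCGCCCTAGGCTCCTGCGGAGCGGGCCC",
    "e37": "GAGCACGATCGAGCCCGGAGCGCTCCGTGAAGGCGCG",
}

ELEMENT_COPIES = {"e61": 5, "e29": 6, "e37": 8}


def synthetic_consensuses(min_identity: float = 0.8) -> list[ElementConsensus]:
    return [
        ElementConsensus(name, seq, min_identity)
        for name, seq in SYNTHETIC_CONSENSUS.items()
    ]


@dataclass
class ArmConfig:
    """One simulated chromosome arm."""

    name: str
    length: int = 300_000
    telomere_units: int = 500            # terminal tract = 6 * units bp
    orientation: str = "q"               # 'q': tract at the end; 'p': at the start
    promoter_elements: tuple[str, ...] = ("e61", "e29", "e37")
    expression: float = 0.0              # expected fragments from the region
    tss_offset: int = 2_000              # TSS -> tract distance (subtelomere length)
    distal_tss_offset: int | None = None  # second, telomere-distal TSS
    distal_expression: float = 0.0
    polya_prob: float = 0.5


@dataclass
class ItsConfig:
    """An interstitial telomeric sequence embedded in an arm."""

    arm: str
    position: int
    tract_units: int = 50
    expressed: bool = False
    expression: float = 0.0
    tss_offset: int = 500
    polya_prob: float = 0.5


@dataclass
class ShortReadConfig:
    read_len: int = 100
    frag_mean: float = 300.0
    frag_sd: float = 30.0
    background_fragments: int = 200
    low_mapq_frac: float = 0.05
    low_mapq: int = 5
    duplicate_frac: float = 0.05
    mapq: int = 60


@dataclass
class LongReadConfig:
    count: int = 200
    min_tract_units: int = 17            # ~100 bp
    max_tract_units: int = 250           # 1500 bp
    subtel_min: int = 200
    subtel_max: int = 800
    sub_rate: float = 0.04
    ins_rate: float = 0.02
    del_rate: float = 0.02
    mapq: int = 40
    supplementary_frac: float = 0.05
    low_mapq_frac: float = 0.05


@dataclass
class CageConfig:
    tags_per_tss: int = 20
    jitter_sd: float = 10.0


@dataclass
class SimConfig:
    seed: int
    arms: list[ArmConfig] = field(default_factory=list)
    its_sites: list[ItsConfig] = field(default_factory=list)
    short_reads: ShortReadConfig = field(default_factory=ShortReadConfig)
    long_reads: LongReadConfig = field(default_factory=LongReadConfig)
    cage: CageConfig = field(default_factory=CageConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def default_config(seed: int) -> SimConfig:
    """The standard six-arm study condition (see module docstring)."""
    arms = [
        ArmConfig("arm1", 320_000, 500, "q", ("e61", "e29", "e37"), 300.0,
                  polya_prob=0.8),
        ArmConfig("arm2", 360_000, 400, "p", ("e61", "e37"), 250.0,
                  polya_prob=0.2),
        ArmConfig("arm3", 400_000, 450, "q", ("e37",), 200.0, polya_prob=0.5),
        ArmConfig("arm4", 340_000, 350, "q", (), 150.0, polya_prob=0.5),
        ArmConfig("arm5", 300_000, 300, "q", (), 0.0),
        ArmConfig("arm6", 330_000, 300, "q", (), 0.0),
    ]
    its_sites = [
        ItsConfig("arm5", 150_000, 60, expressed=True, expression=120.0,
                  polya_prob=0.5),
        ItsConfig("arm6", 180_000, 45, expressed=True, expression=100.0,
                  polya_prob=0.5),
    ]
    return SimConfig(seed=seed, arms=arms, its_sites=its_sites)


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated dataset."""

    seq_lengths: dict[str, int] = field(default_factory=dict)
    tracts: list[RepeatTract] = field(default_factory=list)
    arrays: list[tuple[str, int, int, str, int]] = field(default_factory=list)
    regions: list[TerraRegion] = field(default_factory=list)
    region_expression: dict[str, float] = field(default_factory=dict)
    polya_prob: dict[str, float] = field(default_factory=dict)
    read_origin: dict[str, str] = field(default_factory=dict)
    read_tract_len: dict[str, int] = field(default_factory=dict)
    read_polya: dict[str, str] = field(default_factory=dict)

    def region(self, region_id: str) -> TerraRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _scrub_motifs(
    arr: np.ndarray, protected: list[tuple[int, int]], rng: np.random.Generator
) -> None:
    """Mutate chance TTAGGG/CCCTAA hits outside protected intervals in place."""
    protected = sorted(protected)
    for _ in range(50):
        s = arr.tobytes().decode()
        dirty = []
        for motif in (TELOMERE_MOTIF, reverse_complement(TELOMERE_MOTIF)):
            i = s.find(motif)
            while i != -1:
                if not any(a <= i and i + 6 <= b for a, b in protected):
                    dirty.append(i)
                i = s.find(motif, i + 1)
        if not dirty:
            return
        for i in dirty:
            # mutate a base of the occurrence lying outside every
            # protected interval
            for off in (2, 3, 1, 4, 0, 5):
                p = i + off
                if not any(a <= p < b for a, b in protected):
                    old = arr[p]
                    choices = [b for b in _BASES if b != old]
                    arr[p] = choices[rng.integers(0, 3)]
                    break
    raise RuntimeError("failed to scrub telomeric motifs from background")


def _mutate_copy(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return seq
    out = []
    for ch in seq:
        if rng.random() < divergence:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
    return "".join(out)


def simulate_genome(
    cfg: SimConfig, element_divergence: float = 0.0
) -> tuple[list[SequenceRecord], SimTruth]:
    """Build the mini-genome and its truth ledger.

    Each arm is assembled in 'q' orientation -- background, promoter
    element arrays filling the 3 kb upstream of the TSS, subtelomeric
    unique sequence, terminal TTAGGG tract -- and reverse-complemented
    wholesale for 'p' arms, mapping all truth coordinates x -> L - x.
    ``element_divergence`` mutates each planted element copy away from
    its consensus by the given per-base substitution rate.
    """
    rng = _rng(cfg, 1)
    truth = SimTruth()
    genome: list[SequenceRecord] = []
    its_by_arm: dict[str, list[ItsConfig]] = {}
    for its in cfg.its_sites:
        its_by_arm.setdefault(its.arm, []).append(its)

    for arm in cfg.arms:
        L = arm.length
        telo_len = 6 * arm.telomere_units
        tract_start = L - telo_len
        tss = tract_start - arm.tss_offset
        if tss <= 3_000:
            raise ValueError(f"{arm.name}: arm too short for promoter placement")
        arr = _random_dna(rng, L)
        protected: list[tuple[int, int]] = []

        # terminal tract
        tract_seq = (TELOMERE_MOTIF * arm.telomere_units).encode()
        arr[tract_start:L] = np.frombuffer(tract_seq, dtype="S1")
        protected.append((tract_start, L))
        tracts = [(tract_start, L, "terminal")]
        arrays: list[tuple[int, int, str, int]] = []

        # promoter element arrays, 37 bp element nearest the TSS
        cursor = tss
        for element in ("e37", "e29", "e61"):
            if element not in arm.promoter_elements:
                continue
            cons = SYNTHETIC_CONSENSUS[element]
            copies = ELEMENT_COPIES[element]
            block = "".join(
                _mutate_copy(cons, element_divergence, rng) for _ in range(copies)
            ).encode()
            start = cursor - 100 - len(block)
            arr[start : start + len(block)] = np.frombuffer(block, dtype="S1")
            arrays.append((start, start + len(block), element, copies))
            protected.append((start, start + len(block)))
            cursor = start

        # distal promoter (second TSS) carries its own e37 array
        if arm.distal_tss_offset is not None:
            d_tss = tract_start - arm.distal_tss_offset
            cons = SYNTHETIC_CONSENSUS["e37"]
            block = "".join(
                _mutate_copy(cons, element_divergence, rng)
                for _ in range(ELEMENT_COPIES["e37"])
            ).encode()
            start = d_tss - 100 - len(block)
            arr[start : start + len(block)] = np.frombuffer(block, dtype="S1")
            arrays.append((start, start + len(block), "e37", ELEMENT_COPIES["e37"]))
            protected.append((start, start + len(block)))

        # interstitial tracts (+ an e37 array upstream of expressed ones)
        for its in its_by_arm.get(arm.name, []):
            its_len = 6 * its.tract_units
            its_seq = (TELOMERE_MOTIF * its.tract_units).encode()
            arr[its.position : its.position + its_len] = np.frombuffer(
                its_seq, dtype="S1"
            )
            protected.append((its.position, its.position + its_len))
            tracts.append((its.position, its.position + its_len, "its"))
            if its.expressed:
                cons = SYNTHETIC_CONSENSUS["e37"]
                block = "".join(
                    _mutate_copy(cons, element_divergence, rng)
                    for _ in range(ELEMENT_COPIES["e37"])
                ).encode()
                i_tss = its.position - its.tss_offset
                start = i_tss - 50 - len(block)
                arr[start : start + len(block)] = np.frombuffer(block, dtype="S1")
                arrays.append((start, start + len(block), "e37",
                               ELEMENT_COPIES["e37"]))
                protected.append((start, start + len(block)))

        _scrub_motifs(arr, protected, rng)

        flip = arm.orientation == "p"
        if flip:
            seq = reverse_complement(arr.tobytes().decode())
        else:
            seq = arr.tobytes().decode()
        genome.append(SequenceRecord(arm.name, seq))
        truth.seq_lengths[arm.name] = L

        def _m(interval: tuple[int, int]) -> tuple[int, int]:
            a, b = interval
            return (L - b, L - a) if flip else (a, b)

        for a, b, kind in tracts:
            ma, mb = _m((a, b))
            if kind == "terminal":
                category = TERMINAL_P if flip else TERMINAL_Q
            else:
                category = INTERSTITIAL
            truth.tracts.append(
                RepeatTract(
                    seq_id=arm.name, start=ma, end=mb,
                    strand="-" if flip else "+",
                    unit_count=(mb - ma) // 6, category=category,
                )
            )
        for a, b, element, copies in arrays:
            ma, mb = _m((a, b))
            truth.arrays.append((arm.name, ma, mb, element, copies))

        strand = "-" if flip else "+"
        signature = PromoterSignature(
            has61="e61" in arm.promoter_elements,
            has29="e29" in arm.promoter_elements,
            has37="e37" in arm.promoter_elements,
        )
        terminal_category = TERMINAL_P if flip else TERMINAL_Q

        def _add_region(r_tss: int, rank: str, expression: float,
                        sig: PromoterSignature) -> None:
            rid = f"{arm.name}{'p' if flip else 'q'}"
            if rank == "distal":
                rid += "_distal"
            m_tss = L - r_tss if flip else r_tss
            m_tract = _m((tract_start, L))
            if flip:
                start, end = m_tract[0], m_tss
                sub = (m_tract[1], m_tss)
            else:
                start, end = m_tss, m_tract[1]
                sub = (m_tss, m_tract[0])
            region = TerraRegion(
                region_id=rid, seq_id=arm.name, start=start, end=end,
                strand=strand, tss=m_tss, subtelomeric=sub,
                telomeric=m_tract, tss_rank=rank,
                tract_category=terminal_category,
            )
            classify_region(region, sig)
            truth.regions.append(region)
            truth.region_expression[rid] = expression
            truth.polya_prob[rid] = arm.polya_prob

        if arm.expression > 0:
            _add_region(tss, "proximal", arm.expression, signature)
        if arm.distal_tss_offset is not None and arm.distal_expression > 0:
            _add_region(tract_start - arm.distal_tss_offset, "distal",
                        arm.distal_expression, signature)

        its_n = 0
        for its in its_by_arm.get(arm.name, []):
            its_n += 1
            if not its.expressed:
                continue
            its_len = 6 * its.tract_units
            i_tss = its.position - its.tss_offset
            a, b = _m((i_tss, its.position + its_len))
            m_tract = _m((its.position, its.position + its_len))
            m_tss = L - i_tss if flip else i_tss
            sub = (m_tract[1], m_tss) if flip else (m_tss, m_tract[0])
            region = TerraRegion(
                region_id=f"ITS_{arm.name}_{its_n}", seq_id=arm.name,
                start=a, end=b, strand="-" if flip else "+", tss=m_tss,
                subtelomeric=sub, telomeric=m_tract, tss_rank="proximal",
                tract_category=INTERSTITIAL,
            )
            classify_region(region, PromoterSignature(False, False, True))
            truth.regions.append(region)
            truth.region_expression[region.region_id] = its.expression
            truth.polya_prob[region.region_id] = its.polya_prob

    for r in truth.regions:
        r.validate()
    return genome, truth


def simulate_short_reads(
    truth: SimTruth, cfg: SimConfig
) -> tuple[list[AlignmentRecord], SimTruth]:
    """Draw paired-end fragments from expressed regions plus background.

    Per region the fragment count is Poisson with the configured
    expectation; fragment midpoints are uniform within the region.
    Background fragments avoid all regions so truth counts stay exact.
    A configured fraction of fragments is emitted with low MAPQ, and a
    configured fraction is re-emitted flagged as a PCR duplicate.
    Records are returned coordinate-sorted.
    """
    rng = _rng(cfg, 2)
    sr = cfg.short_reads
    records: list[AlignmentRecord] = []
    n_frag = 0

    def _emit(seq_id: str, start: int, end: int, origin: str, mapq: int,
              duplicate: bool, read_id: str, strand: str) -> None:
        r1s, r1e = start, min(start + sr.read_len, end)
        r2e, r2s = end, max(end - sr.read_len, start)
        rev_first = strand == "-"
        common = dict(
            read_id=read_id, seq_id=seq_id, mapq=mapq, paired=True,
            proper_pair=True, primary=True, duplicate=duplicate,
        )
        records.append(
            AlignmentRecord(start=r1s, end=r1e, reverse_strand=rev_first,
                            first_in_pair=True, mate_seq_id=seq_id,
                            mate_start=r2s, **common)
        )
        records.append(
            AlignmentRecord(start=r2s, end=r2e, reverse_strand=not rev_first,
                            first_in_pair=False, mate_seq_id=seq_id,
                            mate_start=r1s, **common)
        )
        truth.read_origin[read_id] = origin

    def _fragment(seq_id: str, lo: int, hi: int, origin: str, strand: str) -> None:
        nonlocal n_frag
        flen = int(np.clip(rng.normal(sr.frag_mean, sr.frag_sd),
                           sr.read_len, max(sr.read_len, hi - lo)))
        start = int(rng.integers(lo, max(lo + 1, hi - flen + 1)))
        end = min(start + flen, hi)
        mapq = sr.low_mapq if rng.random() < sr.low_mapq_frac else sr.mapq
        read_id = f"sr{n_frag:06d}"
        n_frag += 1
        _emit(seq_id, start, end, origin, mapq, False, read_id, strand)
        if rng.random() < sr.duplicate_frac:
            dup_id = f"sr{n_frag:06d}"
            n_frag += 1
            _emit(seq_id, start, end, origin, mapq, True, dup_id, strand)

    for region in truth.regions:
        n = rng.poisson(truth.region_expression[region.region_id])
        for _ in range(n):
            _fragment(region.seq_id, region.start, region.end,
                      region.region_id, region.strand)

    regions_by_seq: dict[str, list[TerraRegion]] = {}
    for r in truth.regions:
        regions_by_seq.setdefault(r.seq_id, []).append(r)
    seq_ids = sorted(truth.seq_lengths)
    emitted = 0
    while emitted < sr.background_fragments:
        seq_id = seq_ids[int(rng.integers(0, len(seq_ids)))]
        L = truth.seq_lengths[seq_id]
        start = int(rng.integers(0, max(1, L - int(sr.frag_mean))))
        end = min(start + int(sr.frag_mean), L)
        if any(start < r.end and r.start < end
               for r in regions_by_seq.get(seq_id, [])):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        _fragment(seq_id, start, end, "background", strand)
        emitted += 1

    records.sort(key=lambda r: (r.seq_id, r.start, r.read_id,
                                not r.first_in_pair))
    return records, truth


def _corrupt(seq: str, lr: LongReadConfig, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        roll = rng.random()
        if roll < lr.del_rate:
            continue
        if roll < lr.del_rate + lr.sub_rate:
            out.append(str(rng.choice([b for b in "ACGT" if b != ch])))
        else:
            out.append(ch)
        if rng.random() < lr.ins_rate:
            out.append(str(rng.choice(list("ACGT"))))
    return "".join(out)


def simulate_long_reads(
    truth: SimTruth,
    cfg: SimConfig,
    genome: Sequence[SequenceRecord],
) -> tuple[list[SequenceRecord], list[AlignmentRecord], SimTruth]:
    """Full-length transcript reads: subtelomeric prefix + telomeric tract.

    Reads are drawn from expressed regions in proportion to expression;
    each read is the transcript-sense subtelomeric sequence immediately
    upstream of the tract followed by a planted number of TTAGGG units,
    then corrupted by the configured substitution/insertion/deletion
    process. The truth ledger records the planted (pre-error) tract
    length per read. Alignment records carry the genomic source interval
    with primary flags; configured fractions get a supplementary twin or
    a low MAPQ to exercise the long-read filters.
    """
    rng = _rng(cfg, 3)
    lr = cfg.long_reads
    seqs = {g.id: g.sequence for g in genome}
    expressed = [r for r in truth.regions
                 if truth.region_expression[r.region_id] > 0]
    if not expressed:
        return [], [], truth
    weights = np.array([truth.region_expression[r.region_id]
                        for r in expressed], dtype=float)
    weights /= weights.sum()
    reads: list[SequenceRecord] = []
    records: list[AlignmentRecord] = []
    for i in range(lr.count):
        region = expressed[int(rng.choice(len(expressed), p=weights))]
        units = int(rng.integers(lr.min_tract_units, lr.max_tract_units + 1))
        t_lo, t_hi = region.telomeric
        units = min(units, (t_hi - t_lo) // 6)
        sub_lo, sub_hi = region.subtelomeric
        prefix_len = int(rng.integers(lr.subtel_min, lr.subtel_max + 1))
        prefix_len = min(prefix_len, sub_hi - sub_lo)
        seq = seqs[region.seq_id]
        if region.strand == "+":
            prefix = seq[t_lo - prefix_len : t_lo]
            g_start, g_end = t_lo - prefix_len, t_lo + 6 * units
        else:
            prefix = reverse_complement(seq[t_hi : t_hi + prefix_len])
            g_start, g_end = t_hi - 6 * units, t_hi + prefix_len
        clean = prefix + TELOMERE_MOTIF * units
        read_id = f"lr{i:05d}"
        corrupted = _corrupt(clean, lr, rng)
        if not corrupted:
            corrupted = clean
        reads.append(SequenceRecord(read_id, corrupted))
        truth.read_origin[read_id] = region.region_id
        truth.read_tract_len[read_id] = 6 * units
        mapq = lr.mapq
        if rng.random() < lr.low_mapq_frac:
            mapq = 0
        records.append(
            AlignmentRecord(
                read_id=read_id, seq_id=region.seq_id, start=g_start,
                end=g_end, mapq=mapq, reverse_strand=region.strand == "-",
                primary=True,
            )
        )
        if rng.random() < lr.supplementary_frac:
            records.append(
                AlignmentRecord(
                    read_id=read_id, seq_id=region.seq_id, start=g_start,
                    end=g_start + max(60, (g_end - g_start) // 4),
                    mapq=max(1, mapq), reverse_strand=region.strand == "-",
                    primary=False, supplementary=True,
                )
            )
    records.sort(key=lambda r: (r.seq_id, r.start, r.read_id))
    return reads, records, truth


def simulate_cage_tags(
    truth: SimTruth, cfg: SimConfig
) -> list[tuple[str, int, str]]:
    """CAGE tags normally jittered around each expressed region's TSS."""
    rng = _rng(cfg, 4)
    tags: list[tuple[str, int, str]] = []
    for region in truth.regions:
        if truth.region_expression[region.region_id] <= 0:
            continue
        L = truth.seq_lengths[region.seq_id]
        for _ in range(cfg.cage.tags_per_tss):
            pos = int(round(rng.normal(region.tss, cfg.cage.jitter_sd)))
            pos = max(0, min(L - 1, pos))
            tags.append((region.seq_id, pos, region.strand))
    tags.sort()
    return tags


def simulate_coverage(
    truth: SimTruth, cfg: SimConfig, bin_size: int = 30,
    capture_level: float = 30.0, base_level: float = 1.0,
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack]]:
    """Capture and control coverage tracks implied by the planted truth.

    Control is flat at ``base_level``; capture adds ``capture_level``
    (scaled by relative expression) over every expressed region span --
    for distal-TSS regions only over the first 2 kb downstream of the
    distal TSS, so the distal and proximal enrichment runs stay separate.
    Deterministic: noise-free by design, so enrichment calls on simulated
    data are exact.
    """
    capture: dict[str, CoverageTrack] = {}
    control: dict[str, CoverageTrack] = {}
    max_expr = max(truth.region_expression.values(), default=1.0) or 1.0
    for seq_id, L in truth.seq_lengths.items():
        n_bins = math.ceil(L / bin_size)
        cap = np.full(n_bins, base_level)
        ctl = np.full(n_bins, base_level)
        for region in truth.regions:
            if region.seq_id != seq_id:
                continue
            expr = truth.region_expression[region.region_id]
            if expr <= 0:
                continue
            lo, hi = region.start, region.end
            if region.tss_rank == "distal":
                if region.strand == "+":
                    lo, hi = region.tss, min(region.tss + 2_000, region.end)
                else:
                    lo, hi = max(region.tss - 2_000, region.start), region.tss
            b_lo, b_hi = lo // bin_size, math.ceil(hi / bin_size)
            cap[b_lo:b_hi] += capture_level * (0.25 + 0.75 * expr / max_expr)
        capture[seq_id] = CoverageTrack(seq_id, L, cap, bin_size, "RPKM")
        control[seq_id] = CoverageTrack(seq_id, L, ctl, bin_size, "RPKM")
    return capture, control


def split_polya_fractions(
    records: Sequence[AlignmentRecord], truth: SimTruth, cfg: SimConfig
) -> tuple[list[AlignmentRecord], list[AlignmentRecord], SimTruth]:
    """Assign each fragment to the poly(A)+ or poly(A)- fraction.

    A fragment from a region goes to the plus fraction with that region's
    configured polyadenylation probability; background fragments split
    evenly. Assignment is per read id, so both mates travel together and
    totals are conserved.
    """
    rng = _rng(cfg, 5)
    assignment: dict[str, str] = {}
    for read_id in sorted({r.read_id for r in records}):
        origin = truth.read_origin.get(read_id, "background")
        p = truth.polya_prob.get(origin, 0.5)
        assignment[read_id] = "+" if rng.random() < p else "-"
        truth.read_polya[read_id] = assignment[read_id]
    plus = [r for r in records if assignment[r.read_id] == "+"]
    minus = [r for r in records if assignment[r.read_id] == "-"]
    return plus, minus, truth
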