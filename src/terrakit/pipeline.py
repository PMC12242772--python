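"""End-to-end pipeline: scan -> elements -> annotate -> count (-> polya).

The pipeline consumes a genome FASTA, coordinate-sorted short-read SAM,
element consensus FASTA and optional evidence files (capture/control
bedGraphs, CAGE tag BED, long-read 5' end BED, poly(A)+/- SAMs), and
writes tract/array/region BED+GTF, count tables and a resolved-config
provenance record into one run directory. Reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from terrakit import io as tio
from terrakit.annotate import (
    call_terra_regions,
    classify_region,
    cluster_cage_tags,
    export_regions_bed,
    export_regions_gtf,
    log2_enrichment,
)
from terrakit.promoter_elements import find_element_arrays, promoter_signature
from terrakit.quantify import count_reads, polya_enrichment, total_terra
from terrakit.repeatscan import classify_tracts, find_repeat_tracts

logger = logging.getLogger("terrakit")

_PROMOTER_WINDOW = 3_000  # bp upstream of the TSS searched for elements


@dataclass
class PipelineConfig:
    """Fully resolved pipeline parameters; unknown keys are rejected."""

    fasta: str
    consensus_fasta: str
    sam: str | None = None
    capture_bedgraph: str | None = None
    control_bedgraph: str | None = None
    cage_bed: str | None = None
    fiveprime_bed: str | None = None
    polya_plus_sam: str | None = None
    polya_minus_sam: str | None = None
    motif: str = "TTAGGG"
    min_tract: int = 200
    max_gap: int = 24
    min_purity: float = 0.8
    end_window: int = 100_000
    min_identity: float = 0.8
    min_copies: int = 2
    enr_threshold: float = 1.0
    min_evidence: int = 2
    pseudocount: float = 1.0
    bin_size: int = 30
    mode: str = "total"
    library_layout: str = "paired"
    strandedness: str = "none"
    cpm_threshold: float = 1.0
    window_frac: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the pipeline; returns the run directory."""
    from terrakit import __version__

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    genome = tio.read_fasta(cfg.fasta)
    seq_lengths = {g.id: len(g) for g in genome}

    # 1. telomeric tracts
    tracts = []
    for g in genome:
        found = find_repeat_tracts(
            g, motif=cfg.motif, min_tract=cfg.min_tract,
            max_gap=cfg.max_gap, min_purity=cfg.min_purity,
        )
        tracts.extend(classify_tracts(found, len(g), cfg.end_window))
    tio.write_bed(tio.tracts_to_bed(tracts), out / "tracts.bed")
    logger.info("found %d telomeric tracts", len(tracts))

    # 2. promoter element arrays
    consensuses = tio.read_consensus_fasta(cfg.consensus_fasta, cfg.min_identity)
    arrays = []
    for g in genome:
        for cons in consensuses:
            arrays.extend(find_element_arrays(g, cons, min_copies=cfg.min_copies))
    tio.write_bed(tio.arrays_to_bed(arrays), out / "element_arrays.bed")

    # 3. region calling and classification
    enrichment = None
    if cfg.capture_bedgraph and cfg.control_bedgraph:
        capture = tio.read_bedgraph(cfg.capture_bedgraph, cfg.bin_size)
        control = tio.read_bedgraph(cfg.control_bedgraph, cfg.bin_size)
        enrichment = {
            sid: log2_enrichment(capture[sid], control[sid], cfg.pseudocount)
            for sid in capture
            if sid in control
        }
    cage = cluster_cage_tags(tio.read_tags_bed(cfg.cage_bed)) if cfg.cage_bed else []
    fiveprime = tio.read_tags_bed(cfg.fiveprime_bed) if cfg.fiveprime_bed else []
    regions = call_terra_regions(
        tracts, enrichment, fiveprime, cage, seq_lengths=seq_lengths,
        end_window=cfg.end_window, enr_threshold=cfg.enr_threshold,
        min_evidence=cfg.min_evidence,
    )
    for region in regions:
        if region.strand == "+":
            promoter = (max(0, region.tss - _PROMOTER_WINDOW), region.tss)
        else:
            promoter = (region.tss, region.tss + _PROMOTER_WINDOW)
        sig = promoter_signature(
            promoter, [a for a in arrays if a.seq_id == region.seq_id]
        )
        classify_region(region, sig)
    (out / "regions.bed").write_text(export_regions_bed(regions))
    (out / "regions.gtf").write_text(export_regions_gtf(regions))
    logger.info("called %d TERRA regions", len(regions))

    # 4. counting
    if cfg.sam:
        alignments = tio.read_sam(cfg.sam)
        counts = count_reads(
            alignments, regions, mode=cfg.mode,
            library_layout=cfg.library_layout,
            strandedness=cfg.strandedness, sample="sample",
        )
        tio.write_count_matrix(counts, out / f"counts_{cfg.mode}.tsv")
        if cfg.mode == "total":
            totals = total_terra(counts)
            totals.rename("total_terra").to_csv(out / "total_terra.tsv", sep="\t")

    # 5. poly(A) partitioning
    if cfg.polya_plus_sam and cfg.polya_minus_sam:
        plus = count_reads(tio.read_sam(cfg.polya_plus_sam), regions,
                           mode="capture", sample="plus")
        minus = count_reads(tio.read_sam(cfg.polya_minus_sam), regions,
                            mode="capture", sample="minus")
        results = polya_enrichment(plus, minus)
        with open(out / "polya.tsv", "w") as fh:
            fh.write("region_id\tfrac_plus\tfrac_minus\tlog2_ratio\tdefined\n")
            for r in results:
                fh.write(
                    f"{r.region_id}\t{r.frac_plus:.6g}\t{r.frac_minus:.6g}\t"
                    f"{r.log2_ratio:.6g}\t{r.defined}\n"
                )

    # provenance: resolved config + input checksums
    inputs = {
        name: {"path": p, "sha256": _checksum(p)}
        for name, p in (
            ("fasta", cfg.fasta), ("consensus_fasta", cfg.consensus_fasta),
            ("sam", cfg.sam), ("capture_bedgraph", cfg.capture_bedgraph),
            ("control_bedgraph", cfg.control_bedgraph),
            ("cage_bed", cfg.cage_bed), ("fiveprime_bed", cfg.fiveprime_bed),
            ("polya_plus_sam", cfg.polya_plus_sam),
            ("polya_minus_sam", cfg.polya_minus_sam),
        )
        if p
    }
    provenance = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": inputs,
    }
    (out / "run_config.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")
    return out
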