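"""End-to-end orchestration: demo fixture bundles and the staged pipeline.

The pipeline mirrors the bench workflow: photograph the plate in both
channels and phenotype it; pick colonies in raster order, tag each with a
forward × reverse barcode pair and pool for sequencing; demultiplex and
genotype the reads; join the two views on the colony index and reduce to
part strengths and relative units.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotyping import (MIN_QUERY_COV, MIN_READS, MIN_SCORE1, MIN_SCORE2,
                         ConstructCaller, build_references, genotype_sample,
                         write_genotypes_tsv)
from .imaging import (DetectParams, detect_colonies, match_colonies, read_image,
                      read_phenotypes_tsv, write_phenotypes_tsv)
from .parts import PartLibrary, random_part_library
from .quantify import (join_colonies, measure_standard, part_strength,
                       write_strengths_tsv)
from .simulate import (PlateParams, ReadSimConfig, place_colonies, render_plate,
                       simulate_tagged_reads, write_fastq, write_png,
                       write_truth_tsv)
from .tags import (FORWARD, REVERSE, demultiplex, design_tags, enumerate_pairs,
                   read_tags_tsv, write_tags_tsv)

#: constant primer-binding context flanking every construct (skipped by the
#: demultiplexer, part of the alignment references)
DEFAULT_FLANK5 = "GATTACCGCCTTTGAGTG"
DEFAULT_FLANK3 = "CACTCGACCGGAATTATC"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults are the method's thresholds."""

    gfp_image: str = ""
    rfp_image: str = ""
    reads: str = ""
    parts_dir: str = ""
    fwd_tags: str = ""
    rev_tags: str = ""
    outdir: str = "out"
    standard_promoter: str = "P1"
    standard_rbs: str = "R1"
    # detection
    min_size: int = 30
    max_dist_px: float = 10.0
    # demultiplexing
    max_edit: int = 1
    binding_len: int = 18
    # genotyping QC
    min_query_cov: float = MIN_QUERY_COV
    min_reads: int = MIN_READS
    min_score1: float = MIN_SCORE1
    min_score2: float = MIN_SCORE2
    # quantification
    min_colonies: int = 3
    strain: str = "DH5a"
    seed: int = 0

    def validate(self) -> None:
        for label, path in (("gfp_image", self.gfp_image), ("rfp_image", self.rfp_image),
                            ("reads", self.reads), ("parts_dir", self.parts_dir),
                            ("fwd_tags", self.fwd_tags), ("rev_tags", self.rev_tags)):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"config field {label!r}: missing path {path!r}")
        for label, v in (("min_query_cov", self.min_query_cov),
                         ("min_score1", self.min_score1),
                         ("min_score2", self.min_score2)):
            if not 0 <= v <= 1:
                raise ValueError(f"{label} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def make_demo(outdir: str | Path, seed: int = 0, n_promoters: int = 4,
              n_rbs: int = 3, colonies_per_combo: int = 3,
              reads_per_colony: int = 30,
              image_size: tuple[int, int] = (640, 640)) -> Path:
    """Write a small, coherent synthetic dataset plus its run config.

    The bundle holds plate images, pooled reads, part FASTAs, tag TSVs and
    truth tables; colonies realize every promoter×RBS combination with the
    standard partner so the quantify stage has something to measure.  Tag
    pairs are assigned to colonies in (y, x) raster order — the order in
    which a researcher picking from the photograph would index them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    parts = random_part_library(n_promoters=n_promoters, n_rbs=n_rbs, seed=seed)
    manifest = parts.to_fasta(outdir / "parts")
    refs = build_references(parts, DEFAULT_FLANK5, DEFAULT_FLANK3)

    # programmed strengths: standard parts score 1.0 by construction
    prom_ids = parts.ids("promoter")
    rbs_ids = parts.ids("rbs")
    prom_strength = {p: 1.0 if i == 0 else float(rng.uniform(0.15, 2.5))
                     for i, p in enumerate(prom_ids)}
    rbs_strength = {r: 1.0 if i == 0 else float(rng.uniform(0.15, 2.5))
                    for i, r in enumerate(rbs_ids)}

    combos = ([ (p, rbs_ids[0]) for p in prom_ids ]
              + [ (prom_ids[0], r) for r in rbs_ids[1:] ])
    combos = combos * colonies_per_combo
    from .parts import PartCombination
    genotypes = [PartCombination(promoter_id=p, rbs_id=r, terminator_id="T1")
                 for p, r in combos]
    base_gfp, base_rfp = 70.0, 110.0
    gfp_levels = [min(235.0, base_gfp * prom_strength[g.promoter_id]
                      * rbs_strength[g.rbs_id]) for g in genotypes]
    rfp_levels = [base_rfp * float(rng.uniform(0.9, 1.1)) for _ in genotypes]

    plate = PlateParams()
    truth = place_colonies(len(genotypes), image_size, plate, rng,
                           gfp_levels=gfp_levels, rfp_levels=rfp_levels,
                           genotypes=genotypes)
    gfp_img, rfp_img = render_plate(truth, image_size, plate,
                                    seed=int(rng.integers(2**31)))
    write_png(gfp_img, outdir / "plate_gfp.png")
    write_png(rfp_img, outdir / "plate_rfp.png")

    flanks = [DEFAULT_FLANK5, DEFAULT_FLANK3]
    fwd = design_tags(8, orientation=FORWARD, seed=seed, avoid_context=flanks)
    rev = design_tags(12, orientation=REVERSE, seed=seed + 1,
                      existing=[t.sequence for t in fwd], avoid_context=flanks)
    write_tags_tsv(fwd, outdir / "fwd_tags.tsv")
    write_tags_tsv(rev, outdir / "rev_tags.tsv")
    pairs = enumerate_pairs(fwd, rev)

    # picking order = raster order of the plate
    order = sorted(truth, key=lambda c: (c.center_xy[1], c.center_xy[0]))
    pair_of = {c.colony_id: pairs[i] for i, c in enumerate(order)}
    specs = [(i, c.genotype, pair_of[c.colony_id])
             for i, c in enumerate(order)]
    reads = simulate_tagged_reads(
        specs, refs, ReadSimConfig(reads_per_colony=reads_per_colony,
                                   seed=int(rng.integers(2**31))))
    write_fastq(reads, outdir / "reads.fastq")
    write_truth_tsv(truth, {c.colony_id: pair_of[c.colony_id] for c in truth},
                    outdir / "truth_colonies.tsv")
    pd.DataFrame([
        {"part_id": p, "part_type": "promoter", "true_strength": s}
        for p, s in prom_strength.items()
    ] + [
        {"part_id": r, "part_type": "RBS", "true_strength": s}
        for r, s in rbs_strength.items()
    ]).to_csv(outdir / "truth_strengths.tsv", sep="\t", index=False)

    config = RunConfig(
        gfp_image=str(outdir / "plate_gfp.png"),
        rfp_image=str(outdir / "plate_rfp.png"),
        reads=str(outdir / "reads.fastq"),
        parts_dir=str(outdir / "parts"),
        fwd_tags=str(outdir / "fwd_tags.tsv"),
        rev_tags=str(outdir / "rev_tags.tsv"),
        outdir=str(outdir / "results"),
        standard_promoter=prom_ids[0],
        standard_rbs=rbs_ids[0],
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return outdir / "config.yaml"


def run_pipeline(config: RunConfig) -> RunReport:
    """Phenotype → demultiplex → genotype → quantify, with a run log."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # ---- phenotype
    gfp_img = read_image(config.gfp_image)
    rfp_img = read_image(config.rfp_image)
    params = DetectParams(min_size=config.min_size)
    gfp_recs = detect_colonies(gfp_img, "GFP", params)
    rfp_recs = detect_colonies(rfp_img, "RFP", params)
    matched, un_g, un_r = match_colonies(gfp_recs, rfp_recs, config.max_dist_px)
    pheno_path = outdir / "phenotypes.tsv"
    write_phenotypes_tsv(matched, pheno_path)
    report.counts.update(
        colonies_gfp=len(gfp_recs), colonies_rfp=len(rfp_recs),
        colonies_matched=len(matched),
        colonies_unmatched=len(un_g) + len(un_r))

    # ---- demultiplex
    from Bio import SeqIO
    fwd = read_tags_tsv(config.fwd_tags)
    rev = read_tags_tsv(config.rev_tags)
    pairs = enumerate_pairs(fwd, rev)
    reads = list(SeqIO.parse(config.reads, "fastq"))
    bins, unassigned = demultiplex(reads, pairs, max_edit=config.max_edit,
                                   binding_len=config.binding_len)
    n_assigned = sum(b.n_reads for b in bins)
    report.counts.update(reads_total=len(reads), reads_assigned=n_assigned,
                         reads_unassigned=len(unassigned))

    # ---- genotype
    slot_paths = {p.stem: p for p in sorted(Path(config.parts_dir).glob("*.fasta"))}
    parts = PartLibrary.from_fasta(slot_paths)
    refs = build_references(parts, DEFAULT_FLANK5, DEFAULT_FLANK3)
    caller = ConstructCaller(refs, min_query_cov=config.min_query_cov)
    genotypes = []
    for b in bins:
        if not b.n_reads:
            continue
        calls = [caller.call(a.read_id, a.trimmed_seq) for a in b.assignments]
        genotypes.append(genotype_sample(
            b, calls, min_reads=config.min_reads, min_score1=config.min_score1,
            min_score2=config.min_score2))
    geno_path = outdir / "genotypes.tsv"
    write_genotypes_tsv(genotypes, geno_path)
    report.counts.update(bins_with_reads=len(genotypes),
                         bins_qc_pass=sum(g.qc_pass for g in genotypes))

    # ---- quantify
    from .genotyping import genotypes_to_frame
    from .imaging import matched_to_frame
    joined, orphans = join_colonies(matched_to_frame(matched),
                                    genotypes_to_frame(genotypes))
    standard = measure_standard(joined, config.standard_promoter,
                                config.standard_rbs, config.min_colonies)
    strengths, dropped = part_strength(joined, standard, strain=config.strain,
                                       min_colonies=config.min_colonies)
    strengths_path = outdir / "part_strengths.tsv"
    write_strengths_tsv(strengths, strengths_path)
    report.counts.update(colonies_joined=len(joined),
                         parts_quantified=len(strengths),
                         parts_dropped=len(dropped))

    report.outputs = {
        "phenotypes": str(pheno_path),
        "genotypes": str(geno_path),
        "part_strengths": str(strengths_path),
    }
    log = {
        "partchar_version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "input_digests": {
            k: _digest(getattr(config, k))
            for k in ("gfp_image", "rfp_image", "reads", "fwd_tags", "rev_tags")
        },
        "counts": report.counts,
        "outputs": report.outputs,
        "standard_intensity": standard.standard_intensity,
        "dropped_groups": dropped,
        "orphans": {k: [int(i) for i in v] for k, v in orphans.items()},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return report
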