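"""Genotype calling for demultiplexed long reads.

Every possible assembled construct (the cartesian product of the part
slots) becomes a reference sequence; each read is aligned against all of
them on both strands and called to the best one, provided at least 95% of
the read participates in the alignment (query coverage).  Per colony bin,
two purity statistics gate the genotype call:

    score1 = primary mapped read count / total read count
    score2 = (primary − second mapped read count) / primary

where *primary* is the read count of the best-supported reference within
the bin and *second* that of the runner-up.  A bin passes QC when
total > 15, score1 > 0.4 and score2 > 0.65.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .parts import SLOT_ORDER, PartCombination, PartLibrary, revcomp
from .tags import DemuxBin

#: QC thresholds (strict inequalities)
MIN_READS = 15
MIN_SCORE1 = 0.4
MIN_SCORE2 = 0.65
MIN_QUERY_COV = 0.95


@dataclass
class ReferenceSet:
    """All assembled constructs reachable from a part library."""

    parts: PartLibrary
    flank5: str = ""
    flank3: str = ""
    constructs: dict[PartCombination, str] = field(default_factory=dict)

    def sequence(self, combo: PartCombination) -> str:
        return self.constructs[combo]


def build_references(parts: PartLibrary, flank5: str = "", flank3: str = "") -> ReferenceSet:
    """Enumerate every slot combination as an assembled reference sequence.

    Flanks are the constant backbone/primer-binding context shared by all
    constructs (they make trimmed reads align end to end).
    """
    combos = parts.combinations()
    constructs = {c: flank5.upper() + parts.assemble(c) + flank3.upper() for c in combos}
    return ReferenceSet(parts=parts, flank5=flank5.upper(), flank3=flank3.upper(),
                        constructs=constructs)


@dataclass
class ReadCall:
    read_id: str
    best_construct: PartCombination
    best_score: float           # affine local alignment score
    edit_distance: int          # glocal edit distance to the best construct
    strand: str                 # "+"/"-"
    query_coverage: float       # aligned query span / read length
    passed: bool
    ambiguous: bool = False


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


class ConstructCaller:
    """Aligns reads against every construct and emits ReadCalls.

    Candidate ranking uses fast glocal edit distance; the affine local
    aligner (match +2, mismatch −3, gap open −5, extend −2) then scores the
    top-ranked candidates, decides ties and yields the query coverage.
    In `circular` mode (plasmid library profiling, reads may start
    anywhere) each reference is doubled before alignment.
    """

    def __init__(self, refs: ReferenceSet, min_query_cov: float = MIN_QUERY_COV,
                 circular: bool = False):
        self.refs = refs
        self.min_query_cov = min_query_cov
        self.aligner = _make_aligner()
        self.combos = sorted(refs.constructs)
        self.targets = []
        for combo in self.combos:
            seq = refs.constructs[combo]
            if circular:
                seq = seq + seq
            self.targets.append((combo, seq, revcomp(seq)))

    def call(self, read_id: str, seq: str) -> ReadCall:
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty read {read_id!r}")
        # rank all constructs/strands by glocal (query-global) edit distance
        ranked = []
        for combo, fwd, rev in self.targets:
            for strand, target in (("+", fwd), ("-", rev)):
                d = edlib.align(seq, target, mode="HW", task="distance")["editDistance"]
                ranked.append((d, combo, strand, target))
        ranked.sort(key=lambda r: (r[0], r[1], r[2]))
        best_d = ranked[0][0]
        finalists = [r for r in ranked if r[0] == best_d]

        best = None
        for d, combo, strand, target in finalists:
            score = self.aligner.score(target, seq)
            if best is None or score > best[0]:
                best = (score, combo, strand, target, d, False)
            elif score == best[0] and combo != best[1]:
                # equal score on a different construct: keep the lower id, flag it
                best = (best[0], best[1], best[2], best[3], best[4], True)
        score, combo, strand, target, d, ambiguous = best

        alignment = self.aligner.align(target, seq)[0]
        qblocks = alignment.aligned[1]
        if len(qblocks):
            span = int(qblocks[-1][1] - qblocks[0][0])
        else:
            span = 0
        coverage = span / len(seq)
        return ReadCall(
            read_id=read_id,
            best_construct=combo,
            best_score=float(score),
            edit_distance=int(d),
            strand=strand,
            query_coverage=coverage,
            passed=coverage >= self.min_query_cov,
            ambiguous=ambiguous,
        )


def call_read(read: tuple[str, str], refs: ReferenceSet,
              min_query_cov: float = MIN_QUERY_COV, circular: bool = False) -> ReadCall:
    """Call a single (read_id, sequence); see ConstructCaller for batches."""
    return ConstructCaller(refs, min_query_cov, circular).call(read[0], read[1])


@dataclass
class SampleGenotype:
    """Per-colony genotype call with the bin-purity QC statistics."""

    colony_index: int
    total_reads: int
    primary_count: int
    second_count: int
    genotype: PartCombination | None
    score1: float
    score2: float
    qc_pass: bool


def genotype_sample(bin: DemuxBin, calls: list[ReadCall],
                    min_reads: int = MIN_READS, min_score1: float = MIN_SCORE1,
                    min_score2: float = MIN_SCORE2,
                    count_failed_in_total: bool = True) -> SampleGenotype:
    """Call the genotype of one colony bin from its reads' construct calls.

    `total_reads` counts every read in the bin, including coverage-failed
    ones (so score1 reflects mapping success as well as purity); set
    `count_failed_in_total=False` to restrict the denominator to passed
    reads.  The genotype is the construct with the most passed reads; a bin
    with no passed reads gets genotype None and fails QC.
    """
    passed = [c for c in calls if c.passed]
    total = bin.n_reads if count_failed_in_total else len(passed)
    tally = Counter(c.best_construct for c in passed)
    if tally:
        ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        genotype, primary = ordered[0]
        second = ordered[1][1] if len(ordered) > 1 else 0
    else:
        genotype, primary, second = None, 0, 0
    score1 = primary / total if total else 0.0
    score2 = (primary - second) / primary if primary else 0.0
    qc = (total > min_reads) and (score1 > min_score1) and (score2 > min_score2) \
        and genotype is not None
    return SampleGenotype(
        colony_index=bin.pair.colony_index,
        total_reads=total,
        primary_count=primary,
        second_count=second,
        genotype=genotype,
        score1=score1,
        score2=score2,
        qc_pass=qc,
    )


@dataclass
class LibraryProfile:
    combination_counts: dict[PartCombination, int]
    combination_ratios: dict[PartCombination, float]
    slot_marginals: dict[str, dict[str, float]]
    comparison: pd.DataFrame | None = None
    spearman_rho: float | None = None
    spearman_p: float | None = None


def profile_library(calls: list[ReadCall],
                    input_ratios: dict[str, dict[str, float]] | None = None) -> LibraryProfile:
    """Genotype distribution of a pooled assembly library.

    With `input_ratios` (per-slot molar ratios of the parts fed into the
    assembly reaction) the profile also carries a combination-level
    comparison table and a Spearman rank correlation between input ratio
    and measured ratio — the assembly-fidelity readout.
    """
    passed = [c for c in calls if c.passed]
    if not passed:
        raise ValueError("no coverage-passing calls to profile")
    counts = Counter(c.best_construct for c in passed)
    n = sum(counts.values())
    ratios = {c: k / n for c, k in counts.items()}
    marginals: dict[str, dict[str, float]] = {}
    for slot in SLOT_ORDER:
        m: Counter = Counter()
        for combo, k in counts.items():
            m[combo.part_id(slot)] += k
        marginals[slot] = {pid: k / n for pid, k in sorted(m.items())}

    comparison = None
    rho = pval = None
    if input_ratios is not None:
        norm = {
            slot: {pid: v / sum(r.values()) for pid, v in r.items()}
            for slot, r in input_ratios.items()
        }
        rows = []
        for combo in sorted(ratios):
            expected = 1.0
            for slot, slot_ratios in norm.items():
                expected *= slot_ratios[combo.part_id(slot)]
            rows.append((combo.label, expected, ratios[combo]))
        comparison = pd.DataFrame(rows, columns=["combination", "input_ratio", "measured_ratio"])
        rho, pval = stats.spearmanr(comparison["input_ratio"], comparison["measured_ratio"])
        rho, pval = float(rho), float(pval)
    return LibraryProfile(
        combination_counts=dict(counts),
        combination_ratios=ratios,
        slot_marginals=marginals,
        comparison=comparison,
        spearman_rho=rho,
        spearman_p=pval,
    )


# -------------------------------------------------------------------- I/O

def genotypes_to_frame(genotypes: list[SampleGenotype]) -> pd.DataFrame:
    rows = []
    for g in genotypes:
        rows.append({
            "colony_index": g.colony_index,
            "promoter": g.genotype.promoter_id if g.genotype else "",
            "rbs": g.genotype.rbs_id if g.genotype else "",
            "terminator": g.genotype.terminator_id if g.genotype else "",
            "total_reads": g.total_reads,
            "primary_count": g.primary_count,
            "second_count": g.second_count,
            "score1": g.score1,
            "score2": g.score2,
            "qc_pass": g.qc_pass,
        })
    return pd.DataFrame(rows)


def write_genotypes_tsv(genotypes: list[SampleGenotype], path) -> None:
    genotypes_to_frame(genotypes).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
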