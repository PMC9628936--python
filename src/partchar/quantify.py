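"""Part strengths and relative units (RPU / RRU).

Phenotypes (colony intensities) and genotypes (QC-passing part calls)
join on the colony index.  A part's strength is characterized in the
standard circuit context: promoters are measured from colonies carrying
the standard RBS, RBSs from colonies carrying the standard promoter.
The mean colony intensity of each part (its RFU) is divided by the
standard circuit's own mean intensity to give the relative promoter unit
(RPU) or relative RBS unit (RRU):

    RPU or RRU = mean part colony fluorescence / standard circuit fluorescence

so the standard circuit itself scores exactly 1.0, and any common
exposure or gain factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats


@dataclass
class StandardReference:
    """The standard characterization circuit's identity and baseline."""

    standard_promoter_id: str = "J23119"
    standard_rbs_id: str = "B0030"
    standard_intensity: float = 1.0
    n_colonies: int = 0


@dataclass
class PartStrength:
    part_id: str
    part_type: str               # "promoter" | "RBS"
    strain: str
    n_colonies: int
    mean_intensity: float        # the part RFU
    sd_intensity: float
    relative_unit: float         # RPU or RRU


def join_colonies(phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Inner-join phenotype and genotype tables on colony_index.

    Only QC-passing genotypes and unflagged (e.g. non-saturated)
    phenotypes enter the join; everything else lands in the orphan
    report.  Duplicate colony indices on either side are an error — the
    index is the physical identity of a picked colony.
    """
    for name, df in (("phenotypes", phenotypes), ("genotypes", genotypes)):
        if df["colony_index"].duplicated().any():
            dupes = df.loc[df["colony_index"].duplicated(), "colony_index"].tolist()
            raise ValueError(f"duplicate colony_index in {name}: {dupes}")
    pheno = phenotypes.copy()
    if "flags" not in pheno.columns:
        pheno["flags"] = ""
    pheno["flags"] = pheno["flags"].fillna("")
    pheno_ok = pheno[pheno["flags"] == ""]
    geno_ok = genotypes[genotypes["qc_pass"].astype(bool)]
    joined = pheno_ok.merge(geno_ok, on="colony_index", how="inner",
                            suffixes=("_pheno", "_geno"))
    joined_ids = set(joined["colony_index"])
    orphans = {
        "pheno_unjoined": sorted(set(pheno_ok["colony_index"]) - joined_ids),
        "pheno_flagged": sorted(pheno.loc[pheno["flags"] != "", "colony_index"]),
        "geno_unjoined": sorted(set(geno_ok["colony_index"]) - joined_ids),
        "geno_qc_failed": sorted(genotypes.loc[~genotypes["qc_pass"].astype(bool),
                                               "colony_index"]),
    }
    return joined, orphans


def relative_unit(mean_intensity: float, standard: StandardReference,
                  convention: str = "ratio") -> float:
    """Relative unit of a part against the standard circuit.

    The default is the simple ratio to the standard baseline (the
    convention under which the standard circuit itself scores 1.0).  The
    subtractive variant ``convention="typeset"`` — mean / (standard −
    mean) — is retained only for auditability; it diverges as the part
    approaches the standard and is not used anywhere in the pipeline.
    """
    if standard.standard_intensity <= 0:
        raise ValueError(f"standard intensity must be positive, "
                         f"got {standard.standard_intensity}")
    if convention == "ratio":
        return mean_intensity / standard.standard_intensity
    if convention == "typeset":
        denom = standard.standard_intensity - mean_intensity
        if denom == 0:
            raise ZeroDivisionError("typeset convention diverges when the part "
                                    "equals the standard")
        return mean_intensity / denom
    raise ValueError(f"unknown convention {convention!r}")


def measure_standard(joined: pd.DataFrame, standard_promoter_id: str,
                     standard_rbs_id: str, min_colonies: int = 3) -> StandardReference:
    """Baseline intensity from the standard circuit's own colonies."""
    mask = ((joined["promoter"] == standard_promoter_id)
            & (joined["rbs"] == standard_rbs_id))
    values = joined.loc[mask, "colony_intensity"]
    if len(values) < min_colonies:
        raise ValueError(
            f"standard circuit {standard_promoter_id}-{standard_rbs_id} has only "
            f"{len(values)} QC-passing colonies; need >= {min_colonies}")
    return StandardReference(standard_promoter_id=standard_promoter_id,
                             standard_rbs_id=standard_rbs_id,
                             standard_intensity=float(values.mean()),
                             n_colonies=int(len(values)))


def part_strength(joined: pd.DataFrame, standard: StandardReference,
                  strain: str = "", min_colonies: int = 3,
                  convention: str = "ratio",
                  ) -> tuple[list[PartStrength], list[tuple[str, str, int]]]:
    """Aggregate colony intensities into per-part strengths.

    Promoters are grouped over colonies with the standard RBS, RBSs over
    colonies with the standard promoter.  Groups with fewer than
    `min_colonies` colonies are dropped and reported as
    (part_id, part_type, n).  Means are plain unweighted means of colony
    intensity; sd is the sample standard deviation (ddof=1).
    """
    if joined.empty:
        raise ValueError("joined table is empty; nothing to aggregate")
    strengths: list[PartStrength] = []
    dropped: list[tuple[str, str, int]] = []
    groups = [
        ("promoter", "promoter", joined[joined["rbs"] == standard.standard_rbs_id]),
        ("RBS", "rbs", joined[joined["promoter"] == standard.standard_promoter_id]),
    ]
    for part_type, column, subset in groups:
        for part_id, grp in subset.groupby(column, sort=True):
            # the standard circuit belongs to both groups; report it once, as a promoter
            if (part_type == "RBS" and part_id == standard.standard_rbs_id):
                continue
            n = len(grp)
            if n < min_colonies:
                dropped.append((str(part_id), part_type, n))
                continue
            mean = float(grp["colony_intensity"].mean())
            sd = float(grp["colony_intensity"].std(ddof=1)) if n > 1 else 0.0
            strengths.append(PartStrength(
                part_id=str(part_id), part_type=part_type, strain=strain,
                n_colonies=n, mean_intensity=mean, sd_intensity=sd,
                relative_unit=relative_unit(mean, standard, convention)))
    return strengths, dropped


def strain_comparison(strengths: list[PartStrength],
                      min_shared: int = 3) -> dict:
    """Part-by-strain matrix of relative units plus pairwise rank concordance.

    Relative units are scale-free within each strain, so rank correlation
    is the right cross-strain comparison: a strain-specific gain factor
    leaves it untouched.
    """
    strains = sorted({s.strain for s in strengths})
    if len(strains) < 2:
        raise ValueError(f"need >= 2 strains, got {strains}")
    frame = pd.DataFrame([{
        "part_id": s.part_id, "part_type": s.part_type, "strain": s.strain,
        "relative_unit": s.relative_unit,
    } for s in strengths])
    matrix = frame.pivot_table(index=["part_type", "part_id"], columns="strain",
                               values="relative_unit")
    rows = []
    for a, b in combinations(strains, 2):
        shared = matrix[[a, b]].dropna()
        if len(shared) < min_shared:
            raise ValueError(f"strains {a!r} and {b!r} share only {len(shared)} parts; "
                             f"need >= {min_shared}")
        rho, pval = stats.spearmanr(shared[a], shared[b])
        rows.append({"strain_a": a, "strain_b": b, "n_shared": len(shared),
                     "spearman_rho": float(rho), "spearman_p": float(pval)})
    return {"matrix": matrix, "concordance": pd.DataFrame(rows)}


# -------------------------------------------------------------------- I/O

def strengths_to_frame(strengths: list[PartStrength]) -> pd.DataFrame:
    return pd.DataFrame([{
        "part_id": s.part_id,
        "part_type": s.part_type,
        "strain": s.strain,
        "n_colonies": s.n_colonies,
        "mean_RFU": s.mean_intensity,
        "sd": s.sd_intensity,
        "RPU_or_RRU": s.relative_unit,
    } for s in strengths])


def write_strengths_tsv(strengths: list[PartStrength], path) -> None:
    strengths_to_frame(strengths).to_csv(path, sep="\t", index=False)
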