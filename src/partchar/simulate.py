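"""Synthetic plates and tagged long reads with known ground truth.

Every downstream stage of the pipeline is exercised offline against
fixtures from this module: dual-channel plate photographs of roughly
circular colonies with configurable noise, combinatorial assembly draws
following input molar ratios, and tagged amplicon reads corrupted by a
substitution/insertion/deletion error model emulating nanopore basecalls.
All randomness flows through explicit seeds; there is no global state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import ReferenceSet
from .parts import BASES, PartCombination, revcomp
from .tags import TagPair


@dataclass(frozen=True)
class TruthColony:
    colony_id: int
    center_xy: tuple[float, float]   # (x, y), 0-based, origin top-left
    radius_px: float
    true_gfp_level: float            # arbitrary fluorescence units, 8-bit scale
    true_rfp_level: float
    genotype: PartCombination | None = None


@dataclass
class PlateParams:
    """Rendering and placement parameters for a synthetic plate.

    Colonies are flat discs at the set level with a Gaussian edge skirt
    falling off *outside* the nominal radius, so the disc mean equals the
    level exactly before noise and 8-bit quantization.  Levels live on the
    8-bit channel scale; a level that would clip at 255 raises a warning.
    """

    radius_range: tuple[float, float] = (6.0, 14.0)
    gfp_range: tuple[float, float] = (40.0, 200.0)
    rfp_range: tuple[float, float] = (60.0, 160.0)
    background: float = 8.0
    noise_sigma: float = 3.0
    edge_sigma: float = 2.0
    min_gap: float = 4.0             # clearance beyond touching, px
    max_place_attempts: int = 2000


class ClippingWarning(UserWarning):
    pass


def place_colonies(n_colonies: int, image_size: tuple[int, int],
                   params: PlateParams, rng: np.random.Generator,
                   gfp_levels=None, rfp_levels=None, genotypes=None,
                   ) -> list[TruthColony]:
    """Rejection-sample non-overlapping colony positions.

    Optional per-colony level/genotype arrays override the random draws
    (used when the plate must realize programmed part strengths).
    """
    h, w = image_size
    r_lo, r_hi = params.radius_range
    margin = r_hi + 3 * params.edge_sigma
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError(f"image {image_size} too small for colonies of radius up to {r_hi}")
    placed: list[TruthColony] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    attempts = 0
    for i in range(n_colonies):
        r = rng.uniform(r_lo, r_hi)
        while True:
            attempts += 1
            if attempts > params.max_place_attempts:
                density = sum(np.pi * rr**2 for rr in radii) / (h * w)
                raise RuntimeError(
                    f"could not place colony {i + 1}/{n_colonies} after "
                    f"{params.max_place_attempts} attempts; packed density {density:.2f} — "
                    "use a larger image, fewer colonies or smaller radii")
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if len(centers):
                d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
                if np.any(d <= radii + r + params.min_gap):
                    continue
            break
        gfp = float(gfp_levels[i]) if gfp_levels is not None \
            else rng.uniform(*params.gfp_range)
        rfp = float(rfp_levels[i]) if rfp_levels is not None \
            else rng.uniform(*params.rfp_range)
        geno = genotypes[i] if genotypes is not None else None
        placed.append(TruthColony(colony_id=i, center_xy=(x, y), radius_px=r,
                                  true_gfp_level=gfp, true_rfp_level=rfp, genotype=geno))
        centers = np.vstack([centers, [x, y]])
        radii = np.append(radii, r)
    return placed


def _render_plane(truth: list[TruthColony], shape: tuple[int, int],
                  levels: list[float], params: PlateParams) -> np.ndarray:
    plane = np.zeros(shape, dtype=float)
    for colony, level in zip(truth, levels):
        x, y = colony.center_xy
        r = colony.radius_px
        reach = int(np.ceil(r + 4 * params.edge_sigma))
        y0, y1 = max(0, int(y) - reach), min(shape[0], int(y) + reach + 1)
        x0, x1 = max(0, int(x) - reach), min(shape[1], int(x) + reach + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - x, yy - y)
        profile = np.where(
            d <= r, 1.0, np.exp(-((d - r) ** 2) / (2 * params.edge_sigma**2)))
        plane[y0:y1, x0:x1] += level * profile
    return plane


def render_plate(truth: list[TruthColony], image_size: tuple[int, int],
                 params: PlateParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render the GFP and RFP channel photographs of a truth table.

    The GFP image carries signal in its green plane, the RFP image in its
    red plane; both get the same flat background plus i.i.d. Gaussian
    noise in every plane, then clip to 8 bits.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    top = max([params.background]
              + [c.true_gfp_level + params.background for c in truth]
              + [c.true_rfp_level + params.background for c in truth])
    if top > 255:
        warnings.warn(
            f"requested level {top - params.background:.0f} + background clips at 255; "
            "rendered intensities will saturate", ClippingWarning, stacklevel=2)
    gfp_plane = _render_plane(truth, image_size, [c.true_gfp_level for c in truth], params)
    rfp_plane = _render_plane(truth, image_size, [c.true_rfp_level for c in truth], params)
    images = []
    for signal_plane, plane_idx in ((gfp_plane, 1), (rfp_plane, 0)):
        img = np.full((h, w, 3), params.background, dtype=float)
        img[:, :, plane_idx] += signal_plane
        if params.noise_sigma > 0:
            img += rng.normal(0.0, params.noise_sigma, size=img.shape)
        images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return images[0], images[1]


def simulate_plate(n_colonies: int, image_size: tuple[int, int] = (768, 768),
                   truth_params: PlateParams | None = None, seed: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray, list[TruthColony]]:
    """Place and render a plate; returns (gfp_image, rfp_image, truth)."""
    params = truth_params or PlateParams()
    rng = np.random.default_rng(seed)
    truth = place_colonies(n_colonies, image_size, params, rng)
    render_seed = int(rng.integers(2**31))
    gfp_img, rfp_img = render_plate(truth, image_size, params, render_seed)
    return gfp_img, rfp_img, truth


def simulate_assembly(part_molar_ratios: dict[str, dict[str, float]],
                      n_constructs: int, seed: int = 0) -> list[PartCombination]:
    """Draw construct genotypes slot-independently by input molar ratio.

    Emulates one-pot combinatorial assembly, where each slot's part is
    incorporated with probability proportional to its molar ratio in the
    reaction — the regime in which measured combination frequencies track
    the input ratios.
    """
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for slot in ("promoter", "rbs", "cds", "terminator"):
        ratios = part_molar_ratios.get(slot)
        if slot == "cds" and not ratios:
            ratios = {"sfGFP": 1.0}
        if not ratios:
            raise ValueError(f"no parts declared for slot {slot!r}")
        if any(v <= 0 for v in ratios.values()):
            raise ValueError(f"molar ratios must be positive in slot {slot!r}")
        ids = sorted(ratios)
        p = np.array([ratios[i] for i in ids], dtype=float)
        p /= p.sum()
        draws[slot] = np.array(ids)[rng.choice(len(ids), size=n_constructs, p=p)]
    return [
        PartCombination(promoter_id=draws["promoter"][k], rbs_id=draws["rbs"][k],
                        cds_id=draws["cds"][k], terminator_id=draws["terminator"][k])
        for k in range(n_constructs)
    ]


@dataclass
class ReadSimConfig:
    """Per-base error model and depth for simulated nanopore reads."""

    substitution_rate: float = 0.05
    insertion_rate: float = 0.015
    deletion_rate: float = 0.015
    reads_per_colony: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not (0 <= r < 1) for r in rates):
            raise ValueError("error rates must be in [0, 1)")
        if sum(rates) >= 1:
            raise ValueError("error rates must sum to < 1")
        if self.reads_per_colony < 1:
            raise ValueError("reads_per_colony must be positive")


_BASE_IDX = {b: i for i, b in enumerate(BASES)}


def mutate_sequence(seq: str, rng: np.random.Generator, sub: float,
                    ins: float, dele: float) -> str:
    """Apply i.i.d. per-base substitution/insertion/deletion errors.

    A substitution always changes the base (drawn from the three others);
    insertions append a uniform random base after the current position.
    """
    out: list[str] = []
    u = rng.random(len(seq))
    for base, r in zip(seq, u):
        if r < dele:
            pass
        elif r < dele + sub:
            out.append(BASES[(_BASE_IDX[base] + 1 + rng.integers(3)) % 4])
        else:
            out.append(base)
        if rng.random() < ins:
            out.append(BASES[rng.integers(4)])
    return "".join(out)


def make_read_id(n: int, colony_id: int, pair: TagPair, combo: PartCombination) -> str:
    return (f"read{n:06d}|colony={colony_id}|fwd={pair.fwd.tag_id}|rev={pair.rev.tag_id}"
            f"|promoter={combo.promoter_id}|rbs={combo.rbs_id}"
            f"|terminator={combo.terminator_id}")


def parse_read_id(read_id: str) -> dict[str, str]:
    """Recover the ground truth encoded in a simulated read id."""
    fields = dict(part.split("=", 1) for part in read_id.split("|")[1:])
    return fields


def simulate_tagged_reads(colonies: list[tuple[int, PartCombination, TagPair]],
                          references: ReferenceSet,
                          config: ReadSimConfig) -> list[SeqRecord]:
    """Simulate tagged colony-PCR amplicon reads for a pool of colonies.

    Each template is fwd_tag + construct (binding sites live in the
    construct flanks) + revcomp(rev_tag); per-base errors follow the
    config rates and roughly half the reads are emitted on the reverse
    strand, as on a real flow cell.  Read ids encode the ground truth so
    tests can audit any downstream assignment.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SeqRecord] = []
    n = 0
    for colony_id, combo, pair in colonies:
        if combo not in references.constructs:
            raise KeyError(f"colony {colony_id}: combination {combo.label!r} "
                           "not in the reference set")
        template = (pair.fwd.sequence + references.constructs[combo]
                    + revcomp(pair.rev.sequence))
        for _ in range(config.reads_per_colony):
            seq = mutate_sequence(template, rng, config.substitution_rate,
                                  config.insertion_rate, config.deletion_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            rec = SeqRecord(Seq(seq), id=make_read_id(n, colony_id, pair, combo),
                            description="")
            rec.letter_annotations["phred_quality"] = [12] * len(seq)
            records.append(rec)
            n += 1
    return records


# -------------------------------------------------------------------- I/O

def write_fastq(records: list[SeqRecord], path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_png(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(path, image)


def write_truth_tsv(truth: list[TruthColony],
                    pairs: dict[int, TagPair] | None, path: str | Path) -> None:
    rows = []
    for c in truth:
        pair = pairs.get(c.colony_id) if pairs else None
        rows.append({
            "colony_id": c.colony_id,
            "x": c.center_xy[0],
            "y": c.center_xy[1],
            "radius": c.radius_px,
            "gfp": c.true_gfp_level,
            "rfp": c.true_rfp_level,
            "promoter": c.genotype.promoter_id if c.genotype else "",
            "rbs": c.genotype.rbs_id if c.genotype else "",
            "fwd_tag": pair.fwd.tag_id if pair else "",
            "rev_tag": pair.rev.tag_id if pair else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
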