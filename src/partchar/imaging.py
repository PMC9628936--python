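"""Colony detection, two-channel linking and colony intensity.

The phenotyping input is a pair of RGB plate photographs of the same
plate: one exposed for GFP (signal in the green plane) and one for RFP
(red plane).  Colonies are segmented per channel, quantified, linked
across the two images by position, and scored with the ratiometric
colony intensity

    colony_intensity = (mean green × green size) / (mean red × red size)

i.e. integrated GFP over integrated RFP, the RFP module acting as an
internal growth control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.segmentation import watershed
from skimage.transform import resize

GFP = "GFP"
RFP = "RFP"

#: RGB plane driving segmentation per channel
CHANNEL_PLANE = {GFP: 1, RFP: 0}


@dataclass
class DetectParams:
    """Segmentation recipe knobs.

    The background is a large-kernel median estimate (computed on a
    downscaled copy for speed), the threshold a robust noise floor
    (median + `noise_k` scaled MADs of the smoothed residual) or Otsu,
    touching colonies are split by distance-transform watershed, and
    candidate regions must pass size and circularity filters.
    """

    min_size: int = 30               # px
    min_circularity: float = 0.6     # 4πA/P²
    threshold: str = "mad"           # "mad" | "otsu"
    noise_k: float = 5.0
    smooth_sigma: float = 1.0
    bg_kernel_px: int = 64
    bg_downscale: int = 4
    peak_min_distance: int = 8
    saturation_level: int = 254
    max_saturation_frac: float = 0.05
    use_sum: bool = False            # report summed instead of mean channel value


@dataclass
class ColonyRecord:
    record_id: int
    channel: str
    center_xy: tuple[float, float]   # (x=column, y=row), 0-based, origin top-left
    size_px: int
    mean_channel_value: float
    saturated_frac: float = 0.0

    @property
    def flagged_saturated(self) -> bool:
        return self.saturated_frac > 0.05


@dataclass
class MatchedColony:
    """A GFP- and an RFP-channel detection of the same physical colony."""

    colony_index: int
    gfp: ColonyRecord
    rfp: ColonyRecord
    total_gfp: float
    total_rfp: float
    colony_intensity: float
    match_distance: float = 0.0
    flags: list[str] = field(default_factory=list)


class SaturationWarning(UserWarning):
    pass


def _estimate_background(plane: np.ndarray, params: DetectParams) -> np.ndarray:
    """Large-kernel median background, computed at reduced resolution."""
    ds = params.bg_downscale
    small = plane[::ds, ::ds]
    size = max(3, params.bg_kernel_px // ds)
    bg_small = ndimage.median_filter(small, size=size)
    return resize(bg_small, plane.shape, order=1, mode="edge", anti_aliasing=False)


def detect_colonies(image: np.ndarray, channel: str,
                    params: DetectParams | None = None) -> list[ColonyRecord]:
    """Segment one channel image into colony records.

    Returns records sorted by (y, x) centroid; a blank image yields an
    empty list.  When more than `max_saturation_frac` of all foreground
    pixels sit at the top of the bit range a SaturationWarning is issued;
    per-region saturation is carried on each record.
    """
    if params is None:
        params = DetectParams()
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    if channel not in CHANNEL_PLANE:
        raise ValueError(f"channel must be one of {list(CHANNEL_PLANE)}")
    raw = image[:, :, CHANNEL_PLANE[channel]].astype(float)
    if np.ptp(raw) < 2:  # flat image: nothing to segment
        return []
    bg = _estimate_background(raw, params)
    sub = np.clip(raw - bg, 0, None)
    smooth = ndimage.gaussian_filter(sub, params.smooth_sigma)

    if params.threshold == "otsu":
        thr = threshold_otsu(smooth)
    else:
        med = np.median(smooth)
        mad = np.median(np.abs(smooth - med))
        thr = med + params.noise_k * 1.4826 * mad
    thr = max(thr, 2.0)
    mask = smooth > thr
    if not mask.any():
        return []

    # declump touching colonies on the distance transform
    dist = ndimage.distance_transform_edt(mask)
    dist_s = ndimage.gaussian_filter(dist, 1.0)
    peaks = peak_local_max(dist_s, min_distance=params.peak_min_distance,
                           labels=mask, exclude_border=False)
    if len(peaks) == 0:
        labels = sk_label(mask)
    else:
        markers = np.zeros_like(dist, dtype=int)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist_s, markers, mask=mask)

    records: list[ColonyRecord] = []
    sat = raw >= params.saturation_level
    for prop in regionprops(labels, intensity_image=sub):
        if prop.area < params.min_size:
            continue
        perimeter = prop.perimeter
        if perimeter > 0:
            circularity = 4 * np.pi * prop.area / perimeter**2
            if circularity < params.min_circularity:
                continue
        value = prop.image_intensity.sum() if params.use_sum else prop.intensity_mean
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        records.append(ColonyRecord(
            record_id=0,
            channel=channel,
            center_xy=(float(prop.centroid[1]), float(prop.centroid[0])),
            size_px=int(prop.area),
            mean_channel_value=float(value),
            saturated_frac=float(sat[rr, cc].mean()),
        ))
    records.sort(key=lambda r: (r.center_xy[1], r.center_xy[0]))
    for i, rec in enumerate(records):
        rec.record_id = i
    fg_area = sum(r.size_px for r in records)
    fg_sat = sum(r.saturated_frac * r.size_px for r in records)
    if fg_area and fg_sat / fg_area > params.max_saturation_frac:
        warnings.warn(
            f"{channel}: {100 * fg_sat / fg_area:.1f}% of colony pixels are saturated; "
            "quantification may be distorted", SaturationWarning, stacklevel=2)
    return records


def colony_intensity(total_gfp: float, total_rfp: float, colony: object = "") -> float:
    """Integrated-GFP / integrated-RFP ratio of one colony."""
    if total_rfp <= 0:
        raise ZeroDivisionError(
            f"colony {colony!r}: total RFP signal is {total_rfp}; cannot normalize")
    return total_gfp / total_rfp


def match_colonies(gfp_records: list[ColonyRecord], rfp_records: list[ColonyRecord],
                   max_dist_px: float = 10.0,
                   ) -> tuple[list[MatchedColony], list[ColonyRecord], list[ColonyRecord]]:
    """Link the two channels' detections by mutual nearest neighbour.

    A GFP and an RFP record pair up iff each is the other's nearest
    neighbour and their centroids lie within `max_dist_px`; pairs are
    confirmed greedily by increasing distance (then lower record id) so no
    record is used twice.  Returns (matched, unmatched_gfp, unmatched_rfp).
    """
    if not gfp_records or not rfp_records:
        return [], list(gfp_records), list(rfp_records)
    g_xy = np.array([r.center_xy for r in gfp_records])
    r_xy = np.array([r.center_xy for r in rfp_records])
    g_tree, r_tree = cKDTree(g_xy), cKDTree(r_xy)
    d_g, nn_of_g = r_tree.query(g_xy)
    d_r, nn_of_r = g_tree.query(r_xy)

    candidates = []
    for gi, (ri, d) in enumerate(zip(nn_of_g, d_g)):
        if d <= max_dist_px and nn_of_r[ri] == gi:
            candidates.append((float(d), gi, int(ri)))
    candidates.sort(key=lambda c: (c[0], gfp_records[c[1]].record_id))

    matched: list[MatchedColony] = []
    used_g: set[int] = set()
    used_r: set[int] = set()
    for d, gi, ri in candidates:
        if gi in used_g or ri in used_r:
            continue
        used_g.add(gi)
        used_r.add(ri)
        g, r = gfp_records[gi], rfp_records[ri]
        total_g = g.mean_channel_value * g.size_px
        total_r = r.mean_channel_value * r.size_px
        flags = []
        if g.flagged_saturated or r.flagged_saturated:
            flags.append("saturated")
        matched.append(MatchedColony(
            colony_index=0,
            gfp=g,
            rfp=r,
            total_gfp=total_g,
            total_rfp=total_r,
            colony_intensity=colony_intensity(total_g, total_r, colony=g.record_id),
            match_distance=d,
            flags=flags,
        ))
    matched.sort(key=lambda m: (m.gfp.center_xy[1], m.gfp.center_xy[0]))
    for i, m in enumerate(matched):
        m.colony_index = i
    unmatched_g = [r for i, r in enumerate(gfp_records) if i not in used_g]
    unmatched_r = [r for i, r in enumerate(rfp_records) if i not in used_r]
    return matched, unmatched_g, unmatched_r


def size_bias_report(matched: list[MatchedColony]) -> dict:
    """Diagnostic: does colony size drive the quantified intensity?

    Returns the per-colony (size, intensity) table and their Spearman rank
    correlation; with constant sizes the correlation is undefined and
    reported as NaN.  Purely diagnostic — nothing is thresholded.
    """
    if len(matched) < 3:
        raise ValueError(f"size bias report needs >= 3 matched colonies, got {len(matched)}")
    table = pd.DataFrame({
        "colony_index": [m.colony_index for m in matched],
        "size_px": [m.gfp.size_px for m in matched],
        "colony_intensity": [m.colony_intensity for m in matched],
    })
    if table["size_px"].nunique() == 1 or table["colony_intensity"].nunique() == 1:
        rho, pval = float("nan"), float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, pval = stats.spearmanr(table["size_px"], table["colony_intensity"])
            rho, pval = float(rho), float(pval)
    return {"table": table, "spearman_rho": rho, "spearman_p": pval}


# -------------------------------------------------------------------- I/O

def read_image(path: str | Path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 2:
        raise ValueError(f"{path}: expected an RGB image, got a single plane")
    return img[:, :, :3]


def matched_to_frame(matched: list[MatchedColony]) -> pd.DataFrame:
    rows = []
    for m in matched:
        rows.append({
            "colony_index": m.colony_index,
            "x": m.gfp.center_xy[0],
            "y": m.gfp.center_xy[1],
            "size_gfp": m.gfp.size_px,
            "size_rfp": m.rfp.size_px,
            "mean_g": m.gfp.mean_channel_value,
            "mean_r": m.rfp.mean_channel_value,
            "total_gfp": m.total_gfp,
            "total_rfp": m.total_rfp,
            "colony_intensity": m.colony_intensity,
            "flags": ";".join(m.flags),
        })
    return pd.DataFrame(rows)


def write_phenotypes_tsv(matched: list[MatchedColony], path: str | Path) -> None:
    matched_to_frame(matched).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["flags"] = df["flags"].fillna("")
    return df
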