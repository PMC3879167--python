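"""Per-colony quantification of plate images.

Pipeline for one image: fit a rigid pin grid to axis-projection profiles of
the value channel, segment each grid cell into colony / agar on the value
channel, estimate the local agar background from the cell's border annulus,
and score colony redness in HSV space.

The redness of a pixel with hue ``h`` (degrees) and saturation ``s`` is

    w = s * exp(-d(h, h_ref)^2 / (2 * sigma_h^2))

with circular hue distance ``d`` and reference hue ``h_ref = 0`` (the red
reaction product).  The colony score ``C`` is the background-corrected sum
of ``w`` over the colony mask plus (by default) its halo annulus:
zero-calibrated on white colonies, extensive, and strictly increasing in
pigment at fixed geometry.  Scores are reported in arbitrary "units" and are
conventionally displayed on a log10 axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import color as skcolor
from skimage.filters import threshold_otsu

from chromopin.plate import PlateImage, PlateLayout, provenance_digest


#: Background redness is corrected with an envelope of the agar redness
#: distribution: mean + BG_ENVELOPE_K * sd over the border-annulus pixels.
#: Zero for noiseless images; suppresses sensor-noise chroma otherwise.
BG_ENVELOPE_K = 2.0


class GridFitError(RuntimeError):
    """Grid fitting failed; carries the projection profile for diagnosis."""

    def __init__(self, message: str, profile: np.ndarray | None = None):
        super().__init__(message)
        self.profile = profile


@dataclass
class GridFit:
    """A rigid row/column grid: per-line center coordinates plus a global
    rotation (degrees) and the RMS residual of the per-line peak refinement
    against the ideal evenly spaced comb."""

    row_centers: np.ndarray
    col_centers: np.ndarray
    rotation: float = 0.0
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.row_centers = np.asarray(self.row_centers, dtype=float)
        self.col_centers = np.asarray(self.col_centers, dtype=float)
        for name, c in (("row", self.row_centers), ("col", self.col_centers)):
            if len(c) > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"{name}_centers must be strictly increasing")
        if abs(self.rotation) > 5.0:
            raise ValueError("|rotation| > 5 degrees: grid fit failure")

    @property
    def row_spacing(self) -> float:
        return float(np.median(np.diff(self.row_centers))) \
            if len(self.row_centers) > 1 else 0.0

    @property
    def col_spacing(self) -> float:
        return float(np.median(np.diff(self.col_centers))) \
            if len(self.col_centers) > 1 else 0.0


@dataclass
class QuantConfig:
    """Tunable quantification parameters (pixels, degrees)."""

    min_area: int = 12
    include_halo: bool = True
    halo_width_factor: float = 0.5   # halo annulus width as fraction of pin spacing
    h_ref: float = 0.0               # reference hue of the red product
    sigma_h: float = 20.0            # hue kernel width
    border_annulus_px: int = 3       # cell border frame used for background
    plate_normalize: bool = False    # divide scores by the plate median score
    max_rotation: float = 2.0        # rotation search half-range
    rotation_step: float = 1.0

    def digest(self) -> str:
        return provenance_digest(asdict(self))


def value_channel(pixels: np.ndarray) -> np.ndarray:
    """HSV value channel (max of RGB), float in [0, 1]."""
    return pixels.astype(float).max(axis=2) / 255.0


def _pixels_of(image: PlateImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, PlateImage) else np.asarray(image)


# ---------------------------------------------------------------------------
# grid fitting


def _projection_profile(dev: np.ndarray, axis: int) -> np.ndarray:
    p = dev.mean(axis=axis)
    return ndimage.gaussian_filter1d(np.maximum(p, 0.0), 2.0)


def _estimate_spacing(profile: np.ndarray, n: int) -> float:
    """Pin spacing from the autocorrelation of the projection profile."""
    p = profile - profile.mean()
    ac = np.correlate(p, p, mode="full")[len(p) - 1:]
    lo = max(4, int(0.5 * len(p) / n))
    hi = min(len(ac) - 1, int(1.25 * len(p) / max(n - 1, 1)))
    if hi <= lo:
        raise GridFitError("profile too short to estimate pin spacing", profile)
    lag = lo + int(np.argmax(ac[lo:hi + 1]))
    peaks, _ = find_peaks(profile, distance=max(3, int(0.6 * lag)))
    if len(peaks) >= max(3, n // 2):
        lag = float(np.median(np.diff(peaks)))
    return float(lag)


def _comb_fit(profile: np.ndarray, n: int) -> tuple[np.ndarray, float]:
    """Fit ``n`` evenly spaced line centers maximizing profile mass.

    Returns (refined per-line centers, RMS residual against the comb).
    """
    length = len(profile)
    s0 = _estimate_spacing(profile, n)
    xs = np.arange(length, dtype=float)
    best = (-np.inf, None, None)
    for s in np.linspace(0.92 * s0, 1.08 * s0, 33):
        if s * (n - 1) >= length:
            continue
        offsets = np.arange(0.0, length - s * (n - 1), 0.5)
        if len(offsets) == 0:
            continue
        pos = offsets[:, None] + s * np.arange(n)[None, :]
        scores = np.interp(pos.ravel(), xs, profile).reshape(pos.shape).sum(axis=1)
        i = int(np.argmax(scores))
        if scores[i] > best[0]:
            best = (float(scores[i]), float(offsets[i]), float(s))
    if best[1] is None:
        raise GridFitError(
            f"could not place {n} grid lines on a profile of length {length}",
            profile)
    o, s = best[1], best[2]
    comb = o + s * np.arange(n)
    # sub-pixel refinement: centroid of the positive profile near each line
    half = max(2, int(0.4 * s))
    refined = np.empty(n)
    for k, c in enumerate(comb):
        a, b = max(0, int(c) - half), min(length, int(c) + half + 1)
        w = profile[a:b]
        refined[k] = (np.arange(a, b) * w).sum() / w.sum() if w.sum() > 0 else c
    if not np.all(np.diff(refined) > 0):
        raise GridFitError("refined grid line centers are not monotone", profile)
    residual = float(np.sqrt(np.mean((refined - comb) ** 2)))
    return refined, residual


def _profile_sharpness(dev: np.ndarray) -> float:
    return float(_projection_profile(dev, 1).var() + _projection_profile(dev, 0).var())


def fit_grid(image: PlateImage | np.ndarray, rows: int, cols: int,
             config: QuantConfig | None = None) -> GridFit:
    """Fit the pin grid of a colony-array image.

    Works on the background-subtracted value channel: colonies project as
    periodic peaks onto each axis.  A small-angle rotation search maximizes
    projection sharpness before the per-axis comb fit.
    """
    if config is None:
        config = QuantConfig()
    pixels = _pixels_of(image)
    v = value_channel(pixels)
    bg = ndimage.gaussian_filter(v, sigma=min(v.shape) / 16.0)
    dev = np.maximum(v - bg, 0.0)

    rotation = 0.0
    if config.max_rotation > 0 and config.rotation_step > 0:
        angles = np.arange(-config.max_rotation, config.max_rotation + 1e-9,
                           config.rotation_step)
        if len(angles) > 1 and not np.allclose(angles, 0.0):
            small = dev[::2, ::2]
            sharp = [_profile_sharpness(
                ndimage.rotate(small, a, reshape=False, order=1))
                for a in angles]
            rotation = float(angles[int(np.argmax(sharp))])
    if rotation != 0.0:
        dev = ndimage.rotate(dev, rotation, reshape=False, order=1)

    col_centers, res_c = _comb_fit(_projection_profile(dev, 0), cols)
    row_centers, res_r = _comb_fit(_projection_profile(dev, 1), rows)
    return GridFit(row_centers=row_centers, col_centers=col_centers,
                   rotation=rotation,
                   residual=float(np.hypot(res_r, res_c) / math.sqrt(2)))


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class CellSegmentation:
    """Segmentation result for one grid cell.

    ``mask``/``halo`` are boolean arrays over the cell bounding box
    ``bbox = (y0, y1, x0, x1)`` in image coordinates.  ``background`` is the
    per-channel median agar colour (floats in [0, 1]) from the cell's border
    annulus.
    """

    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    halo: np.ndarray
    background: np.ndarray
    empty: bool
    area: int
    centroid: tuple[float, float]  # (x, y) in image coordinates
    #: raw border-annulus pixel colours (N, 3); feeds the background
    #: redness envelope used for score correction
    background_pixels: np.ndarray = None


def _cell_bbox(grid: GridFit, row: int, col: int,
               shape: tuple[int, int]) -> tuple[int, int, int, int]:
    cy = grid.row_centers[row]
    cx = grid.col_centers[col]
    hy = grid.row_spacing / 2 if grid.row_spacing else shape[0] / 2
    hx = grid.col_spacing / 2 if grid.col_spacing else shape[1] / 2
    y0, y1 = int(round(cy - hy)), int(round(cy + hy))
    x0, x1 = int(round(cx - hx)), int(round(cx + hx))
    return (max(0, y0), min(shape[0], y1), max(0, x0), min(shape[1], x1))


def segment_colony(image: PlateImage | np.ndarray, grid: GridFit,
                   row: int, col: int,
                   config: QuantConfig | None = None) -> CellSegmentation:
    """Segment the colony in one grid cell and estimate its local background.

    Foreground = pixels whose value-channel deviation from the border-annulus
    background exceeds an Otsu-derived split; the connected component at the
    cell center is kept.  Cells whose component is smaller than ``min_area``
    are flagged empty.  Degenerate cells never raise; they come back empty.
    """
    if config is None:
        config = QuantConfig()
    pixels = _pixels_of(image)
    y0, y1, x0, x1 = _cell_bbox(grid, row, col, pixels.shape[:2])
    cell = pixels[y0:y1, x0:x1].astype(float) / 255.0
    h, w = cell.shape[:2]

    b = config.border_annulus_px
    border = np.zeros((h, w), dtype=bool)
    border[:b, :] = border[-b:, :] = True
    border[:, :b] = border[:, -b:] = True
    bg_pixels = cell[border] if border.any() else cell.reshape(-1, 3)
    background = np.median(bg_pixels, axis=0)

    v = cell.max(axis=2)
    dev = v - background.max()
    empty = CellSegmentation(bbox=(y0, y1, x0, x1),
                             mask=np.zeros((h, w), bool),
                             halo=np.zeros((h, w), bool),
                             background=background, empty=True, area=0,
                             centroid=(float(grid.col_centers[col]),
                                       float(grid.row_centers[row])),
                             background_pixels=bg_pixels)
    if h < 3 or w < 3 or dev.max() <= 0.02:
        return empty
    try:
        thr = threshold_otsu(dev)
    except ValueError:
        return empty
    fg = dev > max(thr, 0.02)
    labels, nlab = ndimage.label(fg)
    if nlab == 0:
        return empty
    # component containing (or nearest) the cell center
    cy, cx = h // 2, w // 2
    lab = labels[cy, cx]
    if lab == 0:
        yy, xx = np.nonzero(fg)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        near = d2 <= (0.25 * max(h, w)) ** 2
        if not near.any():
            return empty
        lab = np.bincount(labels[yy[near], xx[near]]).argmax()
        if lab == 0:
            return empty
    mask = labels == lab
    area = int(mask.sum())
    if area < config.min_area:
        return empty
    yy, xx = np.nonzero(mask)
    centroid = (x0 + float(xx.mean()), y0 + float(yy.mean()))

    # halo annulus: agar pixels of the cell within halo_width of the rim
    spacing = max(grid.row_spacing, grid.col_spacing, 1.0)
    rim = math.sqrt(area / math.pi)
    reach = rim + config.halo_width_factor * spacing
    gy, gx = np.mgrid[0:h, 0:w]
    d = np.hypot(gx - (centroid[0] - x0), gy - (centroid[1] - y0))
    halo = (~ndimage.binary_dilation(mask)) & (d <= reach)
    return CellSegmentation(bbox=(y0, y1, x0, x1), mask=mask, halo=halo,
                            background=background, empty=False, area=area,
                            centroid=centroid, background_pixels=bg_pixels)


# ---------------------------------------------------------------------------
# colour measurement


def circular_hue_distance(h: np.ndarray | float, h_ref: float) -> np.ndarray:
    """Shortest angular distance between hues, degrees in [0, 180]."""
    d = np.abs(np.asarray(h, dtype=float) - h_ref) % 360.0
    return np.minimum(d, 360.0 - d)


def redness_weights(hue_deg: np.ndarray, sat: np.ndarray,
                    h_ref: float = 0.0, sigma_h: float = 20.0) -> np.ndarray:
    """Per-pixel redness: saturation weighted by a Gaussian hue kernel."""
    d = circular_hue_distance(hue_deg, h_ref)
    return np.asarray(sat, dtype=float) * np.exp(-d ** 2 / (2.0 * sigma_h ** 2))


def _background_redness(background: np.ndarray, h_ref: float,
                        sigma_h: float) -> float:
    """Redness level attributable to the agar background.

    ``background`` is either one RGB triple (its redness is returned) or an
    (N, 3) array of agar pixel colours, in which case a robust upper
    envelope mean + BG_ENVELOPE_K * sd of their per-pixel redness is used so
    that sensor-noise chroma does not accumulate into colony scores.
    """
    arr = np.asarray(background, dtype=float)
    hsv = skcolor.rgb2hsv(arr.reshape(-1, 1, 3)).reshape(-1, 3)
    w = redness_weights(hsv[:, 0] * 360.0, hsv[:, 1], h_ref, sigma_h)
    if arr.ndim <= 1 or len(w) == 1:
        return float(w[0])
    return float(w.mean() + BG_ENVELOPE_K * w.std())


def annulus_redness_stats(background_pixels: np.ndarray, h_ref: float = 0.0,
                          sigma_h: float = 20.0) -> tuple[float, float]:
    """(mean, sd) of per-pixel redness over a set of agar pixels."""
    hsv = skcolor.rgb2hsv(np.asarray(background_pixels, dtype=float)
                          .reshape(-1, 1, 3)).reshape(-1, 3)
    w = redness_weights(hsv[:, 0] * 360.0, hsv[:, 1], h_ref, sigma_h)
    return float(w.mean()), float(w.std())


def measure_color(image: PlateImage | np.ndarray, mask: np.ndarray,
                  halo_annulus: np.ndarray | None,
                  background: Sequence[float],
                  h_ref: float = 0.0, sigma_h: float = 20.0,
                  background_redness: float | None = None,
                  ) -> tuple[float, float, float, float]:
    """HSV colour statistics and background-corrected redness sum.

    ``mask`` and ``halo_annulus`` are boolean arrays over the image (or over
    the same crop of it).  Returns ``(mean_hue, mean_sat, mean_value, R)``
    where ``R = sum over mask+halo of max(0, w - w_bg)`` and ``mean_hue`` is
    the saturation-weighted circular mean over the mask (NaN when the mask
    is achromatic).
    """
    pixels = _pixels_of(image).astype(float) / 255.0
    mask = np.asarray(mask, dtype=bool)
    union = mask if halo_annulus is None else (mask | np.asarray(halo_annulus, bool))
    if not union.any():
        return (float("nan"), 0.0, 0.0, 0.0)
    hsv_union = skcolor.rgb2hsv(pixels[union].reshape(-1, 1, 3)).reshape(-1, 3)
    w = redness_weights(hsv_union[:, 0] * 360.0, hsv_union[:, 1], h_ref, sigma_h)
    w_bg = background_redness if background_redness is not None \
        else _background_redness(background, h_ref, sigma_h)
    redness_sum = float(np.maximum(w - w_bg, 0.0).sum())

    if mask.any():
        hsv_mask = skcolor.rgb2hsv(pixels[mask].reshape(-1, 1, 3)).reshape(-1, 3)
        s, v = hsv_mask[:, 1], hsv_mask[:, 2]
        mean_sat, mean_val = float(s.mean()), float(v.mean())
        chrom = s > 0.02
        if chrom.any():
            ang = np.deg2rad(hsv_mask[chrom, 0] * 360.0)
            ws = s[chrom]
            mean_hue = float(np.rad2deg(math.atan2(
                (ws * np.sin(ang)).sum(), (ws * np.cos(ang)).sum())) % 360.0)
        else:
            mean_hue = float("nan")
    else:
        mean_hue, mean_sat, mean_val = float("nan"), 0.0, 0.0
    return (mean_hue, mean_sat, mean_val, redness_sum)


def plate_background_redness(pixels: np.ndarray, grid: GridFit,
                             h_ref: float = 0.0, sigma_h: float = 20.0,
                             ) -> float | None:
    """Background-redness envelope from the agar frame outside the grid.

    The margin beyond the outermost cells is the one region a colony halo
    can never tint, so its per-pixel redness distribution characterises
    agar plus sensor noise; the envelope is mean + BG_ENVELOPE_K * sd.
    Returns None when the grid leaves no usable frame (< 200 pixels).
    """
    h, w = pixels.shape[:2]
    y_lo = int(grid.row_centers[0] - grid.row_spacing / 2)
    y_hi = int(math.ceil(grid.row_centers[-1] + grid.row_spacing / 2))
    x_lo = int(grid.col_centers[0] - grid.col_spacing / 2)
    x_hi = int(math.ceil(grid.col_centers[-1] + grid.col_spacing / 2))
    frame = np.ones((h, w), dtype=bool)
    frame[max(0, y_lo):min(h, y_hi), max(0, x_lo):min(w, x_hi)] = False
    n = int(frame.sum())
    if n < 200:
        return None
    px = pixels[frame].astype(float) / 255.0
    if n > 20000:  # subsample for speed; deterministic stride
        px = px[:: n // 20000 + 1]
    hsv = skcolor.rgb2hsv(px.reshape(-1, 1, 3)).reshape(-1, 3)
    wgt = redness_weights(hsv[:, 0] * 360.0, hsv[:, 1], h_ref, sigma_h)
    return float(wgt.mean() + BG_ENVELOPE_K * wgt.std())


def cprg_score(redness_sum: float, plate_calibration: float = 1.0) -> float:
    """Colony score: the background-corrected redness sum, optionally
    divided by a per-plate calibration factor."""
    if plate_calibration <= 0:
        raise ValueError("plate_calibration must be > 0")
    return max(0.0, float(redness_sum) / plate_calibration)


def _halo_side_sums(pixels: np.ndarray, seg: CellSegmentation,
                    h_ref: float, sigma_h: float,
                    background_redness: float) -> dict[str, float]:
    """Background-corrected halo redness split into N/S/E/W quadrants.

    The quadrant of a halo pixel is the dominant axis of its offset from the
    colony centroid (y up = North = lower row index).
    """
    sums = {"halo_n": 0.0, "halo_s": 0.0, "halo_e": 0.0, "halo_w": 0.0}
    if seg.empty or not seg.halo.any():
        return sums
    y0, y1, x0, x1 = seg.bbox
    cell = pixels[y0:y1, x0:x1].astype(float) / 255.0
    yy, xx = np.nonzero(seg.halo)
    hsv = skcolor.rgb2hsv(cell[yy, xx].reshape(-1, 1, 3)).reshape(-1, 3)
    w = redness_weights(hsv[:, 0] * 360.0, hsv[:, 1], h_ref, sigma_h)
    w = np.maximum(w - background_redness, 0.0)
    dy = (y0 + yy) - seg.centroid[1]
    dx = (x0 + xx) - seg.centroid[0]
    vertical = np.abs(dy) >= np.abs(dx)
    sums["halo_n"] = float(w[vertical & (dy < 0)].sum())
    sums["halo_s"] = float(w[vertical & (dy >= 0)].sum())
    sums["halo_e"] = float(w[~vertical & (dx >= 0)].sum())
    sums["halo_w"] = float(w[~vertical & (dx < 0)].sum())
    return sums


# ---------------------------------------------------------------------------
# whole-plate quantification


MEASUREMENT_COLUMNS = [
    "plate", "condition", "timepoint", "row", "col", "mutant_id",
    "clone_index", "center_x", "center_y", "area", "mean_hue", "mean_sat",
    "mean_value", "redness", "cprg_score", "size_score",
    "halo_n", "halo_s", "halo_e", "halo_w", "flags",
]


def quantify_plate(image: PlateImage, layout: PlateLayout,
                   config: QuantConfig | None = None,
                   grid: GridFit | None = None) -> pd.DataFrame:
    """Measure every non-empty layout position of one plate image.

    Returns one row per position with area, HSV statistics, redness sum and
    CPRG score (see :data:`MEASUREMENT_COLUMNS`).  Positions whose
    segmentation comes back below ``min_area`` are flagged ``empty`` with
    zero area and score.

    Scores are corrected against a plate-level background-redness envelope
    measured on the agar frame outside the grid (see
    :func:`plate_background_redness`), which colony halos cannot reach; when
    the grid leaves no frame, the median over cells of the border-annulus
    redness statistics is used instead.  Per-cell border medians are still
    used for value-channel segmentation.
    """
    if config is None:
        config = QuantConfig()
    if grid is None:
        grid = fit_grid(image, layout.rows, layout.cols, config)
    pixels = image.pixels
    entries = layout.entries[layout.entries["plate"] == image.plate_id]
    if len(entries) == 0:
        entries = layout.entries

    segs: list[tuple[object, CellSegmentation]] = []
    stats = []
    for e in entries.itertuples():
        if e.is_empty:
            continue
        seg = segment_colony(image, grid, int(e.row), int(e.col), config)
        segs.append((e, seg))
        if seg.background_pixels is not None and len(seg.background_pixels):
            stats.append(annulus_redness_stats(seg.background_pixels,
                                               config.h_ref, config.sigma_h))
    w_bg = plate_background_redness(pixels, grid, config.h_ref, config.sigma_h)
    if w_bg is None:
        if stats:
            means, sds = np.array(stats).T
            w_bg = float(np.median(means) + BG_ENVELOPE_K * np.median(sds))
        else:
            w_bg = 0.0

    records = []
    for e, seg in segs:
        if seg.empty:
            records.append({
                "plate": image.plate_id, "condition": image.condition,
                "timepoint": image.timepoint, "row": int(e.row),
                "col": int(e.col), "mutant_id": e.mutant_id,
                "clone_index": int(e.clone_index),
                "center_x": seg.centroid[0], "center_y": seg.centroid[1],
                "area": 0, "mean_hue": float("nan"), "mean_sat": 0.0,
                "mean_value": 0.0, "redness": 0.0, "cprg_score": 0.0,
                "size_score": 0.0, "halo_n": 0.0, "halo_s": 0.0,
                "halo_e": 0.0, "halo_w": 0.0, "flags": "empty",
            })
            continue
        y0, y1, x0, x1 = seg.bbox
        cell = pixels[y0:y1, x0:x1]
        halo = seg.halo if config.include_halo else None
        mh, ms, mv, R = measure_color(cell, seg.mask, halo, seg.background,
                                      config.h_ref, config.sigma_h,
                                      background_redness=w_bg)
        sides = _halo_side_sums(pixels, seg, config.h_ref, config.sigma_h, w_bg)
        records.append({
            "plate": image.plate_id, "condition": image.condition,
            "timepoint": image.timepoint, "row": int(e.row),
            "col": int(e.col), "mutant_id": e.mutant_id,
            "clone_index": int(e.clone_index),
            "center_x": seg.centroid[0], "center_y": seg.centroid[1],
            "area": seg.area, "mean_hue": mh, "mean_sat": ms,
            "mean_value": mv, "redness": R, "cprg_score": cprg_score(R),
            "size_score": float(seg.area), **sides, "flags": "",
        })
    table = pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)
    if config.plate_normalize and len(table):
        med = float(table.loc[table["area"] > 0, "cprg_score"].median())
        if med > 0:
            table["cprg_score"] = table["cprg_score"] / med
        else:
            warnings.warn("plate median score is 0; skipping normalization",
                          stacklevel=2)
    return table


def flag_neighbor_contamination(measurements: pd.DataFrame,
                                threshold: float,
                                gamma: float = 1.5,
                                floor_fraction: float = 0.05) -> pd.DataFrame:
    """Flag colonies whose redness is halo spill-over from a red neighbor.

    A colony is flagged ``neighbor_contaminated`` when an 8-neighbor scores
    above ``threshold`` (and above the colony's own score: spill flows from
    redder to whiter positions) and the colony's halo redness on the side
    facing that neighbor exceeds ``gamma`` times the opposite side (and an
    absolute floor of ``floor_fraction * threshold``).  A second pass drops
    flags whose only contaminating neighbors were themselves flagged (their
    redness is spill, not product), so contamination does not cascade
    outward from a single red colony.  Operates per plate; returns a copy
    with the ``flags`` column updated.
    """
    out = measurements.copy()
    out["flags"] = out["flags"].fillna("").astype(str)
    floor = floor_fraction * threshold
    side_pairs = {(-1, 0): ("halo_n", "halo_s"), (1, 0): ("halo_s", "halo_n"),
                  (0, 1): ("halo_e", "halo_w"), (0, -1): ("halo_w", "halo_e")}

    for plate, sub in out.groupby("plate"):
        by_pos = {(int(r.row), int(r.col)): r for r in sub.itertuples()}
        hot = {(int(r.row), int(r.col)) for r in sub.itertuples()
               if r.cprg_score > threshold}

        def contaminated(pos: tuple[int, int], sources: set) -> bool:
            r = by_pos[pos]
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    src = (pos[0] + dr, pos[1] + dc)
                    if src not in sources:
                        continue
                    if by_pos[src].cprg_score <= r.cprg_score:
                        continue
                    faces, opps = [], []
                    for d, (fc, oc) in side_pairs.items():
                        if (d[0] and d[0] == np.sign(dr)) or \
                           (d[1] and d[1] == np.sign(dc)):
                            faces.append(getattr(r, fc))
                            opps.append(getattr(r, oc))
                    face, opp = float(np.mean(faces)), float(np.mean(opps))
                    if face > gamma * opp and face > floor:
                        return True
            return False

        flagged = {p for p in by_pos if p in hot and contaminated(p, hot)}
        # second pass: only unflagged hot colonies are genuine sources
        sources = hot - flagged
        flagged = {p for p in by_pos if contaminated(p, sources)}
        for p in flagged:
            i = by_pos[p].Index
            cur = out.at[i, "flags"]
            if "neighbor_contaminated" not in cur:
                out.at[i, "flags"] = (cur + ";" if cur else "") + "neighbor_contaminated"
    return out
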