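"""Synthetic plate-image and screen generator with exact ground truth.

Forward model of a chromogenic indicator-agar screen: colonies are pinned in
a regular grid (384-pin default); most are white, a small fraction hydrolyse
the chromogenic substrate and turn pink to red, surrounded by a halo of
diffused red product whose width grows with incubation time.  Pigment
accumulates linearly in time (redness at time ``t`` equals ``effect_size *
t`` for positive mutants); colony geometry is shared across timepoints so
colour effects are isolated from size effects.

Colour model: a colony with redness ``r`` is rendered at HSV hue 0 deg (the
red reaction product) with saturation ``s = SAT_MAX * (1 - exp(-r))`` —
linear in ``r`` for faint colonies and saturating for deep red ones — on a
near-white colony body.  The halo carries a radially decaying (Gaussian)
fraction of the colony redness into the surrounding agar.

All randomness flows from integer seeds through numpy's splittable
``default_rng``; per-plate substreams are derived from (seed, condition
index, plate index), so identical seeds reproduce images bit for bit.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from chromopin.plate import (
    DEFAULT_CONDITIONS,
    STANDARD_FORMATS,
    PlateImage,
    PlateLayout,
    map_replicates,
    write_image,
)

#: Saturation of a fully developed red colony (sRGB chroma ceiling).
SAT_MAX = 0.95
#: Colony body value (brightness); colonies sit brighter than the agar.
COLONY_VALUE = 0.95
#: Fraction of colony redness carried into the halo at the rim.
HALO_AMP = 0.5

#: Default imaging times in hours: end of vegetative growth (~12 h at 30 C)
#: and after growth plateaus, 7 h later.
DEFAULT_TIMEPOINTS = (12.0, 19.0)

TRUTH_COLUMNS = [
    "plate", "condition", "timepoint", "row", "col", "mutant_id",
    "center_x", "center_y", "grid_x", "grid_y", "radius",
    "redness_true", "size_true", "is_empty",
]


@dataclass
class PlateSpec:
    """Geometry and photometry of a synthetic pinned plate.

    Distances are in pixels, intensities in [0, 1].
    ``halo_diffusion_sigma_per_hour`` sets the Gaussian halo width per hour
    of incubation.
    """

    rows: int = 16
    cols: int = 24
    pin_spacing: float = 30.0
    margin: float = 24.0
    colony_radius_mean: float = 9.0
    colony_radius_sd: float = 1.0
    position_jitter_sd: float = 1.0
    background_level: float = 0.80
    background_gradient: float = 5e-5
    vignette_strength: float = 0.10
    noise_sd: float = 0.01
    halo_diffusion_sigma_per_hour: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.rows * self.cols not in STANDARD_FORMATS:
            warnings.warn(
                f"{self.rows}x{self.cols} = {self.rows * self.cols} positions "
                "is not a standard 96/384/1536 pinned format", stacklevel=2)
        for name in ("colony_radius_sd", "position_jitter_sd", "noise_sd",
                     "halo_diffusion_sigma_per_hour", "colony_radius_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def max_radius(self) -> int:
        return int(math.ceil(self.colony_radius_mean + 3 * self.colony_radius_sd))

    @property
    def image_shape(self) -> tuple[int, int]:
        """(height, width), deterministic from the spec."""
        h = int(round(2 * self.margin + self.pin_spacing * (self.rows - 1)
                      + 2 * self.max_radius))
        w = int(round(2 * self.margin + self.pin_spacing * (self.cols - 1)
                      + 2 * self.max_radius))
        return h, w

    @property
    def origin(self) -> float:
        """Pixel coordinate of the first pin center on each axis."""
        return self.margin + self.max_radius

    def grid_position(self, row: int, col: int) -> tuple[float, float]:
        """Analytic (x, y) center of a pin position."""
        return (self.origin + col * self.pin_spacing,
                self.origin + row * self.pin_spacing)


@dataclass
class ColonyTruth:
    """Ground truth for one grid position.

    ``center`` and ``radius`` may be left ``None`` to be filled in by the
    renderer (jittered grid position, radius drawn around the spec mean).
    ``redness_true`` is the dimensionless pigment level: 0 for white
    colonies.
    """

    row: int
    col: int
    redness_true: float = 0.0
    mutant_id: str = ""
    center: tuple[float, float] | None = None
    radius: float | None = None
    is_empty: bool = False

    def __post_init__(self) -> None:
        if self.redness_true < 0:
            raise ValueError("redness_true must be >= 0")
        if self.is_empty:
            self.radius = 0.0


@dataclass
class ScreenTruth:
    """Planted per-mutant, per-condition truth of a simulated screen.

    ``table`` has columns mutant_id, condition, true_class (CPRG+/CPRG-),
    effect_size (redness accrued per hour; 0 for CPRG-).
    """

    table: pd.DataFrame

    def positives(self, condition: str | None = None) -> set[str]:
        t = self.table[self.table["true_class"] == "CPRG+"]
        if condition is not None:
            t = t[t["condition"] == condition]
        return set(t["mutant_id"])


@dataclass
class GISimSpec:
    """Generative model for double-mutant colony sizes.

    size(gene, rep) = base_size * gene_fitness * interaction
                      * LogNormal_plate * LogNormal_noise
    with mean-one log-normal factors (sd on the log scale), so a neutral
    gene's expected growth score is exactly 1.
    """

    base_size: float = 200.0
    gene_fitness: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    plate_effect_sd: float = 0.2
    noise_sd: float = 0.1
    replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_size <= 0:
            raise ValueError("base_size must be > 0")
        for name in ("gene_fitness", "interaction"):
            bad = {g: m for g, m in getattr(self, name).items() if m <= 0}
            if bad:
                raise ValueError(f"{name} multipliers must be > 0: {bad}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def saturation_from_redness(redness: np.ndarray | float) -> np.ndarray | float:
    """Rendered red saturation as a function of pigment level."""
    return SAT_MAX * -np.expm1(-np.asarray(redness, dtype=float))


def _fill_geometry(spec: PlateSpec, truths: list[ColonyTruth],
                   rng: np.random.Generator) -> list[ColonyTruth]:
    """Fill in jittered centers and drawn radii for truths lacking them.

    Draw order is fixed (sorted by row, col; jitter first, then radius) so a
    given rng state yields identical geometry.
    """
    out = []
    for t in sorted(truths, key=lambda t: (t.row, t.col)):
        if not (0 <= t.row < spec.rows and 0 <= t.col < spec.cols):
            raise ValueError(
                f"truth position (row={t.row}, col={t.col}) outside the "
                f"{spec.rows}x{spec.cols} grid")
        t = replace(t)
        gx, gy = spec.grid_position(t.row, t.col)
        if t.is_empty:
            t.center = (gx, gy)
            t.radius = 0.0
            out.append(t)
            continue
        if t.center is None:
            jx, jy = rng.normal(0.0, spec.position_jitter_sd, size=2)
            t.center = (gx + jx, gy + jy)
        if t.radius is None:
            r = rng.normal(spec.colony_radius_mean, spec.colony_radius_sd)
            t.radius = float(np.clip(r, 2.0, spec.max_radius))
        out.append(t)
    return out


def _truth_frame(spec: PlateSpec, truths: list[ColonyTruth],
                 elapsed_time: float, plate: str = "p1",
                 condition: str = "") -> pd.DataFrame:
    rows = []
    for t in truths:
        gx, gy = spec.grid_position(t.row, t.col)
        radius = float(t.radius or 0.0)
        rows.append({
            "plate": plate, "condition": condition, "timepoint": elapsed_time,
            "row": t.row, "col": t.col, "mutant_id": t.mutant_id,
            "center_x": t.center[0], "center_y": t.center[1],
            "grid_x": gx, "grid_y": gy, "radius": radius,
            "redness_true": t.redness_true,
            "size_true": math.pi * radius ** 2,
            "is_empty": t.is_empty,
        })
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def background_field(spec: PlateSpec) -> np.ndarray:
    """Deterministic agar background (H, W): gradient plus vignette."""
    h, w = spec.image_shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    b = spec.background_level * (
        1.0 + spec.background_gradient / max(spec.background_level, 1e-9)
        * ((x - w / 2) + 0.5 * (y - h / 2)))
    # simple quadratic vignette, darkest in the corners
    r2 = ((x - w / 2) ** 2 + (y - h / 2) ** 2) / ((w / 2) ** 2 + (h / 2) ** 2)
    b *= 1.0 - spec.vignette_strength * r2
    return np.clip(b, 0.0, 1.0)


def render_plate(spec: PlateSpec, truths: list[ColonyTruth],
                 elapsed_time: float = DEFAULT_TIMEPOINTS[0],
                 rng: np.random.Generator | None = None,
                 plate: str = "p1", condition: str = "",
                 ) -> tuple[PlateImage, pd.DataFrame]:
    """Render one plate image and return it with its ground-truth table.

    Colonies are discs at jittered grid positions whose colour interpolates
    white -> red with ``redness_true``; red colonies carry a Gaussian halo of
    width ``halo_diffusion_sigma_per_hour * elapsed_time`` beyond the rim.
    The background has a linear gradient, a vignette and i.i.d. Gaussian
    sensor noise.  Identical seeds give bit-identical images.
    """
    if elapsed_time < 0:
        raise ValueError("elapsed_time must be >= 0")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truths = _fill_geometry(spec, truths, rng)

    h, w = spec.image_shape
    base_v = background_field(spec)
    sat = np.zeros((h, w))          # red saturation map, max-blended
    colony_v = np.zeros((h, w))     # colony body value, max-blended

    live = [t for t in truths if not t.is_empty]
    if len(live) > 1:
        centers = np.array([t.center for t in live])
        radii = np.array([t.radius for t in live])
        tree = cKDTree(centers)
        pairs = tree.query_pairs(r=float(2 * radii.max()))
        overlapping = [(live[i], live[j]) for i, j in pairs
                       if np.hypot(*(centers[i] - centers[j])) < radii[i] + radii[j]]
        if overlapping:
            pos = [((a.row, a.col), (b.row, b.col)) for a, b in overlapping]
            warnings.warn(f"overlapping colony discs (max-blended): {pos}",
                          stacklevel=2)

    sigma = spec.halo_diffusion_sigma_per_hour * elapsed_time
    for t in live:
        cx, cy = t.center
        rad = float(t.radius)
        reach = int(math.ceil(rad + (3.5 * sigma if t.redness_true > 0 else 0) + 2))
        x0, x1 = max(0, int(cx) - reach), min(w, int(cx) + reach + 1)
        y0, y1 = max(0, int(cy) - reach), min(h, int(cy) + reach + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        d = np.hypot(xx - cx, yy - cy)
        disc = d <= rad
        np.maximum(colony_v[y0:y1, x0:x1], np.where(disc, COLONY_VALUE, 0.0),
                   out=colony_v[y0:y1, x0:x1])
        if t.redness_true > 0:
            conc = np.where(
                disc, t.redness_true,
                t.redness_true * HALO_AMP
                * (np.exp(-((d - rad) ** 2) / (2 * sigma ** 2)) if sigma > 0
                   else 0.0))
            s = SAT_MAX * -np.expm1(-conc)
            np.maximum(sat[y0:y1, x0:x1], s, out=sat[y0:y1, x0:x1])

    value = np.where(colony_v > 0, colony_v, base_v)
    img = np.empty((h, w, 3))
    img[..., 0] = value                     # red channel carries full value
    img[..., 1] = value * (1.0 - sat)
    img[..., 2] = value * (1.0 - sat)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)

    image = PlateImage(pixels=pixels, plate_id=plate, condition=condition,
                       timepoint=elapsed_time)
    return image, _truth_frame(spec, truths, elapsed_time, plate, condition)


# ---------------------------------------------------------------------------
# screen-level simulation


def design_screen(n_mutants: int = 192,
                  conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
                  cprg_fraction: float = 0.02,
                  specific_fraction: float | None = 0.75,
                  effect_size_range: tuple[float, float] = (0.01, 0.15),
                  spec: PlateSpec | None = None,
                  arrangement: str = "same_plate",
                  dropout_fraction: float = 0.0,
                  seed: int = 0,
                  ) -> tuple[dict[str, PlateLayout], ScreenTruth]:
    """Design layouts and planted truth for a multi-condition screen.

    Each mutant has 2 replicate clones per condition; with
    ``arrangement="same_plate"`` (default) both clones sit at separate
    positions of the same plate, with ``"sister_plates"`` they sit at the
    same position of two sister plates.  ``cprg_fraction`` is the expected
    per-condition fraction of positive mutants.  With ``specific_fraction``
    set, that share of the positive union is positive in exactly one
    condition and the remainder in all conditions (emulating mostly
    condition-specific hits); with ``specific_fraction=None`` each mutant is
    planted positive independently per condition (Binomial planting).
    Positive effect sizes (redness per hour) are drawn log-uniformly over
    ``effect_size_range``.
    """
    if n_mutants < 1:
        raise ValueError("n_mutants must be >= 1")
    if spec is None:
        spec = PlateSpec()
    rng = np.random.default_rng(seed)
    k = len(conditions)
    mutants = [f"m{i:05d}" for i in range(n_mutants)]

    # planted positivity pattern per mutant x condition
    positive = {m: set() for m in mutants}
    if specific_fraction is None:
        for cond in conditions:
            mask = rng.random(n_mutants) < cprg_fraction
            for m, hit in zip(mutants, mask):
                if hit:
                    positive[m].add(cond)
    else:
        per_cond_share = specific_fraction / k + (1.0 - specific_fraction)
        union_n = min(n_mutants,
                      max(1, int(round(cprg_fraction * n_mutants / per_cond_share))))
        chosen = rng.choice(n_mutants, size=union_n, replace=False)
        n_specific = int(round(specific_fraction * union_n))
        for i, mi in enumerate(chosen):
            m = mutants[mi]
            if i < n_specific:
                positive[m].add(conditions[rng.integers(k)])
            else:
                positive[m].update(conditions)

    lo, hi = effect_size_range
    if not (0 < lo <= hi):
        raise ValueError("effect_size_range must be positive and ordered")
    truth_rows = []
    for m in mutants:
        for cond in conditions:
            is_pos = cond in positive[m]
            eff = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if is_pos else 0.0
            truth_rows.append({"mutant_id": m, "condition": cond,
                               "true_class": "CPRG+" if is_pos else "CPRG-",
                               "effect_size": eff})
    truth = ScreenTruth(pd.DataFrame(truth_rows))

    # layouts: identical arraying in every condition
    per_plate = spec.rows * spec.cols
    entries = []
    if arrangement == "same_plate":
        slots = []  # (plate, row, col) in fill order
        n_slots = 2 * n_mutants
        n_plates = math.ceil(n_slots / per_plate)
        for p in range(n_plates):
            for r in range(spec.rows):
                for c in range(spec.cols):
                    slots.append((f"p{p + 1}", r, c))
        for i, m in enumerate(mutants):
            for clone in (1, 2):
                pl, r, c = slots[i + (clone - 1) * n_mutants]
                entries.append((pl, r, c, m, m, clone, False, False))
    elif arrangement == "sister_plates":
        n_plates = math.ceil(n_mutants / per_plate)
        for i, m in enumerate(mutants):
            p, off = divmod(i, per_plate)
            r, c = divmod(off, spec.cols)
            entries.append((f"p{p + 1}a", r, c, m, m, 1, False, False))
            entries.append((f"p{p + 1}b", r, c, m, m, 2, False, False))
    else:
        raise ValueError(f"unknown arrangement {arrangement!r}")

    df = pd.DataFrame(entries, columns=["plate", "row", "col", "strain_id",
                                        "mutant_id", "clone_index",
                                        "is_control", "is_empty"])
    if dropout_fraction > 0:
        keep = rng.random(len(df)) >= dropout_fraction
        df = df[keep].reset_index(drop=True)
    layouts = {cond: PlateLayout(rows=spec.rows, cols=spec.cols,
                                 entries=df.copy()) for cond in conditions}
    return layouts, truth


@dataclass
class ScreenSim:
    """A rendered synthetic screen: images plus complete ground truth."""

    images: list[PlateImage]
    truth_table: pd.DataFrame
    layouts: dict[str, PlateLayout]
    truth: ScreenTruth
    spec: PlateSpec
    timepoints: tuple[float, ...]


def simulate_screen(layouts: dict[str, PlateLayout], truth: ScreenTruth,
                    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
                    spec: PlateSpec | None = None,
                    out_dir: str | Path | None = None) -> ScreenSim:
    """Render a full screen: one image per plate per condition per timepoint.

    Redness of a positive mutant's colonies at time ``t`` is
    ``effect_size * t`` (pigment accrues linearly with incubation); white
    colonies stay at 0.  Geometry (centers, radii) is drawn once per plate
    and shared across timepoints; sensor noise is fresh per exposure.
    When ``out_dir`` is given, images (PNG + JSON sidecars), the ground-truth
    table (TSV) and the simulation config (JSON) are written there.
    """
    if spec is None:
        spec = PlateSpec()
    tps = tuple(float(t) for t in timepoints)
    if len(tps) == 0 or any(b <= a for a, b in zip(tps, tps[1:])):
        raise ValueError("timepoints must be strictly increasing")

    truth_mutants = set(truth.table["mutant_id"])
    images: list[PlateImage] = []
    frames: list[pd.DataFrame] = []
    for ci, cond in enumerate(sorted(layouts)):
        layout = layouts[cond]
        lay_mutants = set(layout.occupied()["mutant_id"])
        missing = sorted(truth_mutants - lay_mutants)
        if missing:
            raise ValueError(
                f"mutants in truth absent from layout for {cond!r}: {missing}")
        eff = truth.table[truth.table["condition"] == cond].set_index(
            "mutant_id")["effect_size"]
        for pi, plate in enumerate(layout.plates):
            sub = layout.entries[layout.entries["plate"] == plate]
            base = [ColonyTruth(row=int(e.row), col=int(e.col),
                                mutant_id=str(e.mutant_id),
                                is_empty=bool(e.is_empty),
                                redness_true=0.0)
                    for e in sub.itertuples()]
            geom_rng = np.random.default_rng([spec.seed, ci, pi])
            base = _fill_geometry(spec, base, geom_rng)
            for ti, t in enumerate(tps):
                truths = []
                for b in base:
                    r = float(eff.get(b.mutant_id, 0.0)) * t if not b.is_empty else 0.0
                    truths.append(replace(b, redness_true=r))
                noise_rng = np.random.default_rng([spec.seed, ci, pi, ti, 1])
                img, tf = render_plate(spec, truths, elapsed_time=t,
                                       rng=noise_rng, plate=plate,
                                       condition=cond)
                images.append(img)
                frames.append(tf)

    truth_table = pd.concat(frames, ignore_index=True)
    sim = ScreenSim(images=images, truth_table=truth_table, layouts=layouts,
                    truth=truth, spec=spec, timepoints=tps)
    if out_dir is not None:
        _write_screen(sim, Path(out_dir))
    return sim


def _write_screen(sim: ScreenSim, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for img in sim.images:
        safe_cond = img.condition.replace(" ", "-")
        name = f"{img.plate_id}_{safe_cond}_t{img.timepoint:g}h.png"
        write_image(img, out_dir / name)
    sim.truth_table.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    for cond, layout in sim.layouts.items():
        safe_cond = cond.replace(" ", "-")
        layout.entries.to_csv(out_dir / f"layout_{safe_cond}.tsv",
                              sep="\t", index=False)
    sim.truth.table.to_csv(out_dir / "screen_truth.tsv", sep="\t", index=False)
    cfg = asdict(sim.spec)
    cfg["timepoints"] = list(sim.timepoints)
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=1))


# ---------------------------------------------------------------------------
# genetic-interaction colony-size simulation


def simulate_colony_sizes(spec: GISimSpec, gene_list: list[str],
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a double-mutant colony-size table with known interactions.

    Returns ``(sizes, truth)``: sizes has columns (gene, replicate, plate,
    size); truth stores per gene the fitness and interaction multipliers.
    Log-normal plate and colony noise factors are mean-one, so a neutral
    gene's expected growth score is 1.
    """
    genes = list(gene_list)
    if not genes:
        raise ValueError("gene_list must be non-empty")
    rng = np.random.default_rng(spec.seed)
    sp, sn = spec.plate_effect_sd, spec.noise_sd
    plate_eff = np.exp(rng.normal(-sp ** 2 / 2, sp, size=spec.replicates)) \
        if sp > 0 else np.ones(spec.replicates)
    rows = []
    for g in genes:
        mult = (spec.base_size * spec.gene_fitness.get(g, 1.0)
                * spec.interaction.get(g, 1.0))
        noise = np.exp(rng.normal(-sn ** 2 / 2, sn, size=spec.replicates)) \
            if sn > 0 else np.ones(spec.replicates)
        for r in range(spec.replicates):
            rows.append({"gene": g, "replicate": r + 1, "plate": f"p{r + 1}",
                         "size": float(mult * plate_eff[r] * noise[r])})
    sizes = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "gene": genes,
        "fitness": [spec.gene_fitness.get(g, 1.0) for g in genes],
        "interaction": [spec.interaction.get(g, 1.0) for g in genes],
    })
    return sizes, truth
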