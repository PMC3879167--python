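"""End-to-end screen analysis: images -> measurements -> scores -> hits.

Ties the stages together the way the screen was analysed: quantify every
image, pick the early quantification timepoint per condition, calibrate (or
accept) the hit threshold, flag halo spill-over onto neighbors, average the
replicate clones, call hits per condition and summarise their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from chromopin.plate import PlateImage, PlateLayout
from chromopin.quantify import QuantConfig, quantify_plate, flag_neighbor_contamination
from chromopin.screen import (
    ComparisonSummary,
    average_replicates,
    call_hits,
    compare_conditions,
    default_threshold,
    hit_sets,
    select_timepoint,
)


@dataclass
class ScreenResult:
    """Everything the screen-level analysis computed."""

    measurements: pd.DataFrame          # all images, all timepoints
    selected_timepoints: dict[str, float]  # condition -> chosen hour
    threshold: float
    scores: pd.DataFrame                # mutant x condition long form
    hit_calls: pd.DataFrame
    comparison: ComparisonSummary | None
    config: QuantConfig = field(default_factory=QuantConfig)

    @property
    def hits(self) -> dict[str, set[str]]:
        return hit_sets(self.hit_calls)


def quantify_screen(images: list[PlateImage],
                    layouts: dict[str, PlateLayout],
                    config: QuantConfig | None = None) -> pd.DataFrame:
    """Quantify every plate image of a screen into one measurement table."""
    if config is None:
        config = QuantConfig()
    frames = []
    for img in images:
        layout = layouts[img.condition] if img.condition in layouts \
            else next(iter(layouts.values()))
        frames.append(quantify_plate(img, layout, config))
    return pd.concat(frames, ignore_index=True)


def analyze_screen(measurements: pd.DataFrame,
                   threshold: float | None = None,
                   config: QuantConfig | None = None,
                   phi: float = 0.9,
                   threshold_z: float = 6.0) -> ScreenResult:
    """Run the screen statistics on a full measurement table.

    Per condition the earliest well-grown timepoint is selected; the hit
    threshold is calibrated from the selected scores unless given; neighbor
    contamination is flagged and excluded; clone scores are averaged and
    hits called per condition.
    """
    if config is None:
        config = QuantConfig()
    selected: dict[str, float] = {}
    kept = []
    for cond, sub in measurements.groupby("condition"):
        t = select_timepoint(sub, phi=phi, min_area=config.min_area)
        selected[cond] = t
        kept.append(sub[sub["timepoint"] == t])
    at_t = pd.concat(kept, ignore_index=True)

    if threshold is None:
        threshold = default_threshold(at_t["cprg_score"], z=threshold_z)

    flagged = pd.concat(
        [flag_neighbor_contamination(grp, threshold)
         for _, grp in at_t.groupby("condition")],
        ignore_index=True)
    scores = pd.concat(
        [average_replicates(grp) for _, grp in flagged.groupby("condition")],
        ignore_index=True)
    calls = call_hits(scores, threshold)
    comparison = compare_conditions(hit_sets(calls)) \
        if calls["condition"].nunique() >= 2 else None
    return ScreenResult(measurements=measurements,
                        selected_timepoints=selected, threshold=threshold,
                        scores=scores, hit_calls=calls,
                        comparison=comparison, config=config)


def run_screen(images: list[PlateImage], layouts: dict[str, PlateLayout],
               threshold: float | None = None,
               config: QuantConfig | None = None) -> ScreenResult:
    """Quantify images and run the full screen analysis in one call."""
    measurements = quantify_screen(images, layouts, config)
    return analyze_screen(measurements, threshold=threshold, config=config)
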