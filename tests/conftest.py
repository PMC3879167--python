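"""Shared fixtures: synthetic screens and layouts built at test time."""

import numpy as np
import pandas as pd
import pytest

from chromopin import (
    ColonyTruth,
    PlateLayout,
    PlateSpec,
    design_screen,
    simulate_screen,
)
from chromopin.pipeline import run_screen


def full_plate_layout(rows: int, cols: int, plate: str = "p1") -> PlateLayout:
    """A layout with every position occupied by its own mutant."""
    df = pd.DataFrame(
        [(plate, i // cols, i % cols, f"m{i:04d}", f"m{i:04d}", 1, False, False)
         for i in range(rows * cols)],
        columns=["plate", "row", "col", "strain_id", "mutant_id",
                 "clone_index", "is_control", "is_empty"])
    return PlateLayout(rows=rows, cols=cols, entries=df)


def full_plate_truths(rows: int, cols: int, redness=0.0) -> list[ColonyTruth]:
    """One ColonyTruth per position; ``redness`` scalar or indexable."""
    r = np.broadcast_to(np.asarray(redness, dtype=float), (rows * cols,))
    return [ColonyTruth(row=i // cols, col=i % cols, redness_true=float(r[i]),
                        mutant_id=f"m{i:04d}")
            for i in range(rows * cols)]


@pytest.fixture(scope="session")
def layout384():
    return full_plate_layout(16, 24)


@pytest.fixture(scope="session")
def screen4():
    """A 4-condition, 2-timepoint, 384-mutant rendered screen (2 plates per
    condition, 2 clones per mutant on the same plate)."""
    spec = PlateSpec(seed=11)
    layouts, truth = design_screen(n_mutants=384, spec=spec, seed=11)
    return simulate_screen(layouts, truth, spec=spec)


@pytest.fixture(scope="session")
def screen4_result(screen4):
    """Full pipeline result on the 4-condition screen."""
    return run_screen(screen4.images, screen4.layouts)
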