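"""Data model and I/O for plate images, library layouts and measurement tables.

Grid positions are 0-based, row-major, origin at the top-left of the image:
row 0 is the top pin row, column 0 the leftmost pin column.  A 384-pin plate
is 16 rows x 24 columns; the 1536-pin condensation is 32 x 48.

Condition labels are free strings.  The four-condition default set
(temperature x NaCl) ships as :data:`DEFAULT_CONDITIONS`.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: Default screen conditions: growth temperature (30 C or room temperature)
#: crossed with LB salt content (0 or 1% NaCl).
DEFAULT_CONDITIONS = ("30 LB0", "30 LB1", "RT LB0", "RT LB1")

#: Standard pinned-array formats: positions -> (rows, cols).
STANDARD_FORMATS = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

LAYOUT_COLUMNS = [
    "plate", "row", "col", "strain_id", "mutant_id",
    "clone_index", "is_control", "is_empty",
]

_FILENAME_RE = re.compile(r"^(?P<plate>[^_]+)_(?P<condition>.+)_t(?P<time>[0-9.]+)h$")


@dataclass
class PlateImage:
    """An RGB plate photograph plus acquisition metadata.

    ``pixels`` is an (H, W, 3) uint8 array; ``timepoint`` is the incubation
    time in hours at acquisition.
    """

    pixels: np.ndarray
    plate_id: str = "p1"
    condition: str = ""
    timepoint: float = 0.0
    acquisition_tag: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"plate image must be (H, W, 3) RGB, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("plate image must have height, width >= 1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PlateLayout:
    """Mapping from grid positions to strains and replicate clones.

    ``entries`` holds one row per occupied (or explicitly empty) position
    with columns ``plate, row, col, strain_id, mutant_id, clone_index,
    is_control, is_empty``.
    """

    rows: int
    cols: int
    entries: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("layout must have rows, cols >= 1")
        n = self.rows * self.cols
        if n not in STANDARD_FORMATS:
            warnings.warn(
                f"{self.rows}x{self.cols} = {n} positions is not a standard "
                "96/384/1536 pinned format", stacklevel=2)
        if self.entries is None or len(self.entries) == 0:
            self.entries = pd.DataFrame(columns=LAYOUT_COLUMNS)
            return
        df = self.entries.copy()
        for col in LAYOUT_COLUMNS:
            if col not in df.columns:
                if col == "plate":
                    df[col] = "p1"
                elif col == "clone_index":
                    df[col] = 1
                elif col in ("is_control", "is_empty"):
                    df[col] = False
                else:
                    raise ValueError(f"layout missing required column {col!r}")
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        df["clone_index"] = df["clone_index"].astype(int)
        df["is_control"] = df["is_control"].astype(bool)
        df["is_empty"] = df["is_empty"].astype(bool)
        bad = df[(df["row"] < 0) | (df["row"] >= self.rows)
                 | (df["col"] < 0) | (df["col"] >= self.cols)]
        if len(bad):
            pos = [(r.plate, r.row, r.col) for r in bad.itertuples()]
            raise ValueError(
                f"layout positions out of range for {self.rows}x{self.cols} "
                f"grid (0-based): {pos}")
        dup = df.duplicated(subset=["plate", "row", "col"], keep=False)
        if dup.any():
            pos = sorted({(r.plate, r.row, r.col)
                          for r in df[dup].itertuples()})
            raise ValueError(f"duplicate layout positions: {pos}")
        missing = df[~df["is_empty"] & (df["mutant_id"].isna()
                                        | (df["mutant_id"] == ""))]
        if len(missing):
            pos = [(r.plate, r.row, r.col) for r in missing.itertuples()]
            raise ValueError(f"non-empty layout entries without mutant_id: {pos}")
        self.entries = df[LAYOUT_COLUMNS].reset_index(drop=True)

    @property
    def plates(self) -> list[str]:
        return sorted(self.entries["plate"].unique().tolist())

    def occupied(self) -> pd.DataFrame:
        """Non-empty entries."""
        return self.entries[~self.entries["is_empty"]]


def read_layout(path: str | Path) -> PlateLayout:
    """Read a layout TSV with columns plate,row,col,strain_id,mutant_id,
    clone_index,is_control,is_empty and validate it.

    Grid size is inferred from the maximum indices, rounded up to the
    smallest standard format that contains them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"plate": str, "strain_id": str, "mutant_id": str})
    required = {"row", "col", "mutant_id"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"layout file {path} lacks required columns "
            f"{sorted(required - set(df.columns))}")
    rows, cols = _infer_grid(df)
    return PlateLayout(rows=rows, cols=cols, entries=df)


def _infer_grid(df: pd.DataFrame) -> tuple[int, int]:
    rmax = int(df["row"].max()) + 1 if len(df) else 0
    cmax = int(df["col"].max()) + 1 if len(df) else 0
    for _, (r, c) in sorted(STANDARD_FORMATS.items()):
        if rmax <= r and cmax <= c:
            return r, c
    return max(rmax, 1), max(cmax, 1)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.entries.to_csv(path, sep="\t", index=False)


def read_image(path: str | Path) -> PlateImage:
    """Read a PNG/TIFF plate photograph plus metadata.

    Metadata comes from a sidecar JSON (same stem, ``.json`` suffix) when
    present, otherwise from a ``plateID_condition_tXXh`` filename pattern.
    RGBA input drops alpha with a warning; grayscale is rejected because hue
    is undefined for single-channel data.
    """
    path = Path(path)
    with Image.open(path) as im:
        if im.mode in ("L", "I", "I;16", "F", "1"):
            raise ValueError(
                f"{path} is grayscale; hue is undefined for single-channel images")
        if im.mode == "RGBA":
            warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
            im = im.convert("RGB")
        elif im.mode != "RGB":
            im = im.convert("RGB")
        pixels = np.asarray(im, dtype=np.uint8)

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        m = _FILENAME_RE.match(path.stem)
        if m:
            meta = {"plate_id": m.group("plate"),
                    "condition": m.group("condition"),
                    "timepoint": float(m.group("time"))}
    return PlateImage(
        pixels=pixels,
        plate_id=str(meta.get("plate_id", path.stem)),
        condition=str(meta.get("condition", "")),
        timepoint=float(meta.get("timepoint", 0.0)),
        acquisition_tag=str(meta.get("acquisition_tag", "")),
    )


def write_image(image: PlateImage, path: str | Path) -> None:
    """Write an 8-bit RGB PNG plus a metadata sidecar JSON."""
    path = Path(path)
    Image.fromarray(image.pixels, mode="RGB").save(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "plate_id": image.plate_id,
        "condition": image.condition,
        "timepoint": image.timepoint,
        "acquisition_tag": image.acquisition_tag,
    }, indent=1))


def provenance_digest(params: dict) -> str:
    """Short stable digest of an analysis parameter set."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_measurements(table: pd.DataFrame, path: str | Path,
                       provenance: str = "") -> None:
    """Write a measurement table as TSV with a provenance header comment.

    Re-reading with :func:`read_measurements` round-trips the table exactly
    (values are written in full precision).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# provenance: {provenance}\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Read a measurement TSV; returns (table, provenance string)."""
    path = Path(path)
    provenance = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            provenance = first.split(":", 1)[1].strip()
        else:
            fh.seek(0)
        table = pd.read_csv(fh, sep="\t")
    return table, provenance


def map_replicates(layouts: dict[str, PlateLayout]) -> pd.DataFrame:
    """Index replicate clone positions per mutant per condition.

    ``layouts`` maps condition label -> layout for that condition.  Returns a
    table with one row per (mutant_id, condition, plate, row, col,
    clone_index) plus a ``flag`` column: ``single_clone`` when a mutant has
    fewer than 2 clones in a condition, ``extra_clones`` when more.  Mutants
    absent from one condition are simply absent from that condition's rows
    (recorded as missing, not an error).  Control and empty positions are
    excluded.
    """
    frames = []
    for cond, layout in layouts.items():
        occ = layout.occupied()
        occ = occ[~occ["is_control"]].copy()
        occ["condition"] = cond
        frames.append(occ[["mutant_id", "condition", "plate", "row", "col",
                           "clone_index"]])
    if not frames:
        return pd.DataFrame(columns=["mutant_id", "condition", "plate", "row",
                                     "col", "clone_index", "flag"])
    idx = pd.concat(frames, ignore_index=True)
    counts = idx.groupby(["mutant_id", "condition"])["row"].transform("size")
    idx["flag"] = ""
    idx.loc[counts < 2, "flag"] = "single_clone"
    idx.loc[counts > 2, "flag"] = "extra_clones"
    return idx.sort_values(["condition", "mutant_id", "clone_index"]).reset_index(drop=True)
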