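"""Genetic-interaction growth scores from double-mutant colony sizes.

The growth score of a gene is the mean colony size of its double-mutant
replicates divided by the average colony size of library clones grown on
the same plate set:

    g = mean(s_gene) / mean(s_library)

Scores greater than one indicate suppressive interactions, scores less than
one negative interactions.  Because the strict >1 / <1 rule classifies pure
noise, a configurable neutral band ``epsilon`` around 1 is applied by
default (``epsilon = 0`` restores the strict rule).

Two reference modes are provided because "the library average" and "the
matched single mutant" are different baselines: ``library-mean`` (default)
divides by the mean over all grown library clones; ``matched-single``
divides each gene by its own single-mutant reference size, supplied by the
caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chromopin.plate import PlateLayout

CLASSES = ("suppressive", "neutral", "negative")


def growth_score(gene_sizes: np.ndarray | list, library_sizes: np.ndarray | list,
                 ) -> float:
    """g = mean(grown replicate sizes) / mean(grown library sizes).

    Dead replicates (size 0) are excluded from the numerator; a gene with no
    grown replicate scores 0 (lethal candidate).  Raises if the library
    reference contains no grown clones.
    """
    lib = np.asarray(library_sizes, dtype=float)
    lib = lib[lib > 0]
    if len(lib) == 0 or lib.mean() <= 0:
        raise ValueError("library size set must contain grown (size > 0) clones")
    s = np.asarray(gene_sizes, dtype=float)
    if np.any(s < 0):
        raise ValueError("colony sizes must be >= 0")
    s = s[s > 0]
    if len(s) == 0:
        return 0.0
    return float(s.mean() / lib.mean())


def classify_interaction(g: float, epsilon: float = 0.2) -> str:
    """Classify a growth score: suppressive above 1 + eps, negative below
    1 - eps, neutral in between (boundaries inclusive of neutral)."""
    if g < 0:
        raise ValueError("growth score must be >= 0")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if g > 1.0 + epsilon:
        return "suppressive"
    if g < 1.0 - epsilon:
        return "negative"
    return "neutral"


def score_screen(sizes: pd.DataFrame, layout: PlateLayout | None = None,
                 per_plate_norm: bool = False, epsilon: float = 0.2,
                 reference: str = "library-mean",
                 reference_sizes: pd.DataFrame | None = None,
                 exclude_border: bool = False) -> pd.DataFrame:
    """Score a whole double-mutant colony-size table.

    ``sizes`` has columns (gene, replicate, plate, size).  With
    ``per_plate_norm`` each size is divided by its plate's mean grown
    library size before pooling, removing plate-to-plate pinning effects.
    ``reference="matched-single"`` divides by per-gene reference sizes
    (columns gene, size) instead of the library mean.  With a layout given
    (384- or 1536-format maps), every scored gene must appear in it;
    ``exclude_border`` drops border rows/columns from the library reference
    (border colonies overgrow in pinned arrays).  Returns one row per gene
    (gene, n_replicates, mean_size, library_mean, growth_score, class),
    sorted by score descending, with dead genes flagged ``lethal-candidate``.
    """
    required = {"gene", "size"}
    if not required.issubset(sizes.columns):
        raise ValueError(f"size table lacks columns {sorted(required - set(sizes.columns))}")
    df = sizes.copy()
    if "plate" not in df.columns:
        df["plate"] = "p1"
    if (df["size"] < 0).any():
        raise ValueError("colony sizes must be >= 0")

    if layout is not None:
        known = set(layout.occupied()["mutant_id"])
        missing = sorted(set(df["gene"]) - known)
        if missing:
            raise ValueError(f"genes absent from layout: {missing}")
        if exclude_border and {"row", "col"}.issubset(df.columns):
            border = (df["row"].isin([0, layout.rows - 1])
                      | df["col"].isin([0, layout.cols - 1]))
            df = df[~border]

    if per_plate_norm:
        def _norm(grp: pd.DataFrame) -> pd.Series:
            grown = grp.loc[grp["size"] > 0, "size"]
            m = grown.mean() if len(grown) else np.nan
            return grp["size"] / m
        df["size"] = df.groupby("plate", group_keys=False).apply(
            _norm, include_groups=False)

    grown = df.loc[df["size"] > 0, "size"]
    library_mean = float(grown.mean()) if len(grown) else float("nan")

    if reference == "matched-single":
        if reference_sizes is None:
            raise ValueError("matched-single reference requires reference_sizes")
        ref = reference_sizes.set_index("gene")["size"].astype(float)
    elif reference != "library-mean":
        raise ValueError(f"unknown reference mode {reference!r}")

    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        s = grp["size"].to_numpy(dtype=float)
        alive = s[s > 0]
        mean_size = float(alive.mean()) if len(alive) else 0.0
        if reference == "matched-single":
            if gene not in ref.index or ref[gene] <= 0:
                raise ValueError(f"no grown single-mutant reference for {gene!r}")
            denom = float(ref[gene])
        else:
            denom = library_mean
        g = mean_size / denom if len(alive) else 0.0
        flags = ""
        if len(alive) == 0:
            flags = "lethal-candidate"
        elif len(alive) < len(s):
            flags = "dead_replicates_excluded"
        rows.append({"gene": gene, "n_replicates": int(len(alive)),
                     "mean_size": mean_size, "library_mean": denom,
                     "growth_score": g,
                     "class": classify_interaction(g, epsilon),
                     "flags": flags})
    out = pd.DataFrame(rows).sort_values("growth_score", ascending=False,
                                         kind="stable").reset_index(drop=True)
    return out
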