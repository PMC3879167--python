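"""Screen-level statistics: timepoint selection, replicate averaging,
threshold hit calling, cross-condition comparison and term enrichment.

A mutant's screen score is the arithmetic mean of the CPRG scores of its
replicate clones (two in the full library).  Hits are mutants whose average
score strictly exceeds a threshold; the published screen used a cut-off of
10^3.7 instrument units (:data:`PAPER_THRESHOLD`), retained here verbatim
for use with the original score tables, while synthetic screens calibrate a
threshold from their own score distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: Published hit cut-off on the original instrument's score scale.
PAPER_THRESHOLD = 10 ** 3.7

SCORE_COLUMNS = ["mutant_id", "condition", "score", "n_clones", "flags"]


def select_timepoint(measurements: pd.DataFrame, phi: float = 0.9,
                     min_area: float = 12.0) -> float:
    """Choose the quantification timepoint for a measurement series.

    Picks the earliest timepoint at which at least a fraction ``phi`` of the
    expected colonies are segmented with area >= ``min_area`` — early
    imaging avoids halo spill-over onto neighbors while colonies must have
    grown enough to measure.  Falls back to the last timepoint (with a
    warning) when none qualifies.
    """
    if "timepoint" not in measurements or len(measurements) == 0:
        raise ValueError("measurements must be non-empty with a timepoint column")
    tps = sorted(measurements["timepoint"].unique())
    for t in tps:
        sub = measurements[measurements["timepoint"] == t]
        if (sub["area"] >= min_area).mean() >= phi:
            return float(t)
    warnings.warn(
        f"no timepoint reaches {phi:.0%} colony coverage; "
        f"falling back to the last ({tps[-1]} h)", stacklevel=2)
    return float(tps[-1])


def average_replicates(measurements: pd.DataFrame,
                       exclude_flags: tuple[str, ...] = ("empty",
                                                         "neighbor_contaminated"),
                       ) -> pd.DataFrame:
    """Average clone CPRG scores into a mutant x condition score table.

    Clones carrying any flag in ``exclude_flags`` are dropped before
    averaging; the mean runs over the clones that remain (mutants reduced to
    one clone are flagged ``single_clone``, to none ``no_clones`` with a
    missing score).  Returns long-form rows (mutant_id, condition, score,
    n_clones, flags).
    """
    df = measurements.copy()
    df["flags"] = df["flags"].fillna("").astype(str)
    excluded = df["flags"].str.contains("|".join(exclude_flags)) \
        if exclude_flags else pd.Series(False, index=df.index)
    rows = []
    for (m, cond), grp in df.groupby(["mutant_id", "condition"], sort=True):
        used = grp[~excluded.loc[grp.index]]
        n = len(used)
        flags = []
        if n < len(grp):
            flags.append("clones_excluded")
        if n == 1:
            flags.append("single_clone")
        if n == 0:
            flags.append("no_clones")
        rows.append({"mutant_id": m, "condition": cond,
                     "score": float(used["cprg_score"].mean()) if n else np.nan,
                     "n_clones": n, "flags": ";".join(flags)})
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def default_threshold(scores: pd.Series | np.ndarray, z: float = 6.0,
                      central_mass: float = 0.9) -> float:
    """Calibrate a hit threshold from a score distribution.

    tau = expm1(mean + z * sd) of log(1 + S) over the central
    ``central_mass`` quantile range — a robust white-colony noise envelope,
    far out in the right tail so only genuinely red colonies exceed it.
    """
    s = np.asarray(pd.Series(scores).dropna(), dtype=float)
    if len(s) == 0:
        raise ValueError("no scores to calibrate a threshold from")
    lo, hi = np.quantile(s, [(1 - central_mass) / 2, 1 - (1 - central_mass) / 2])
    central = np.log1p(s[(s >= lo) & (s <= hi)])
    return float(np.expm1(central.mean() + z * central.std()))


def call_hits(score_matrix: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Call hits: mutants whose average score strictly exceeds the threshold.

    Rows with missing scores (no usable clones) are never hits.  Returns the
    score table with ``threshold`` and boolean ``is_hit`` columns added.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = score_matrix.copy()
    out["threshold"] = float(threshold)
    out["is_hit"] = out["score"].gt(threshold).fillna(False)
    return out


def hit_sets(hit_calls: pd.DataFrame) -> dict[str, set[str]]:
    """Per-condition sets of hit mutants from a hit-call table."""
    return {cond: set(grp.loc[grp["is_hit"], "mutant_id"])
            for cond, grp in hit_calls.groupby("condition")}


@dataclass
class ComparisonSummary:
    """Cross-condition hit overlap: per-condition counts, all 2^k - 1 Venn
    membership classes, and the fraction of union hits specific to exactly
    one condition."""

    per_condition: dict[str, int]
    class_sizes: dict[tuple[str, ...], int]
    union_size: int
    condition_specific_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"conditions": "+".join(k), "n_conditions": len(k), "size": v}
                for k, v in sorted(self.class_sizes.items(),
                                   key=lambda kv: (len(kv[0]), kv[0]))]
        return pd.DataFrame(rows)


def compare_conditions(hits: dict[str, set[str]]) -> ComparisonSummary:
    """Enumerate Venn membership classes of per-condition hit sets.

    ``condition_specific_fraction`` = |hits in exactly one condition| /
    |union of hits| (0 when the union is empty).
    """
    if len(hits) < 2:
        raise ValueError("need hit sets for at least 2 conditions")
    conds = sorted(hits)
    union = set().union(*hits.values())
    class_sizes: dict[tuple[str, ...], int] = {}
    for r in range(1, len(conds) + 1):
        for combo in combinations(conds, r):
            class_sizes[combo] = 0
    specific = 0
    for m in union:
        member = tuple(c for c in conds if m in hits[c])
        class_sizes[member] += 1
        if len(member) == 1:
            specific += 1
    frac = specific / len(union) if union else 0.0
    return ComparisonSummary(
        per_condition={c: len(hits[c]) for c in conds},
        class_sizes=class_sizes, union_size=len(union),
        condition_specific_fraction=frac)


def enrich(hits: set[str] | list[str], universe: set[str] | list[str],
           annotation: pd.DataFrame, k_min: int = 3) -> pd.DataFrame:
    """Hypergeometric term enrichment of a hit list against a universe.

    ``annotation`` maps genes to terms (two columns, gene then term; GO- or
    KEGG-style).  For each term with at least ``k_min`` annotated universe
    genes, the upper-tail hypergeometric probability of drawing >= k
    annotated genes among the n hits is computed and Benjamini-Hochberg
    adjusted across tested terms.  Returns columns
    (term, N, K, n, k, p, q) sorted by p.
    """
    hits, universe = set(hits), set(universe)
    stray = sorted(hits - universe)
    if stray:
        raise ValueError(f"hits not contained in the universe: {stray}")
    gene_col, term_col = annotation.columns[:2]
    ann = annotation[annotation[gene_col].isin(universe)]
    N, n = len(universe), len(hits)
    rows = []
    for term, grp in ann.groupby(term_col):
        genes = set(grp[gene_col])
        K = len(genes)
        if K < k_min:
            continue
        k = len(genes & hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "N": N, "K": K, "n": n, "k": k, "p": p})
    result = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "p"])
    if len(result):
        result["q"] = multipletests(result["p"], method="fdr_bh")[1]
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["q"] = []
    return result


def read_condition_scores(path: str | Path) -> pd.DataFrame:
    """Read a per-condition average-score table.

    Accepts either a spreadsheet with one tab per condition (tab name =
    condition label, first column = gene/mutant, last numeric column =
    average score) — the layout of the published supplementary score
    workbook — or a TSV with columns (mutant_id, condition, score).
    Returns long-form (mutant_id, condition, score).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        frames = []
        for cond, df in sheets.items():
            num = df.select_dtypes("number")
            if num.shape[1] == 0 or df.shape[1] < 2:
                continue  # e.g. a hit-name-only tab
            frames.append(pd.DataFrame({
                "mutant_id": df.iloc[:, 0].astype(str),
                "condition": cond,
                "score": num.iloc[:, -1].astype(float)}))
        if not frames:
            raise ValueError(f"no score tabs found in {path}")
        return pd.concat(frames, ignore_index=True).dropna(subset=["score"])
    df = pd.read_csv(path, sep="\t")
    required = {"mutant_id", "condition", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path} lacks columns {sorted(required - set(df.columns))}")
    return df[["mutant_id", "condition", "score"]].dropna(subset=["score"])
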