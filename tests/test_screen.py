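"""Screen statistics: averaging, thresholds, Venn classes, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromopin.screen import (
    PAPER_THRESHOLD,
    average_replicates,
    call_hits,
    compare_conditions,
    default_threshold,
    enrich,
    hit_sets,
    read_condition_scores,
    select_timepoint,
)


def _meas(rows):
    return pd.DataFrame(rows, columns=["mutant_id", "condition", "plate",
                                       "row", "col", "timepoint", "area",
                                       "cprg_score", "flags"])


class TestSelectTimepoint:
    def test_single_timepoint_trivial(self):
        m = _meas([("a", "c", "p1", 0, 0, 12.0, 100, 1.0, "")])
        assert select_timepoint(m) == 12.0

    def test_earliest_wellgrown_timepoint_chosen(self):
        rows = []
        for t, area in [(8.0, 5), (12.0, 100), (19.0, 120)]:
            rows += [("a", "c", "p1", 0, i, t, area, 0.0, "") for i in range(10)]
        assert select_timepoint(_meas(rows)) == 12.0

    def test_fallback_to_last_with_warning(self):
        rows = [("a", "c", "p1", 0, i, t, 3, 0.0, "")
                for t in (12.0, 19.0) for i in range(10)]
        with pytest.warns(UserWarning, match="falling back"):
            assert select_timepoint(_meas(rows)) == 19.0


class TestAverageReplicates:
    def test_mean_of_two_clones(self):
        m = _meas([("a", "c", "p1", 0, 0, 12.0, 100, 1000.0, ""),
                   ("a", "c", "p1", 0, 1, 12.0, 100, 3000.0, "")])
        out = average_replicates(m)
        assert out.loc[0, "score"] == 2000.0
        assert out.loc[0, "n_clones"] == 2

    def test_clone_order_irrelevant(self):
        rows = [("a", "c", "p1", 0, 0, 12.0, 100, 1000.0, ""),
                ("a", "c", "p1", 0, 1, 12.0, 100, 3000.0, "")]
        out1 = average_replicates(_meas(rows))
        out2 = average_replicates(_meas(rows[::-1]))
        pd.testing.assert_frame_equal(out1, out2)

    def test_single_clone_flagged(self):
        m = _meas([("a", "c", "p1", 0, 0, 12.0, 100, 5.0, "")])
        out = average_replicates(m)
        assert out.loc[0, "flags"] == "single_clone"

    def test_contaminated_clone_excluded(self):
        m = _meas([("a", "c", "p1", 0, 0, 12.0, 100, 9000.0,
                    "neighbor_contaminated"),
                   ("a", "c", "p1", 0, 1, 12.0, 100, 10.0, "")])
        out = average_replicates(m)
        assert out.loc[0, "score"] == 10.0
        assert "clones_excluded" in out.loc[0, "flags"]

    def test_matches_brute_force_groupby_oracle(self):
        """Random plate fixture: the score matrix equals a hand-rolled
        dict-based group-by mean."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(192):
            for clone, pos in enumerate((i, i + 192)):
                rows.append((f"m{i:04d}", "c1", "p1", pos // 24, pos % 24,
                             12.0, 100, float(rng.gamma(2, 10)), ""))
        m = _meas(rows)
        out = average_replicates(m).set_index("mutant_id")
        oracle: dict[str, list[float]] = {}
        for r in rows:
            oracle.setdefault(r[0], []).append(r[7])
        for mut, scores in oracle.items():
            assert out.loc[mut, "score"] == pytest.approx(
                sum(scores) / len(scores))


class TestCallHits:
    def test_no_hits_when_all_below(self):
        sm = pd.DataFrame({"mutant_id": ["a", "b"], "condition": "c",
                           "score": [1.0, 2.0], "n_clones": 2, "flags": ""})
        calls = call_hits(sm, 5.0)
        assert not calls["is_hit"].any()

    def test_nested_thresholds_give_nested_hits(self):
        rng = np.random.default_rng(1)
        sm = pd.DataFrame({"mutant_id": [f"m{i}" for i in range(50)],
                           "condition": "c",
                           "score": rng.lognormal(1, 2, 50),
                           "n_clones": 2, "flags": ""})
        taus = [0.5, 2.0, 8.0, 32.0]
        sets = [set(call_hits(sm, t).query("is_hit")["mutant_id"])
                for t in taus]
        for small, big in zip(sets[1:], sets[:-1]):
            assert small <= big

    def test_strictly_above_threshold(self):
        sm = pd.DataFrame({"mutant_id": ["a"], "condition": "c",
                           "score": [PAPER_THRESHOLD], "n_clones": 2,
                           "flags": ""})
        assert not call_hits(sm, PAPER_THRESHOLD)["is_hit"].any()

    def test_missing_scores_never_hits(self):
        sm = pd.DataFrame({"mutant_id": ["a"], "condition": "c",
                           "score": [np.nan], "n_clones": 0,
                           "flags": "no_clones"})
        assert not call_hits(sm, 1.0)["is_hit"].any()


class TestDefaultThreshold:
    def test_far_out_in_right_tail(self):
        rng = np.random.default_rng(2)
        s = rng.lognormal(-1, 0.3, 1000)
        tau = default_threshold(s)
        assert tau > np.quantile(s, 0.999)


class TestCompareConditions:
    def test_identical_hit_sets_zero_specific(self):
        h = {"a": {"x", "y"}, "b": {"x", "y"}, "c": {"x", "y"}}
        s = compare_conditions(h)
        assert s.condition_specific_fraction == 0.0
        assert s.union_size == 2

    def test_disjoint_hit_sets_fully_specific(self):
        h = {"a": {"x"}, "b": {"y"}, "c": {"z"}}
        s = compare_conditions(h)
        assert s.condition_specific_fraction == 1.0

    def test_class_sizes_match_exhaustive_enumeration(self):
        """Random hit sets over 100 mutants x 4 conditions: all 15
        membership classes equal brute-force pattern counting."""
        rng = np.random.default_rng(3)
        muts = [f"m{i}" for i in range(100)]
        conds = ["c1", "c2", "c3", "c4"]
        hits = {c: {m for m in muts if rng.random() < 0.3} for c in conds}
        s = compare_conditions(hits)
        # oracle: enumerate every of the 15 nonempty membership patterns
        oracle = {}
        for r in range(1, 5):
            for combo in itertools.combinations(conds, r):
                inside = set(muts)
                for c in combo:
                    inside &= hits[c]
                for c in set(conds) - set(combo):
                    inside -= hits[c]
                oracle[combo] = len(inside)
        assert s.class_sizes == oracle
        assert sum(s.class_sizes.values()) == s.union_size

    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()),
                    min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_class_sizes_always_sum_to_union(self, rows):
        conds = ["a", "b", "c"]
        hits = {c: {i for i, r in enumerate(rows) if r[j]}
                for j, c in enumerate(conds)}
        s = compare_conditions(hits)
        assert sum(s.class_sizes.values()) == s.union_size

    def test_requires_two_conditions(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": {"x"}})


class TestEnrich:
    @staticmethod
    def _ann(mapping):
        return pd.DataFrame([(g, t) for g, ts in mapping.items() for t in ts],
                            columns=["gene", "term"])

    def test_hits_equal_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        ann = self._ann({f"g{i}": ["T"] for i in range(4)})
        res = enrich(universe, universe, ann)
        assert res.loc[0, "k"] == res.loc[0, "K"]
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_exact_tail_probability_vs_enumeration(self):
        """N=10, K=4, n=3, k=3: p = C(4,3)/C(10,3) = 4/120, confirmed by
        exhaustive enumeration of all 120 draws."""
        universe = [f"g{i}" for i in range(10)]
        annotated = set(universe[:4])
        hits = set(universe[:3])           # all three hits annotated
        ann = self._ann({g: ["T"] for g in annotated})
        res = enrich(hits, universe, ann)
        assert res.loc[0, "p"] == pytest.approx(4 / 120)
        count = sum(1 for draw in itertools.combinations(universe, 3)
                    if len(set(draw) & annotated) >= 3)
        total = math.comb(10, 3)
        assert res.loc[0, "p"] == pytest.approx(count / total)

    def test_random_tables_match_enumeration_oracle(self):
        """Hypergeometric upper tails agree with brute-force enumeration on
        small universes (N <= 12)."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            N = int(rng.integers(6, 13))
            universe = [f"g{i}" for i in range(N)]
            annotated = set(rng.choice(universe, size=rng.integers(3, N),
                                       replace=False))
            n = int(rng.integers(1, N))
            hits = set(rng.choice(universe, size=n, replace=False))
            res = enrich(hits, universe, self._ann({g: ["T"] for g in annotated}))
            k = len(hits & annotated)
            count = sum(1 for draw in itertools.combinations(universe, n)
                        if len(set(draw) & annotated) >= k)
            assert res.loc[0, "p"] == pytest.approx(
                count / math.comb(N, n), rel=1e-9)

    def test_bh_q_monotone_and_single_term_identity(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(40)]
        hits = set(universe[:10])
        mapping = {}
        for t in range(6):
            for g in rng.choice(universe, size=8, replace=False):
                mapping.setdefault(g, []).append(f"T{t}")
        res = enrich(hits, universe, self._ann(mapping))
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert (np.diff(res["q"]) >= -1e-12).all()   # nondecreasing in p rank
        single = enrich(hits, universe,
                        self._ann({g: ["T0"] for g in universe[:8]}))
        assert single.loc[0, "q"] == pytest.approx(single.loc[0, "p"])

    def test_small_terms_skipped(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrich(set(universe[:2]), universe,
                     self._ann({"g0": ["tiny"], "g1": ["tiny"]}), k_min=3)
        assert len(res) == 0

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            enrich({"ghost"}, {"a", "b"}, self._ann({"a": ["T"]}))


class TestReadConditionScores:
    def test_tsv_roundtrip(self, tmp_path):
        df = pd.DataFrame({"mutant_id": ["a", "b"], "condition": ["c1", "c1"],
                           "score": [1.0, 2.0]})
        p = tmp_path / "scores.tsv"
        df.to_csv(p, sep="\t", index=False)
        pd.testing.assert_frame_equal(read_condition_scores(p), df)

    def test_workbook_tab_per_condition(self, tmp_path):
        """Synthetic stand-in for the published score workbook: one tab per
        condition plus a names-only tab that is skipped."""
        p = tmp_path / "scores.xlsx"
        with pd.ExcelWriter(p) as w:
            for cond in ("30 LB0", "30 LB1", "RT LB0", "RT LB1"):
                pd.DataFrame({"gene": ["thrA", "elyC"],
                              "score": [12.0, 9000.0]}).to_excel(
                    w, sheet_name=cond, index=False)
            pd.DataFrame({"gene": ["elyC"]}).to_excel(w, sheet_name="hits",
                                                      index=False)
        scores = read_condition_scores(p)
        assert set(scores["condition"]) == {"30 LB0", "30 LB1", "RT LB0",
                                            "RT LB1"}
        calls = call_hits(scores, PAPER_THRESHOLD)
        assert hit_sets(calls) == {c: {"elyC"} for c in set(scores["condition"])}
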