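"""Perturbation scoring, permutation calibration, ranking, overlap graph."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathmarkers import (
    Pathway,
    PathwayCollection,
    overlap_graph,
    permutation_pvalues,
    perturbation_score,
    rank_pathways,
    score_pathways,
)
from pathmarkers.activity import ActivityMatrix, compute_activity, filter_measured_pathways
from pathmarkers.perturbation import column_statistics


def _activity(matrix: np.ndarray, sample_ids=None, names=None) -> ActivityMatrix:
    matrix = np.asarray(matrix, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(matrix.shape[0])]
    names = names or [f"p{k}" for k in range(matrix.shape[1])]
    return ActivityMatrix(
        pd.DataFrame(matrix, index=sample_ids, columns=names),
        pd.DataFrame(
            (~np.isnan(matrix)).astype(int), index=sample_ids, columns=names
        ),
    )


class TestScore:
    def test_hand_evaluated_pooled_t(self):
        t, score = perturbation_score([1, 2, 3, 4], ["A", "A", "B", "B"])
        # pooled s^2 = 0.5, se = sqrt(0.5 * (1/2 + 1/2)), |dmean| = 2
        assert score == pytest.approx(2 * math.sqrt(2), abs=1e-12)
        assert t == pytest.approx(-2 * math.sqrt(2), abs=1e-12)

    def test_agrees_with_scipy_both_variants(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=9), rng.normal(1.0, 2.0, size=7)
        values = np.concatenate([a, b])
        labels = ["A"] * 9 + ["B"] * 7
        t_pooled, _ = perturbation_score(values, labels, variant="pooled")
        t_welch, _ = perturbation_score(values, labels, variant="welch")
        assert t_pooled == pytest.approx(stats.ttest_ind(a, b).statistic, abs=1e-12)
        assert t_welch == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).statistic, abs=1e-12
        )

    def test_degenerate_equal_groups_score_zero(self):
        t, score = perturbation_score([1, 1, 1, 1], ["A", "A", "B", "B"])
        assert t == 0.0 and score == 0.0

    def test_zero_variance_nonzero_difference_is_infinite(self):
        t, score = perturbation_score([2, 2, 1, 1], ["A", "A", "B", "B"])
        assert t == math.inf and score == math.inf

    def test_label_swap_flips_sign_only(self):
        values = [1.0, 2.5, 0.3, 4.0, 5.0, 1.1]
        labels = ["A", "B", "A", "B", "A", "B"]
        flipped = ["B", "A", "B", "A", "B", "A"]
        t1, s1 = perturbation_score(values, labels)
        t2, s2 = perturbation_score(values, flipped)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_location_shift_of_all_samples_leaves_score_unchanged(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=10)
        labels = ["A"] * 5 + ["B"] * 5
        _, s1 = perturbation_score(values, labels)
        _, s2 = perturbation_score(values + 123.456, labels)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_unscorable_column_flagged_nan(self):
        act = _activity([[1.0], [np.nan], [2.0], [3.0]])
        labels = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        stats_df = column_statistics(act, labels)
        assert np.isnan(stats_df["t_signed"].iloc[0])


class TestPermutationP:
    def test_constant_column_gives_p_one(self):
        act = _activity(np.ones((6, 3)))
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        p = permutation_pvalues(act, labels, B=200, seed=1)
        assert (p == 1.0).all()

    def test_exhaustive_two_vs_two(self):
        act = _activity([[10.0], [9.0], [1.0], [2.0]])
        labels = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
        p = permutation_pvalues(act, labels, mode="exhaustive")
        # only the true assignment and its mirror reach the maximal |t|
        assert p.iloc[0] == pytest.approx(2 / 6)

    def test_exhaustive_matches_enumeration_oracle(self):
        """Brute-force oracle: scipy t on every C(n, n_A) label assignment."""
        rng = np.random.default_rng(17)
        L = rng.normal(size=(8, 5))
        L[1, 2] = np.nan
        act = _activity(L)
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        p = permutation_pvalues(act, labels, mode="exhaustive")
        for k in range(5):
            col = L[:, k]

            def unsigned_t(mask):
                a = col[list(mask)]
                b = col[[i for i in range(8) if i not in mask]]
                a, b = a[~np.isnan(a)], b[~np.isnan(b)]
                return abs(stats.ttest_ind(a, b).statistic)

            observed = unsigned_t((0, 1, 2, 3))
            assignments = list(itertools.combinations(range(8), 4))
            c = sum(unsigned_t(m) >= observed - 1e-12 for m in assignments)
            assert p.iloc[k] == pytest.approx(c / len(assignments), abs=1e-12)

    def test_sampled_floor_and_seed_determinism(self):
        rng = np.random.default_rng(2)
        act = _activity(rng.normal(size=(10, 20)))
        labels = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        p1 = permutation_pvalues(act, labels, B=500, seed=9)
        p2 = permutation_pvalues(act, labels, B=500, seed=9)
        assert (p1 >= 1 / 501).all()
        pd.testing.assert_series_equal(p1, p2)

    def test_sampled_converges_to_exhaustive(self):
        """With n <= 8 samples, sampled p lies within 3 MC standard errors
        of the exhaustive value."""
        rng = np.random.default_rng(4)
        act = _activity(rng.normal(size=(8, 6)))
        labels = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}
        exact = permutation_pvalues(act, labels, mode="exhaustive")
        B = 50_000
        sampled = permutation_pvalues(act, labels, B=B, seed=0)
        se = np.sqrt(exact * (1 - exact) / B)
        assert (np.abs(sampled - exact) <= 3 * se + 2 / B).all()

    def test_exhaustive_guard_on_large_cohorts(self):
        act = _activity(np.zeros((22, 1)))
        labels = {f"s{i}": ("A" if i < 11 else "B") for i in range(22)}
        with pytest.raises(ValueError, match="exhaustive"):
            permutation_pvalues(act, labels, mode="exhaustive")


class TestRanking:
    def _table(self, scores, ps, names=None):
        names = names or [f"p{k}" for k in range(len(scores))]
        return pd.DataFrame(
            {
                "t_signed": scores,
                "score": np.abs(np.asarray(scores, dtype=float)),
                "p_value": ps,
            },
            index=names,
        )

    def test_descending_score_order(self):
        table = rank_pathways(self._table([3.0, 4.7, 1.0], [0.01, 0.001, 0.5]))
        assert table["rank"].tolist() == [1, 2, 3]
        assert table.index.tolist() == ["p1", "p0", "p2"]

    def test_tie_broken_by_smaller_p(self):
        table = rank_pathways(self._table([2.0, 2.0], [0.01, 0.001]))
        assert table.index.tolist() == ["p1", "p0"]

    def test_tie_broken_by_name_last(self):
        table = rank_pathways(self._table([2.0, 2.0], [0.01, 0.01], ["zz", "aa"]))
        assert table.index.tolist() == ["aa", "zz"]

    def test_infinite_score_ranks_first(self):
        table = rank_pathways(self._table([np.inf, 5.0], [0.001, 0.001]))
        assert table.index[0] == "p0"

    def test_matches_stable_sort_oracle(self):
        rng = np.random.default_rng(23)
        scores = rng.choice([1.0, 2.0, 3.0], size=50)  # force ties
        ps = rng.choice([0.01, 0.02], size=50)
        names = [f"pw{idx:02d}" for idx in rng.permutation(50)]
        table = rank_pathways(self._table(scores, ps, names))
        oracle = sorted(
            zip(scores, ps, names), key=lambda r: (-r[0], r[1], r[2])
        )
        assert table.index.tolist() == [name for _, _, name in oracle]

    def test_unscorable_rows_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="unscorable"):
            table = rank_pathways(
                self._table([2.0, np.nan, 1.0], [0.1, np.nan, 0.2])
            )
        assert len(table) == 2


class TestMonotoneAssociation:
    def test_score_and_significance_strongly_associated(self, small_simulation):
        """Stronger perturbations get smaller p: Spearman(score, -log p) > 0.9
        on a seeded synthetic run with >= 100 pathways."""
        from pathmarkers import SimulationConfig, simulate_dataset

        config = SimulationConfig(
            n_genes=3000,
            n_pathways=120,
            pathway_size_range=(10, 40),
            n_planted=10,
            effect_size=1.0,
            noise_sd=1.0,
            n_unmeasured_pathways=0,
            seed=6,
        )
        ds, coll, _ = simulate_dataset(config)
        act = compute_activity(ds, coll)
        table = score_pathways(act, ds.labels, B=2000, seed=6)
        rho = stats.spearmanr(table["score"], -np.log(table["p_value"])).statistic
        assert rho > 0.9


class TestOverlapGraph:
    def test_shared_gene_edge(self):
        coll = PathwayCollection(
            [
                Pathway("P1", "na", frozenset({"G1", "G2"})),
                Pathway("P2", "na", frozenset({"G2", "G3"})),
            ]
        )
        g = overlap_graph(coll)
        assert g.number_of_edges() == 1
        assert g.edges["P1", "P2"]["shared_genes"] == {"G2"}

    def test_disjoint_sets_stay_isolated(self):
        coll = PathwayCollection(
            [
                Pathway("P1", "na", frozenset({"G1"})),
                Pathway("P2", "na", frozenset({"G2"})),
            ]
        )
        g = overlap_graph(coll)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {"P1", "P2"}

    def test_unknown_subset_name_is_error(self):
        coll = PathwayCollection([Pathway("P1", "na", frozenset({"G1"}))])
        with pytest.raises(KeyError, match="NOPE"):
            overlap_graph(coll, subset=["NOPE"])

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(31)
        universe = [f"G{i}" for i in range(30)]
        sets = [
            frozenset(rng.choice(universe, size=rng.integers(2, 8), replace=False))
            for _ in range(10)
        ]
        coll = PathwayCollection(
            [Pathway(f"P{i}", "na", s) for i, s in enumerate(sets)]
        )
        g = overlap_graph(coll)
        expected_edges = set()
        for i in range(10):
            for j in range(10):
                if i < j and any(x in sets[j] for x in sets[i]):
                    expected_edges.add((f"P{i}", f"P{j}"))
        assert {tuple(sorted(e)) for e in g.edges} == expected_edges
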