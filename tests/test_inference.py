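"""Chi-square independence tests, Kruskal-Wallis and Dunn comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coopnet.datatypes import Corpus, PipelineConfig, ValidationError
from coopnet.inference import (
    DegenerateTableError,
    chi_square_independence,
    dichotomize_intensity,
    dunn_pairwise,
    emotion_group_tests,
    intensity_by_module_table,
    kruskal_wallis,
    misuse_by_module_table,
)

from conftest import make_record


def kruskal_oracle(groups):
    """Brute-force H from first principles: rank everything, apply
    H = 12/(N(N+1)) * sum n_g (rbar_g - rbar)^2, then tie-correct."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for k, g in enumerate(groups):
        rbar = ranks[bounds[k] : bounds[k + 1]].mean()
        h += len(g) * (rbar - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(t**3 - t) / (n**3 - n)
    return h / correction


def dunn_z_oracle(groups, i, j):
    """Mean-rank-difference z statistic computed directly."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_i = ranks[bounds[i] : bounds[i + 1]].mean()
    mean_j = ranks[bounds[j] : bounds[j + 1]].mean()
    _, t = np.unique(pooled, return_counts=True)
    tie = np.sum(t**3 - t) / (12 * (n - 1))
    se = np.sqrt((n * (n + 1) / 12 - tie) * (1 / len(groups[i]) + 1 / len(groups[j])))
    return (mean_i - mean_j) / se


class TestChiSquare:
    def test_hand_computed_2x2(self):
        res = chi_square_independence([[10, 20], [20, 10]])
        assert res.chi2 == pytest.approx(20 / 3, abs=1e-9)
        assert res.df == 1 and res.n == 60

    def test_proportional_rows_give_zero(self):
        res = chi_square_independence([[10, 20, 30], [20, 40, 60]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_2x4_table_has_3_df(self):
        res = chi_square_independence([[10, 20, 30, 40], [40, 30, 20, 10]])
        assert res.df == 3

    def test_residuals_are_standardized_deviations(self):
        res = chi_square_independence([[10, 20], [20, 10]])
        o, e = res.observed.to_numpy(), res.expected.to_numpy()
        assert np.allclose(res.residuals.to_numpy(), (o - e) / np.sqrt(e))
        # chi2 equals the sum of squared residuals
        assert res.chi2 == pytest.approx(float((res.residuals.to_numpy() ** 2).sum()))

    def test_invariance_under_permutation_and_transpose(self):
        table = np.array([[5, 9, 14], [11, 3, 8]])
        base = chi_square_independence(table).chi2
        assert chi_square_independence(table[:, [2, 0, 1]]).chi2 == pytest.approx(base)
        assert chi_square_independence(table[::-1]).chi2 == pytest.approx(base)
        assert chi_square_independence(table.T).chi2 == pytest.approx(base)

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_independence([[0, 0], [5, 5]])

    def test_margins_preserved_in_expected(self):
        res = chi_square_independence([[7, 2, 9], [4, 11, 5]])
        assert np.allclose(
            res.expected.sum(axis=1), res.observed.sum(axis=1).astype(float)
        )
        assert np.allclose(
            res.expected.sum(axis=0), res.observed.sum(axis=0).astype(float)
        )


class TestIntensity:
    def test_split_rule(self):
        records = [
            make_record(f"p{i}", list("abcde"), intensity=i + 1) for i in range(4)
        ]
        groups = dichotomize_intensity(records)
        assert groups == {"p0": "low", "p1": "low", "p2": "low", "p3": "high"}

    def test_group_sizes_sum_to_cohort(self):
        rng = np.random.default_rng(0)
        records = [
            make_record(f"p{i}", list("abcde"), intensity=int(rng.integers(1, 5)))
            for i in range(50)
        ]
        groups = dichotomize_intensity(records)
        assert len(groups) == 50


class TestKruskalWallis:
    def test_matches_rank_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(5, 15)).astype(float)
                      for _ in range(int(rng.integers(2, 5)))]
            if all(np.all(np.concatenate(groups) == groups[0][0]) for _ in [0]):
                continue
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            res = kruskal_wallis(groups)
            assert res.h == pytest.approx(kruskal_oracle(groups), abs=1e-9)
            assert res.df == len(groups) - 1

    def test_two_identical_groups_give_zero(self):
        res = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert res.h == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_flagged_not_raised(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert res.undefined and np.isnan(res.h)

    def test_four_groups_three_df(self):
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert res.df == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_give_z0_p1(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = dunn_pairwise([g, list(g), list(g)])
        off_diag = res.dunn_z.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 0.0)
        assert np.allclose(res.dunn_p.to_numpy()[~np.eye(3, dtype=bool)], 1.0)

    def test_matrix_symmetry_and_empty_diagonal(self):
        rng = np.random.default_rng(9)
        groups = [list(rng.normal(size=8)), list(rng.normal(1, 1, size=10)),
                  list(rng.normal(2, 1, size=6))]
        res = dunn_pairwise(groups)
        z = res.dunn_z.to_numpy()
        p = res.dunn_p.to_numpy()
        assert np.allclose(z, -z.T, equal_nan=True) or np.allclose(
            z[~np.isnan(z)], -z.T[~np.isnan(z.T)]
        )
        assert np.allclose(p[~np.eye(3, dtype=bool)], p.T[~np.eye(3, dtype=bool)])
        assert np.all(np.isnan(np.diag(z)))

    def test_matches_mean_rank_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            groups = [rng.integers(0, 5, size=rng.integers(6, 12)).astype(float)
                      for _ in range(3)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            res = dunn_pairwise(groups)
            for i, j in itertools.combinations(range(3), 2):
                z_expected = dunn_z_oracle(groups, i, j)
                assert res.dunn_z.iloc[i, j] == pytest.approx(z_expected, abs=1e-9)

    def test_holm_adjustment_is_monotone(self):
        rng = np.random.default_rng(21)
        groups = [list(rng.normal(size=12)), list(rng.normal(0.5, 1, size=12)),
                  list(rng.normal(2, 1, size=12))]
        raw = dunn_pairwise(groups, adjust="none")
        holm = dunn_pairwise(groups, adjust="holm")
        for i, j in itertools.combinations(range(3), 2):
            assert holm.dunn_p.iloc[i, j] >= raw.dunn_p.iloc[i, j] - 1e-12


class TestPipelineTables:
    @pytest.fixture
    def assigned(self):
        records = [
            make_record("p1", list("abcde"), category="alcohol", intensity=4),
            make_record("p2", list("abcde"), category="tobacco", intensity=2),
            make_record("p3", list("abcde"), category="gaming", intensity=4),
            make_record("p4", list("abcde"), category="eating", intensity=1),
        ]
        corpus = Corpus(records=records)
        assignments = {"p1": 0, "p2": 1, "p3": 0, "p4": None}
        return corpus, assignments

    def test_misuse_table_counts(self, assigned):
        corpus, asg = assigned
        table = misuse_by_module_table(corpus, asg, PipelineConfig())
        assert table.loc["substance", 0] == 1
        assert table.loc["substance", 1] == 1
        assert table.loc["behavior", 0] == 1
        assert int(table.to_numpy().sum()) == 3  # unassigned p4 excluded

    def test_intensity_table_by_kind(self, assigned):
        corpus, asg = assigned
        table = intensity_by_module_table(
            corpus, asg, PipelineConfig(), kind="substance"
        )
        assert table.loc["high", 0] == 1 and table.loc["low", 1] == 1

    def test_emotion_group_tests_structure(self):
        rng = np.random.default_rng(33)
        records = []
        for i in range(40):
            lab = ("joy", "worries") if i % 2 else ("shame", "anxiety")
            records.append(
                make_record(f"p{i}", [f"t{i % 4}", f"u{i}", f"v{i}", f"w{i}", f"x{i}"],
                            labels=tuple(lab for _ in range(5))))
        corpus = Corpus(records=records)
        asg = {f"p{i}": i % 2 for i in range(40)}
        out = emotion_group_tests(
            corpus, asg, ["joy", "worries", "shame"], PipelineConfig()
        )
        assert set(out) == {"joy", "worries", "shame"}
        res = out["joy"]
        assert res.df == 1 and res.dunn_p is not None
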