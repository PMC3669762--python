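import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matbin import ecostats as es
from matbin import ordination as od
from matbin import synthetic_data as sd

counts_strategy = st.lists(st.integers(min_value=1, max_value=50), min_size=2, max_size=30)


# ---------------------------------------------------------------------------
# Gower


def toy_env():
    return pd.DataFrame(
        {"x": [0.0, 5.0, 10.0], "c": ["red", "red", "blue"]},
        index=["A", "B", "C"],
    )


class TestGower:
    def test_identical_rows_zero(self):
        env = pd.DataFrame({"x": [1.0, 1.0, 2.0], "c": ["a", "a", "b"]})
        D = es.gower_distance(env)
        assert D.iloc[0, 1] == 0.0

    def test_single_categorical_mismatch_is_one(self):
        env = pd.DataFrame({"c": ["a", "b"]})
        assert es.gower_distance(env).iloc[0, 1] == 1.0

    def test_hand_computed_three_sites(self):
        # x range 10: delta(A,B)=0.5, delta(A,C)=1.0, delta(B,C)=0.5
        # c: delta(A,B)=0, delta(A,C)=1, delta(B,C)=1; averaged over 2 vars
        D = es.gower_distance(toy_env())
        assert D.loc["A", "B"] == pytest.approx(0.25)
        assert D.loc["A", "C"] == pytest.approx(1.0)
        assert D.loc["B", "C"] == pytest.approx(0.75)

    def test_min_max_pair_contribution_one(self):
        env = pd.DataFrame({"x": [0.0, 10.0, 5.0]})
        assert es.gower_distance(env).iloc[0, 1] == pytest.approx(1.0)

    def test_missing_value_drops_weight(self):
        env = pd.DataFrame({"x": [0.0, 5.0, 10.0], "c": ["red", None, "blue"]},
                           index=["A", "B", "C"])
        D = es.gower_distance(env)
        assert D.loc["A", "B"] == pytest.approx(0.5)  # numeric only

    def test_zero_range_variable_ignored(self):
        env = pd.DataFrame({"x": [1.0, 1.0], "c": ["a", "b"]})
        assert es.gower_distance(env).iloc[0, 1] == 1.0

    def test_no_comparable_pair_errors(self):
        env = pd.DataFrame({"x": [1.0, np.nan, 2.0], "y": [np.nan, 1.0, 2.0]},
                           index=["A", "B", "C"])
        with pytest.raises(ValueError, match="comparable"):
            es.gower_distance(env)

    def test_pseudo_metric_on_random_complete_data(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            env = pd.DataFrame({
                "a": rng.normal(size=6),
                "b": rng.normal(size=6),
                "c": rng.choice(["x", "y", "z"], size=6),
            })
            D = es.gower_distance(env).to_numpy()
            assert np.allclose(D, D.T)
            assert np.all(np.diag(D) == 0)
            assert D.min() >= 0 and D.max() <= 1 + 1e-12
            # triangle inequality holds without missing data
            for i in range(6):
                for j in range(6):
                    for k in range(6):
                        assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


# ---------------------------------------------------------------------------
# envfit


class TestEnvFit:
    def test_variable_identical_to_axis(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(12, 2))
        env = pd.DataFrame({"v": scores[:, 0]})
        fit = es.fit_env_variables(scores, env, n_permutations=999, seed=0)
        assert fit.r_squared("v") == pytest.approx(1.0)
        assert fit.p_value("v") <= 0.01

    def test_constant_variable(self):
        scores = np.random.default_rng(2).normal(size=(10, 2))
        env = pd.DataFrame({"v": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            fit = es.fit_env_variables(scores, env, n_permutations=99, seed=0)
        assert fit.r_squared("v") == 0.0

    def test_factor_fit_perfect_separation(self):
        scores = np.array([[0.0, 0], [0.1, 0], [5.0, 0], [5.1, 0],
                           [0.05, 0], [5.05, 0]])
        env = pd.DataFrame({"f": ["a", "a", "b", "b", "a", "b"]})
        fit = es.fit_env_variables(scores, env, n_permutations=99, seed=0)
        assert fit.r_squared("f") > 0.99
        assert set(fit.variables["f"]["centroids"]) == {"a", "b"}

    def test_p_value_bounds(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(10, 2))
        env = pd.DataFrame({"v": rng.normal(size=10)})
        fit = es.fit_env_variables(scores, env, n_permutations=99, seed=1)
        assert 1 / 100 <= fit.p_value("v") <= 1.0

    def test_too_few_sites_errors(self):
        with pytest.raises(ValueError, match="axes"):
            es.fit_env_variables(np.zeros((3, 3)), pd.DataFrame({"v": [1.0, 2, 3]}))

    def test_null_p_uniform_small(self):
        # 200-rep sanity version of the acceptance-scale null simulation
        ps = []
        for rep in range(200):
            env, _ = sd.generate_env_matrix(10, n_numeric=4, n_factor=0,
                                            effect_axis=0.0, seed=rep)
            D = es.gower_distance(env.drop(columns=["num_0"]))
            scores = od.pcoa(D, n_axes=2).scores
            fit = es.fit_env_variables(scores, env[["num_0"]],
                                       n_permutations=199, seed=5_000 + rep)
            ps.append(fit.p_value("num_0"))
        frac = np.mean(np.asarray(ps) <= 0.05)
        assert abs(frac - 0.05) <= 0.04


# ---------------------------------------------------------------------------
# diversity indices


class TestChao1:
    def test_closed_form(self):
        # S=3, f1=2, f2=1 -> 3 + 4/2 = 5
        assert es.chao1({"a": 1, "b": 1, "c": 2}) == pytest.approx(5.0)

    def test_no_singletons(self):
        assert es.chao1([2, 3, 4]) == 3.0

    def test_bias_corrected_single_singleton(self):
        assert es.chao1({"a": 1}) == pytest.approx(1.0)

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_at_least_s_obs_and_label_invariant(self, counts):
        v = es.chao1(counts)
        assert v >= len(counts)
        assert v == es.chao1(list(reversed(counts)))


def ace_textbook(counts, cutoff=10):
    """Independent recomputation of classic ACE from the textbook formula."""
    n = np.asarray(counts)
    n = n[n > 0]
    rare = n[n <= cutoff]
    s_abund = np.sum(n > cutoff)
    s_rare = rare.size
    n_rare = rare.sum()
    f1 = np.sum(rare == 1)
    c = 1 - f1 / n_rare
    gamma2 = max(
        (s_rare / c)
        * sum(i * (i - 1) * np.sum(rare == i) for i in range(1, cutoff + 1))
        / (n_rare * (n_rare - 1))
        - 1,
        0,
    )
    return s_abund + s_rare / c + f1 / c * gamma2


class TestACE:
    def test_all_abundant_equals_s_obs(self):
        assert es.ace([11, 20, 30]) == 3.0

    def test_matches_textbook_formula(self):
        counts = [1, 1, 2, 3, 4, 5, 7, 10, 15, 40, 2, 1]
        assert es.ace(counts) == pytest.approx(ace_textbook(counts))

    def test_all_singletons_falls_back_to_chao1(self):
        counts = [1, 1, 1, 1]
        with pytest.warns(UserWarning, match="Chao1"):
            v = es.ace(counts)
        assert v == pytest.approx(es.chao1(counts))

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_at_least_s_obs(self, counts):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert es.ace(counts) >= len(counts) - 1e-9


class TestShannonSimpson:
    def test_uniform_four_species(self):
        assert es.shannon([5, 5, 5, 5]) == pytest.approx(math.log(4))
        assert es.simpson_reciprocal([5, 5, 5, 5]) == pytest.approx(4.0)

    def test_single_species(self):
        assert es.shannon([7]) == 0.0
        assert es.simpson_reciprocal([7]) == pytest.approx(1.0)

    def test_log2_flag(self):
        assert es.shannon([1, 1], base=2) == pytest.approx(1.0)

    @given(counts_strategy)
    @settings(max_examples=50, deadline=None)
    def test_simpson_bounds_and_label_invariance(self, counts):
        v = es.simpson_reciprocal(counts)
        assert 1.0 - 1e-9 <= v <= len(counts) + 1e-9
        assert v == pytest.approx(es.simpson_reciprocal(list(reversed(counts))))


class TestFisherAlpha:
    def test_back_substitution(self):
        counts = np.ones(10, dtype=int) * 10  # S=10, N=100
        alpha = es.fisher_alpha(counts)
        assert abs(alpha * math.log1p(100 / alpha) - 10) < 1e-9

    def test_every_individual_unique_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            es.fisher_alpha([1, 1, 1])

    @given(st.integers(2, 30), st.integers(2, 50))
    @settings(max_examples=30, deadline=None)
    def test_residual_property(self, s, mult):
        counts = [mult] * s  # N = s * mult > S
        alpha = es.fisher_alpha(counts)
        N = s * mult
        assert abs(alpha * math.log1p(N / alpha) - s) < 1e-9


class TestRarefaction:
    def test_full_depth_gives_s_obs(self):
        counts = [4, 3, 2, 1]
        curve = es.rarefaction(counts, [10])
        assert curve[0][1] == pytest.approx(4.0)

    def test_depth_one(self):
        assert es.rarefaction([5, 5], [1])[0][1] == pytest.approx(1.0)

    def test_depth_exceeding_total_errors(self):
        with pytest.raises(ValueError):
            es.rarefaction([2, 2], [5])

    def test_monotone_nondecreasing(self):
        counts = [10, 6, 3, 1, 1, 1]
        curve = es.rarefaction(counts, range(1, 23))
        values = [v for _, v in curve]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] <= len(counts) + 1e-12

    def test_matches_monte_carlo(self):
        counts = np.array([8, 5, 3, 2, 1, 1])
        N = counts.sum()
        m = 10
        expected = es.rarefaction(counts, [m])[0][1]
        rng = np.random.default_rng(42)
        pool = np.repeat(np.arange(len(counts)), counts)
        obs = np.array([
            len(np.unique(rng.choice(pool, size=m, replace=False)))
            for _ in range(10_000)
        ])
        se = obs.std(ddof=1) / math.sqrt(len(obs))
        assert abs(obs.mean() - expected) <= 3 * se


class TestDiversityReport:
    def test_report_invariants(self):
        counts = {"a": 10, "b": 5, "c": 2, "d": 1, "e": 1}
        rep = es.diversity_report(counts)
        assert rep.s_obs == 5
        assert rep.chao1 >= rep.s_obs and rep.ace >= rep.s_obs
        assert 1 <= rep.simpson_reciprocal <= rep.s_obs
        depths = [m for m, _ in rep.rarefaction_curve]
        assert depths == sorted(depths)

    def test_fisher_alpha_none_when_undefined(self):
        rep = es.diversity_report([1, 1])
        assert rep.fisher_alpha is None


class TestEnvTableParsing:
    def test_below_detection_rule(self, tmp_path):
        p = tmp_path / "env.tsv"
        p.write_text("site\tT\tAs\nA\t60\t<3\nB\t70\t8\n")
        df, notes = es.read_env_table(p)
        assert df.loc["A", "As"] == pytest.approx(1.5)
        assert any("below-detection" in n for n in notes)

    def test_schema_forces_factor(self, tmp_path):
        p = tmp_path / "env.tsv"
        p.write_text("site\tcode\nA\t1\nB\t2\n")
        df, _ = es.read_env_table(p, schema={"code": "factor"})
        assert df["code"].dtype == object
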