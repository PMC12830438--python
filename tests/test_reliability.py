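"""Split-half, Spearman-Brown, alpha/KR-20, down-sampling grid, test-retest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rsvpdi import cohort, reliability, scoring
from rsvpdi.errors import ConfigurationError, UndefinedResultError
from conftest import kr20


class TestSplitHalf:
    def test_identical_halves_correlate_perfectly(self):
        half = np.random.default_rng(0).integers(0, 2, size=(10, 6))
        mat = np.empty((10, 12), dtype=int)
        mat[:, 0::2] = half  # even indices = first half
        mat[:, 1::2] = half
        assert reliability.split_half(mat) == pytest.approx(1.0)

    def test_proportional_deterministic_outcomes(self):
        """Propensities {.1,.3,.5,.7,.9} realized exactly in both halves give
        r_half = 1."""
        rows = []
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            ones = int(p * 10)
            half = [1] * ones + [0] * (10 - ones)
            row = np.empty(20, dtype=int)
            row[0::2] = half
            row[1::2] = half
            rows.append(row)
        assert reliability.split_half(np.array(rows)) == pytest.approx(1.0)

    def test_zero_variance_half_is_undefined(self):
        mat = np.zeros((5, 8), dtype=int)
        with pytest.raises(UndefinedResultError):
            reliability.split_half(mat)

    def test_attenuation_formula_oracle(self):
        """Observed r_half for 200 binomial participants matches the
        attenuation identity var(p) / (var(p) + E[p(1-p)]/(t/2))."""
        rng = np.random.default_rng(12)
        p = np.clip(rng.normal(0.3, 0.2, 200), 0.01, 0.95)
        mat = (rng.random((200, 80)) < p[:, None]).astype(int)
        predicted = p.var(ddof=1) / (p.var(ddof=1) + (p * (1 - p)).mean() / 40)
        assert reliability.split_half(mat) == pytest.approx(predicted, abs=0.05)

    def test_random_scheme_requires_rng_and_reproduces(self):
        rng_mat = np.random.default_rng(3)
        p = np.clip(rng_mat.normal(0.3, 0.2, 50), 0.01, 0.95)
        mat = (rng_mat.random((50, 40)) < p[:, None]).astype(int)
        with pytest.raises(ConfigurationError):
            reliability.split_half(mat, scheme="random")
        r1 = reliability.split_half(mat, "random", np.random.default_rng(9))
        r2 = reliability.split_half(mat, "random", np.random.default_rng(9))
        assert r1 == r2


class TestSpearmanBrown:
    @pytest.mark.parametrize("r,expected", [(0.0, 0.0), (1.0, 1.0),
                                            (0.9 / (2 - 0.9), 0.90)])
    def test_values(self, r, expected):
        assert reliability.spearman_brown(r) == pytest.approx(expected, abs=1e-12)

    def test_boundary_undefined(self):
        with pytest.raises(UndefinedResultError):
            reliability.spearman_brown(-1.0)

    @given(st.floats(-0.999, 0.998))
    @settings(deadline=None, max_examples=100)
    def test_strictly_increasing_and_maps_unit_interval(self, r):
        eps = 1e-3
        assert reliability.spearman_brown(r + eps) > reliability.spearman_brown(r)
        if 0.0 <= r <= 1.0:
            assert 0.0 <= reliability.spearman_brown(r) <= 1.0


class TestCronbachAlpha:
    def test_perfectly_correlated_items(self):
        col = np.array([0, 0, 1, 1, 0, 1])[:, None]
        mat = np.repeat(col, 5, axis=1)
        assert reliability.cronbach_alpha(mat) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        """Independent fair-coin items carry no shared signal: alpha ~ 0 at
        n = 5,000, k = 40."""
        mat = (np.random.default_rng(7).random((5000, 40)) < 0.5).astype(int)
        assert abs(reliability.cronbach_alpha(mat)) < 0.05

    def test_hand_built_matrix_equals_kr20(self):
        mat = np.array([[1, 0, 1], [1, 1, 1], [0, 0, 1], [0, 1, 0]])
        assert reliability.cronbach_alpha(mat) == pytest.approx(kr20(mat), abs=1e-12)

    @given(arrays(np.int8, (6, 5), elements=st.integers(0, 1)))
    @settings(deadline=None, max_examples=200)
    def test_alpha_equals_kr20_on_binary_matrices(self, mat):
        """On every binary matrix with total-score variance, alpha is exactly
        KR-20 (independent implementation in conftest)."""
        if np.asarray(mat).sum(axis=1).var(ddof=1) == 0:
            return
        assert reliability.cronbach_alpha(mat) == pytest.approx(kr20(mat), abs=1e-10)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(UndefinedResultError):
            reliability.cronbach_alpha(np.ones((5, 4), dtype=int))


@pytest.fixture(scope="module")
def fixture_matrix():
    rng = np.random.default_rng(8)
    p = np.clip(rng.normal(0.35, 0.2, 6), 0.05, 0.9)
    return (rng.random((6, 8)) < p[:, None]).astype(int)


class TestDownsampleGrid:
    def test_full_cell_reproduces_full_sample_statistics(self, fixture_matrix):
        grid = reliability.downsample_grid(fixture_matrix, [6], [8], iterations=5, seed=1)
        full_r = reliability.spearman_brown(reliability.split_half(fixture_matrix))
        full_a = reliability.cronbach_alpha(fixture_matrix)
        assert grid.mean_r_sb[0, 0] == pytest.approx(full_r, abs=1e-12)
        assert grid.mean_alpha[0, 0] == pytest.approx(full_a, abs=1e-12)
        assert grid.valid_iterations[0, 0] == 5

    def test_matches_brute_force_enumerator(self, fixture_matrix):
        """An independent re-implementation of the sampling loop (same per-cell
        seed stream, subsampling, KR-20 and corrcoef formulas) reproduces the
        grid exactly."""
        seed, iters = 123, 3
        grid = reliability.downsample_grid(fixture_matrix, [4], [4],
                                           iterations=iters, seed=seed)

        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0, 0)))
        r_vals, a_vals = [], []
        for _ in range(iters):
            rows = np.sort(rng.choice(6, size=4, replace=False))
            cols = np.sort(rng.choice(8, size=4, replace=False))
            sub = fixture_matrix[np.ix_(rows, cols)].astype(float)
            h1 = sub[:, [0, 2]].mean(axis=1)
            h2 = sub[:, [1, 3]].mean(axis=1)
            if h1.std(ddof=1) > 0 and h2.std(ddof=1) > 0:
                r = np.corrcoef(h1, h2)[0, 1]
                if r > -1:
                    r_vals.append(2 * r / (1 + r))
            if sub.sum(axis=1).var(ddof=1) > 0:
                a_vals.append(kr20(sub))
        expect_r = np.mean(r_vals) if r_vals else np.nan
        expect_a = np.mean(a_vals) if a_vals else np.nan
        assert grid.valid_r_sb[0, 0] == len(r_vals)
        assert grid.valid_alpha[0, 0] == len(a_vals)
        np.testing.assert_allclose(grid.mean_r_sb[0, 0], expect_r, atol=1e-12)
        np.testing.assert_allclose(grid.mean_alpha[0, 0], expect_a, atol=1e-12)

    def test_grid_shape_and_bounds(self, di_matrix_100x80):
        grid = reliability.downsample_grid(di_matrix_100x80, [10, 20], [20, 40, 60],
                                           iterations=10, seed=2)
        assert grid.mean_r_sb.shape == (2, 3)
        assert (grid.valid_iterations <= 10).all()
        df = grid.to_frame()
        assert len(df) == 6 and set(df["n"]) == {10, 20}

    def test_mean_reliability_nondecreasing_in_trials(self, di_matrix_100x80):
        """For fixed n, mean corrected reliability grows with trial count up
        to Monte-Carlo noise."""
        grid = reliability.downsample_grid(di_matrix_100x80, [40], [20, 40, 60, 80],
                                           iterations=60, seed=3)
        vals = grid.mean_r_sb[0]
        assert all(vals[i + 1] > vals[i] - 0.03 for i in range(len(vals) - 1))

    def test_oversized_request_rejected(self, di_matrix_100x80):
        with pytest.raises(ConfigurationError):
            reliability.downsample_grid(di_matrix_100x80, [200], [20], seed=0)


class TestRetest:
    def test_identical_scores_give_unity(self):
        s = pd.DataFrame({"participant_id": list("abcde"), "di_rate": [.1, .2, .3, .4, .5]})
        assert reliability.retest_reliability(s, s)["r"] == pytest.approx(1.0)

    def test_independent_sessions_near_zero(self):
        rng = np.random.default_rng(10)
        pids = [f"P{i:04d}" for i in range(2000)]
        s1 = pd.DataFrame({"participant_id": pids, "di_rate": rng.random(2000)})
        s2 = pd.DataFrame({"participant_id": pids, "di_rate": rng.random(2000)})
        assert abs(reliability.retest_reliability(s1, s2)["r"]) < 0.05

    def test_too_few_pairs_rejected(self):
        s1 = pd.DataFrame({"participant_id": ["a", "b"], "di_rate": [.1, .2]})
        with pytest.raises(ConfigurationError):
            reliability.retest_reliability(s1, s1)

    def test_default_cohort_retest_in_expected_band(self):
        """With stable latent propensities and 60 trials per session, observed
        DI-rate stability lands in [.85, .95], per the attenuation identity
        rho ~ var(p) / (var(p) + E[p(1-p)]/60)."""
        profs = cohort.gen_profiles(cohort.GeneratorConfig(n_participants=1000, seed=20))
        t1 = cohort.gen_di_trials(profs, 60, session=1, seed=20)
        t2 = cohort.gen_di_trials(profs, 60, session=2, seed=20)
        r = reliability.retest_reliability(
            scoring.score_di_trials(t1), scoring.score_di_trials(t2))["r"]
        assert 0.85 <= r <= 0.95


class TestSplitHalfDerived:
    def test_derived_blink_halves_scored_fully(self, small_profiles):
        """Each half is scored completely (lag7 - lag3 within the half) before
        correlating, so the derived split-half runs end to end."""
        trials = cohort.gen_ab_trials(small_profiles, 96, seed=30)
        dual = trials[trials["trial_type"] == "dual"]
        res = reliability.split_half_derived(
            dual, lambda df: scoring.ab_scores(df).set_index("participant_id")["ab_magnitude"])
        assert -1.0 <= res.r_half <= 1.0
        assert res.r_sb == pytest.approx(2 * res.r_half / (1 + res.r_half))
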