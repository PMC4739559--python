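import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodem.correlate import permutation_pvalue, run_study, spearman
from phylodem.simulate import StudyConfig, simulate_study


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 7.0, 9.0, 20.0])
        assert spearman(x, x**3) == pytest.approx(1.0)
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import spearmanr

        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12) + 0.5 * x
            assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_ties_use_midranks(self):
        from scipy.stats import spearmanr

        x = [1.0, 1.0, 2.0, 3.0, 3.0, 3.0]
        y = [2.0, 1.0, 5.0, 4.0, 4.0, 9.0]
        assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic)

    def test_constant_vector_undefined(self):
        assert math.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @given(st.sampled_from([np.exp, np.cbrt, lambda v: 5 * v + 2]))
    @settings(max_examples=10, deadline=None)
    def test_invariant_under_monotone_transform(self, f):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        assert spearman(x, y) == pytest.approx(spearman(f(x), y), abs=1e-12)


class TestPermutationPvalue:
    def test_minimum_attainable_p(self):
        x = np.arange(12.0)
        rho, p = permutation_pvalue(x, x**2, reps=9999, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 10000)

    def test_fixed_seed_reproducible(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert permutation_pvalue(x, y, seed=42) == permutation_pvalue(x, y, seed=42)

    def test_type_one_error_calibrated(self):
        # independent x, y: rejection rate at alpha=0.05 near nominal
        rng = np.random.default_rng(11)
        reps, rejections = 500, 0
        for _ in range(reps):
            x = rng.normal(size=16)
            y = rng.normal(size=16)
            _, p = permutation_pvalue(x, y, reps=999, seed=rng)
            if p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.08

    def test_reps_floor_enforced(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2, 3], [1, 2, 3], reps=10)


@pytest.fixture(scope="module")
def small_study():
    config = StudyConfig(n_populations=8, n_range=(10, 30))
    return simulate_study(config, seed=3)


class TestRunStudy:
    def test_per_population_table_complete(self, small_study):
        result = run_study(small_study, seed=3, neutrality_reps=100)
        frame = result.per_population
        assert len(frame) == 8
        for col in ("h", "p", "pi", "S", "D", "Fs", "tau", "tmrca", "t_max_kya"):
            assert col in frame.columns
        assert frame["h"].between(0, 1).all()

    def test_same_seed_identical_bundle(self, small_study):
        r1 = run_study(small_study, seed=5, neutrality_reps=100)
        r2 = run_study(small_study, seed=5, neutrality_reps=100)
        assert r1.per_population.equals(r2.per_population)
        assert [
            (c.metric, c.covariate, c.rho, c.p_perm) for c in r1.correlations
        ] == [(c.metric, c.covariate, c.rho, c.p_perm) for c in r2.correlations]

    def test_tiny_population_flagged_not_fatal(self):
        config = StudyConfig(n_populations=3, n_range=(3, 3))
        ds = simulate_study(config, seed=21)
        result = run_study(ds, seed=21, neutrality_reps=100)
        frame = result.per_population
        assert (frame["n"] == 3).all()
        assert frame["h"].notna().all()  # diversity still computed
        assert "D" not in frame.columns or frame["D"].isna().all()

    def test_pulse_concentration_recovers_common_expansion_time(self):
        # 12-population studies, all suddenly expanded at the same tau:
        # the pooled t_max values concentrate within +-50% of the true
        # expansion time (strong-expansion regime, theta1 >> tau)
        from phylodem.clock import ClockConfig, calibrate, classic_skyline, clock_tree
        from phylodem.growth import growth_rate_series, max_growth

        cfg = ClockConfig()
        tau = 5.0
        T_kya = tau / (2 * cfg.lineage_rate_per_year * 1140) / 1000.0
        hits = total = 0
        for rep in range(200):
            sc = StudyConfig(
                n_populations=12,
                n_range=(20, 40),
                tau=tau,
                expansion_fraction=1.0,
                theta_ratio=0.01,
                link_intercept=-1.386,  # theta1 ~ 15-120 across the gradient
            )
            ds = simulate_study(sc, seed=9000 + rep)
            for _, aln in ds.populations:
                tree = clock_tree(aln)
                if tree.tmrca == 0:
                    continue
                traj = classic_skyline(calibrate(tree, cfg))
                profile = growth_rate_series(traj)
                t_max, _, _ = max_growth(profile)
                if math.isfinite(t_max):
                    total += 1
                    if 0.5 * T_kya <= t_max <= 1.5 * T_kya:
                        hits += 1
        assert hits / total >= 0.60
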