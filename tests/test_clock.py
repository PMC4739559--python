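import numpy as np
import pytest

from phylodem.clock import (
    ClockConfig,
    calibrate,
    classic_skyline,
    clock_tree,
    tmrca_kya,
)
from phylodem.genealogy import Genealogy, Node
from phylodem.simulate import Demography, mutate, simulate_genealogy

from conftest import alignment_from_seqs, random_alignment


def two_tip_tree(depth: float) -> Genealogy:
    return Genealogy(
        Node(height=depth, children=[Node(label="a"), Node(label="b")])
    )


class TestClockTree:
    def test_pair_root_at_half_distance(self):
        a = alignment_from_seqs("AAAA", "AAAT")  # p-distance 0.25
        assert clock_tree(a).tmrca == pytest.approx(0.125)

    def test_three_taxon_average_linkage(self):
        # d(A,B)=0.01, d(A,C)=d(B,C)=0.02 over 100 sites
        ref = "A" * 100
        b = "T" + ref[1:]
        c = "G" + "T" + ref[2:]
        a = alignment_from_seqs(ref, b, c)
        tree = clock_tree(a)
        assert tree.tmrca == pytest.approx(0.01)
        assert sorted(tree.coalescent_times()) == pytest.approx([0.005, 0.01])
        # topology: the cherry is (s0, s1)
        cherry = min(
            (n for n in tree.preorder() if not n.is_leaf), key=lambda n: n.height
        )
        assert sorted(t.label for t in cherry.children) == ["s0", "s1"]

    def test_matches_bruteforce_average_linkage(self, rng):
        # naive oracle: recompute every cluster distance from the original
        # matrix at every step
        from phylodem.clock import p_distance_matrix

        for trial in range(5):
            a = random_alignment(rng, 8, 40)
            d = p_distance_matrix(a)
            clusters = [frozenset([i]) for i in range(8)]
            heights = {}
            labels = {frozenset([i]): a.ids[i] for i in range(8)}
            while len(clusters) > 1:
                best = None
                for x in range(len(clusters)):
                    for y in range(x + 1, len(clusters)):
                        cx, cy = clusters[x], clusters[y]
                        avg = np.mean([d[i, j] for i in cx for j in cy])
                        key = (avg, *sorted((labels[cx], labels[cy])))
                        if best is None or key < best[0]:
                            best = (key, x, y)
                _, x, y = best
                cx, cy = clusters[x], clusters[y]
                merged = cx | cy
                heights[merged] = best[0][0] / 2.0
                labels[merged] = min(labels[cx], labels[cy])
                clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
                clusters.append(merged)
            tree = clock_tree(a)
            assert sorted(tree.coalescent_times()) == pytest.approx(
                sorted(heights.values()), abs=1e-12
            )


class TestTmrca:
    def test_calibration_of_one_myr_root(self):
        # root height 0.0091 subs/site at 0.91%/Myr per lineage -> 1 Myr
        assert tmrca_kya(two_tip_tree(0.0091), ClockConfig(0.0182)) == pytest.approx(
            1000.0
        )

    def test_zero_depth(self):
        assert tmrca_kya(two_tip_tree(0.0)) == 0.0

    def test_lineage_rate_is_half_divergence_rate(self):
        cfg = ClockConfig(divergence_rate=0.02)
        assert cfg.lineage_rate == 0.01

    def test_simulation_recovery_within_quarter(self, rng):
        # E[TMRCA] = 2(1 - 1/n) coalescent units; one unit spans
        # theta / (2 u_seq) years under the clock
        n, theta, L = 25, 10.0, 1140
        cfg = ClockConfig()
        unit_years = theta / (2 * cfg.lineage_rate_per_year * L)
        expected = 2 * (1 - 1 / n) * unit_years
        estimates = []
        for _ in range(100):
            g = simulate_genealogy(n, Demography(model="constant", theta1=theta), rng)
            aln = mutate(g, theta, L, seed=rng)
            estimates.append(tmrca_kya(clock_tree(aln), cfg) * 1000.0)
        assert abs(np.median(estimates) - expected) < 0.25 * expected


class TestClassicSkyline:
    def test_pair_single_interval(self):
        traj = classic_skyline(two_tip_tree(4000.0), grid_step=1000.0)
        assert np.allclose(traj.step_values, [4000.0])  # k(k-1)/2 = 1
        assert traj.times[0] == 0.0

    def test_infinite_epsilon_pools_everything(self, rng):
        g = simulate_genealogy(10, Demography(), rng).scaled(1e4)
        traj = classic_skyline(g, epsilon=np.inf, grid_step=1000.0)
        assert traj.step_values.size == 1
        expected = np.mean(
            [k * (k - 1) * w / 2.0 for k, w in g.coalescent_intervals()]
        )
        assert traj.step_values[0] == pytest.approx(expected)

    def test_resampling_preserves_step_values_at_midpoints(self):
        tree = Genealogy(
            Node(
                height=5000.0,
                children=[
                    Node(
                        height=2000.0,
                        children=[Node(label="a"), Node(label="b")],
                    ),
                    Node(label="c"),
                ],
            )
        )
        traj = classic_skyline(tree, grid_step=100.0)
        for i in range(len(traj.step_values)):
            mid = (traj.step_times[i] + traj.step_times[i + 1]) / 2.0
            grid_at_mid = traj.values[np.searchsorted(traj.times, mid) - 1]
            assert grid_at_mid == traj.step_values[i]

    def test_harmonic_mean_consistency_under_constant_size(self, rng):
        # estimator consistency: harmonic mean of the skyline tracks the
        # true (constant) scaled size
        reps, N = 200, 1000.0
        means = []
        for _ in range(reps):
            g = simulate_genealogy(30, Demography(), rng).scaled(N)
            traj = classic_skyline(g, grid_step=N / 100)
            w = np.diff(traj.step_times)
            v = traj.step_values
            means.append(w.sum() / np.sum(w / v))
        assert abs(np.mean(means) - N) / N < 0.15

    def test_trajectory_positive_everywhere(self, rng):
        g = simulate_genealogy(15, Demography(), rng).scaled(5e4)
        traj = classic_skyline(g)
        assert np.all(traj.values > 0)

    def test_expansion_drop_recovered_near_true_time(self, rng):
        # weak-recovery: the largest backward-time decrease of the skyline
        # falls within [T/2, 2T] of the true expansion time in >= 70% of
        # replicates (the surrogate is noisier than a full MCMC skyline)
        demog = Demography(model="sudden_expansion", theta0=0.5, theta1=50.0, tau=5.0)
        cfg = ClockConfig()
        T_years = demog.tau / (2 * cfg.lineage_rate_per_year * 1140)
        hits, reps = 0, 200
        for _ in range(reps):
            g = simulate_genealogy(30, demog, rng)
            aln = mutate(g, demog.theta1, 1140, seed=rng)
            tree = calibrate(clock_tree(aln), cfg)
            traj = classic_skyline(tree)
            v, t = traj.step_values, traj.step_times
            if v.size < 2:
                continue
            drops = np.log(v[:-1] / v[1:])
            t_drop = t[np.argmax(drops) + 1]
            if 0.5 * T_years <= t_drop <= 2.0 * T_years:
                hits += 1
        assert hits / reps >= 0.70
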