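import numpy as np
import pytest

from phylodem.diversity import mean_pairwise_differences
from phylodem.genealogy import Genealogy, Node
from phylodem.io import write_fasta
from phylodem.neutrality import tajimas_d_from_counts
from phylodem.simulate import (
    Demography,
    StudyConfig,
    mutate,
    mutate_infinite_sites,
    simulate_genealogy,
    simulate_study,
)


def pairwise_k_hat(geno: np.ndarray) -> float:
    n = geno.shape[0]
    derived = geno.sum(axis=0)
    return float(np.sum(derived * (n - derived))) / (n * (n - 1) / 2.0)


class TestGenealogy:
    def test_pair_tmrca_mean_is_one(self, rng):
        reps = 5000
        t2 = np.array(
            [simulate_genealogy(2, Demography(), rng).tmrca for _ in range(reps)]
        )
        se = t2.std() / np.sqrt(reps)
        assert abs(t2.mean() - 1.0) < 3 * se

    def test_event_count_is_n_minus_one(self, rng):
        g = simulate_genealogy(10, Demography(), rng)
        assert len(g.coalescent_times()) == 9
        assert g.n_tips == 10

    def test_expansion_makes_genealogy_starlike(self, rng):
        reps = 2000
        expanded = Demography(model="sudden_expansion", theta0=0.5, theta1=50.0, tau=5.0)
        constant = Demography(model="constant", theta1=50.0)

        def mean_external_ratio(demog):
            vals = []
            for _ in range(reps):
                g = simulate_genealogy(20, demog, rng)
                vals.append(g.external_branch_length() / g.total_branch_length())
            return np.mean(vals)

        assert mean_external_ratio(expanded) > mean_external_ratio(constant)

    def test_requires_two_tips(self):
        with pytest.raises(ValueError):
            simulate_genealogy(1, Demography(), seed=0)

    def test_matches_msprime_tmrca_distribution(self, rng):
        # independent coalescent oracle: same model, same time scale
        msprime = pytest.importorskip("msprime")
        reps = 500
        ours = np.array(
            [simulate_genealogy(10, Demography(), rng).tmrca for _ in range(reps)]
        )
        theirs = np.array(
            [
                ts.max_root_time
                for ts in msprime.sim_ancestry(
                    samples=10,
                    ploidy=1,
                    population_size=1.0,
                    num_replicates=reps,
                    random_seed=1234,
                )
            ]
        )
        pooled_se = np.sqrt(ours.var() / reps + theirs.var() / reps)
        assert abs(ours.mean() - theirs.mean()) < 3 * pooled_se


class TestMutate:
    def test_segregating_sites_near_watterson(self, rng):
        # finite sites at L=1140 sit within sampling error of the
        # infinite-sites expectation theta * a1 at this depth
        reps, n, theta = 2000, 30, 5.0
        S = np.empty(reps)
        for r in range(reps):
            g = simulate_genealogy(n, Demography(model="constant", theta1=theta), rng)
            _, geno = mutate_infinite_sites(g, theta, rng)
            S[r] = geno.shape[1]
        a1 = np.sum(1.0 / np.arange(1, n))
        se = S.std() / np.sqrt(reps)
        assert abs(S.mean() - theta * a1) < 3 * se

    def test_mean_pairwise_differences_near_theta(self, rng):
        reps, n, theta = 300, 30, 5.0
        k = np.empty(reps)
        for r in range(reps):
            g = simulate_genealogy(n, Demography(model="constant", theta1=theta), rng)
            a = mutate(g, theta, 1140, seed=rng)
            k[r] = mean_pairwise_differences(a)
        se = k.std() / np.sqrt(reps)
        assert abs(k.mean() - theta) < 3 * se

    def test_zero_length_tree_gives_identical_sequences(self, rng):
        root = Node(
            height=0.0, children=[Node(label="a"), Node(label="b")]
        )
        a = mutate(Genealogy(root), theta=5.0, L=50, seed=rng)
        assert a.seqs[0] == a.seqs[1]

    def test_argument_validation(self, rng):
        g = simulate_genealogy(3, Demography(), rng)
        with pytest.raises(ValueError):
            mutate(g, theta=0.0, L=10, seed=rng)
        with pytest.raises(ValueError):
            mutate(g, theta=1.0, L=0, seed=rng)


class TestTajimaCalibration:
    def test_mean_d_under_constant_size(self, rng):
        reps, n, theta = 2000, 30, 5.0
        vals = []
        for _ in range(reps):
            g = simulate_genealogy(n, Demography(model="constant", theta1=theta), rng)
            _, geno = mutate_infinite_sites(g, theta, rng)
            if geno.shape[1] == 0:
                continue
            vals.append(tajimas_d_from_counts(n, geno.shape[1], pairwise_k_hat(geno)))
        assert -0.25 < np.mean(vals) < 0.10

    def test_mean_d_under_sudden_expansion(self, rng):
        reps, n = 2000, 30
        demog = Demography(model="sudden_expansion", theta0=0.5, theta1=50.0, tau=5.0)
        vals = []
        for _ in range(reps):
            g = simulate_genealogy(n, demog, rng)
            _, geno = mutate_infinite_sites(g, demog.theta1, rng)
            if geno.shape[1] == 0:
                continue
            vals.append(tajimas_d_from_counts(n, geno.shape[1], pairwise_k_hat(geno)))
        assert np.mean(vals) < -0.8


class TestStudyGenerator:
    def test_positive_link_orders_truth_theta_by_precipitation(self):
        from phylodem.correlate import spearman

        config = StudyConfig(n_populations=20, link_slope=1.0)
        ds = simulate_study(config, seed=9)
        pops = ds.truth["populations"]
        thetas = [pops[k]["theta"] for k in sorted(pops)]
        precs = [pops[k]["precipitation"] for k in sorted(pops)]
        assert spearman(precs, thetas) == pytest.approx(1.0)

    def test_null_link_gives_uniform_pvalues(self):
        # with slope 0, observed diversity is unrelated to precipitation:
        # the rejection count at alpha=0.05 behaves like Binomial(reps, .05)
        from phylodem.correlate import permutation_pvalue
        from phylodem.diversity import diversity_summary

        reps, rejections = 60, 0
        for r in range(reps):
            ds = simulate_study(
                StudyConfig(n_populations=10, n_range=(8, 20), link_slope=0.0),
                seed=5000 + r,
            )
            h = [diversity_summary(aln).h for _, aln in ds.populations]
            prec = [rec.precipitation for rec, _ in ds.populations]
            _, p = permutation_pvalue(prec, h, reps=999, seed=r)
            if p <= 0.05:
                rejections += 1
        # Binomial(60, 0.05): P(X > 9) < 1e-4
        assert rejections <= 9

    def test_same_seed_is_byte_identical(self, tmp_path):
        config = StudyConfig(n_populations=4, n_range=(5, 15))
        d1 = simulate_study(config, seed=77)
        d2 = simulate_study(config, seed=77)
        for (r1, a1), (r2, a2) in zip(d1.populations, d2.populations):
            p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
            write_fasta(a1, p1)
            write_fasta(a2, p2)
            assert p1.read_bytes() == p2.read_bytes()
        assert d1.truth == d2.truth

    def test_invalid_link_slope_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(link_slope=float("nan"))

    def test_demography_validation(self):
        with pytest.raises(ValueError):
            Demography(model="sudden_expansion", theta0=5.0, theta1=1.0, tau=1.0)
        with pytest.raises(ValueError):
            Demography(model="constant", theta1=-1.0)
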