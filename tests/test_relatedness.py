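"""Estimator checks against Monte-Carlo pedigree truths and brute-force ML."""

import numpy as np
import pandas as pd
import pytest

from codkin import GenotypeMatrix
from codkin import relatedness as rel
from codkin.relatedness import (_qg_batch, _ml_batch, _joint_mode_tensors,
                                _mode_likelihoods, _loglik)
from conftest import gamete, grid_ml, make_families


def matrix(calls, freqs=None):
    calls = np.asarray(calls, dtype=float)
    ids = [f"s{i}" for i in range(calls.shape[0])]
    loci = [f"l{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(ids=np.array(ids, dtype=object),
                          loci=np.array(loci, dtype=object), calls=calls)


class TestAlleleFrequencyEstimation:
    def test_simple_mean(self):
        g = matrix([[0], [1], [2]])
        af = rel.estimate_allele_frequencies(g)
        assert af.values[0] == pytest.approx(0.5)
        assert af.retained[0]

    def test_monomorphic_excluded(self):
        g = matrix([[0, 1], [0, 1], [0, 1]])
        af = rel.estimate_allele_frequencies(g)
        assert not af.retained[0] and np.isnan(af.values[0])
        assert af.retained[1]

    def test_missing_then_fixed_excluded(self):
        g = matrix([[2, 1], [2, 0], [np.nan, 1]])
        af = rel.estimate_allele_frequencies(g)
        assert not af.retained[0]  # f = 1.0 from the two observed calls
        assert af.retained[1]

    def test_missingness_ceiling(self):
        g = matrix([[1, 1], [np.nan, 1], [np.nan, 0], [np.nan, 2]])
        af = rel.estimate_allele_frequencies(g, max_missing=0.5)
        assert not af.retained[0] and af.retained[1]


class TestQuellerGoodnight:
    def test_identical_individuals_r_one(self):
        row = [0, 1, 2, 0, 2, 1, 0, 2]
        g = matrix([row, row])
        est = rel.queller_goodnight_r(g, ("s0", "s1"),
                                      freqs=np.full(8, 0.5), min_joint_loci=1)
        assert est.r == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetric_in_pair_order(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, 200)
        a = rng.binomial(2, p).astype(float)
        b = rng.binomial(2, p).astype(float)
        r_ab, _ = _qg_batch(a, b, p)
        r_ba, _ = _qg_batch(b, a, p)
        assert r_ab[0] == r_ba[0]

    def test_category_means_unrelated_and_fullsib(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0.1, 0.5, 3000)
        n = 200
        P1 = rng.binomial(2, p, (n, p.size)).astype(float)
        P2 = rng.binomial(2, p, (n, p.size)).astype(float)
        fs_a = gamete(P1, rng) + gamete(P2, rng)
        fs_b = gamete(P1, rng) + gamete(P2, rng)
        u_a = rng.binomial(2, p, (n, p.size)).astype(float)
        u_b = rng.binomial(2, p, (n, p.size)).astype(float)
        r_fs, _ = _qg_batch(fs_a, fs_b, p)
        r_u, _ = _qg_batch(u_a, u_b, p)
        assert r_fs.mean() == pytest.approx(0.5, abs=0.01)
        assert r_u.mean() == pytest.approx(0.0, abs=0.01)

    def test_too_few_joint_loci_flagged(self):
        calls = np.full((2, 50), 1.0)
        calls[1, 10:] = np.nan
        g = matrix(calls)
        est = rel.queller_goodnight_r(g, ("s0", "s1"),
                                      freqs=np.full(50, 0.4), min_joint_loci=100)
        assert est.flag.startswith("too_few_joint_loci")


class TestDyadML:
    def test_identical_genotypes_k2_near_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, 2000)
        a = rng.binomial(2, p).astype(float)
        g = matrix([a, a])
        est = rel.dyadic_ml_r(g, ("s0", "s1"), freqs=p, error_rate=0.0)
        assert est.k2 > 0.99
        assert est.r == pytest.approx(1.0, abs=0.01)
        assert est.k0 + est.k1 + est.k2 == pytest.approx(1.0, abs=1e-8)

    def test_parent_offspring_k1_dominates(self):
        """PO shares exactly one allele IBD per locus: mean k1 >= 0.95, r ~ 0.5."""
        rng = np.random.default_rng(4)
        L, n = 10_000, 40
        p = rng.uniform(0.1, 0.5, L)
        parent = rng.binomial(2, p, (n, L)).astype(float)
        mate = rng.binomial(2, p, (n, L)).astype(float)
        child = gamete(parent, rng) + gamete(mate, rng)
        k, r, _, flags = _ml_batch(parent, child, p, 0.0)
        assert (flags == "").all()
        assert k[:, 1].mean() >= 0.95
        assert r.mean() == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("g1,g2,freqs", [
        ([0, 1, 2], [0, 1, 2], [0.3, 0.5, 0.7]),
        ([2, 1, 0], [1, 1, 1], [0.4, 0.4, 0.4]),
        ([0, 0, 2], [1, 2, 2], [0.2, 0.6, 0.8]),
        ([1, 2, 1], [0, 2, 2], [0.5, 0.3, 0.6]),
    ])
    def test_matches_grid_search_on_toys(self, g1, g2, freqs):
        """EM solution matches brute-force simplex search at step 0.001."""
        p = np.asarray(freqs, dtype=float)
        G1 = np.asarray(g1, dtype=float)[None, :]
        G2 = np.asarray(g2, dtype=float)[None, :]
        O = _joint_mode_tensors(p, 0.0)
        A, mask = _mode_likelihoods(O, G1, G2)
        k_grid, ll_grid = grid_ml(A[0], step=0.001)
        k, r, _, _ = _ml_batch(G1, G2, p, 0.0)
        ll_em = _loglik(k, A, mask.astype(float))[0]
        assert ll_em >= ll_grid - 1e-6
        r_grid = k_grid[2] + 0.5 * k_grid[1]
        assert r[0] == pytest.approx(r_grid, abs=0.002)

    def test_likelihood_beats_simplex_corners(self):
        """Invariant: the returned k is at least as likely as U, PO, identical."""
        rng = np.random.default_rng(8)
        p = rng.uniform(0.1, 0.5, 500)
        G1 = rng.binomial(2, p, (10, 500)).astype(float)
        G2 = gamete(G1, rng) + rng.binomial(1, p, (10, 500))
        O = _joint_mode_tensors(p, 0.01)
        A, mask = _mode_likelihoods(O, G1, G2)
        k, r, _, _ = _ml_batch(G1, G2, p, 0.01)
        ll = _loglik(k, A, mask.astype(float))
        for corner in np.eye(3):
            ll_c = _loglik(np.tile(corner, (10, 1)), A, mask.astype(float))
            assert (ll >= ll_c - 1e-6).all()

    def test_estimator_rank_ordering(self):
        """Mean r ranks U < HS < PO ~ FS across simulated categories."""
        from codkin.sibship import simulate_category_r
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.5, 2000)
        d = simulate_category_r(p, estimator="dyadml", n_sim=60, seed=1)
        assert d.mean("U") < d.mean("HS") < d.mean("PO")
        assert d.mean("FS") == pytest.approx(d.mean("PO"), abs=0.03)

    def test_moment_and_ml_agree_on_fullsibs(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(0.1, 0.5, 2000)
        n = 150
        P1 = rng.binomial(2, p, (n, p.size)).astype(float)
        P2 = rng.binomial(2, p, (n, p.size)).astype(float)
        a = gamete(P1, rng) + gamete(P2, rng)
        b = gamete(P1, rng) + gamete(P2, rng)
        r_qg, _ = _qg_batch(a, b, p)
        _, r_ml, _, _ = _ml_batch(a, b, p, 0.0)
        assert abs(r_qg.mean() - r_ml.mean()) < 0.05


class TestInbreeding:
    def test_all_homozygous_is_one(self):
        g = matrix([[0, 2, 0, 2]])
        df = rel.inbreeding_coefficients(g, freqs=np.full(4, 0.5), min_loci=1)
        assert df["F"].iloc[0] == pytest.approx(1.0)

    def test_all_heterozygous_clamps_to_minus_one(self):
        g = matrix([[1, 1, 1, 1]])
        df = rel.inbreeding_coefficients(g, freqs=np.full(4, 0.5), min_loci=1)
        assert df["F"].iloc[0] == pytest.approx(-1.0)

    def test_hwe_individual_near_zero(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.5, 10_000)
        g = matrix(rng.binomial(2, p, (1, p.size)).astype(float))
        df = rel.inbreeding_coefficients(g, freqs=p)
        assert abs(df["F"].iloc[0]) < 0.05


class TestOutbredScreen:
    def test_threshold_application(self):
        est = pd.DataFrame({"larva_id": ["a", "b", "c"],
                            "F": [-0.5, -0.39, 0.1],
                            "loci_used": [100] * 3, "flag": [""] * 3})
        retained, excluded = rel.screen_outbreds(est, threshold=-0.4)
        assert list(excluded["larva_id"]) == ["a"]
        assert retained == ["b", "c"]

    def test_no_outbreds_empty_exclusion(self):
        est = pd.DataFrame({"larva_id": ["a", "b"], "F": [0.0, -0.1],
                            "loci_used": [100] * 2, "flag": [""] * 2})
        retained, excluded = rel.screen_outbreds(est)
        assert len(excluded) == 0 and len(retained) == 2

    def test_invalid_threshold(self):
        est = pd.DataFrame({"larva_id": ["a"], "F": [0.0],
                            "loci_used": [10], "flag": [""]})
        with pytest.raises(ValueError):
            rel.screen_outbreds(est, threshold=0.5)

    def test_planted_outbreds_recovered(self):
        """>= 80% of F1 stocked contaminants fall below F = -0.4."""
        from codkin import SimConfig, simulate_pedigree_and_genotypes
        cfg = SimConfig(n_loci=800, n_adult_pairs=20, n_years=2, nests_per_year=5,
                        outbred_fraction=0.1, outbred_freq_shift=0.7, seed=31)
        g, _, truth = simulate_pedigree_and_genotypes(cfg)
        est = rel.inbreeding_coefficients(g)
        _, excluded = rel.screen_outbreds(est, threshold=-0.4)
        planted = set(truth.larvae.loc[truth.larvae["outbred"], "larva_id"])
        found = set(excluded["larva_id"])
        assert len(planted & found) >= 0.8 * len(planted)
        # and no more than a sliver of true river fish mislabelled
        river = set(truth.larvae.loc[~truth.larvae["outbred"], "larva_id"])
        assert len(river & found) <= 0.02 * len(river) + 1
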