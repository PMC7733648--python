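"""Cutoff calibration, full-sib classification and family assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from codkin import SimConfig, simulate_pedigree_and_genotypes, GenotypeMatrix
from codkin import sibship
from codkin.relatedness import _qg_batch, estimate_allele_frequencies
from codkin.sibship import (CategoryDistributions, simulate_category_r,
                            choose_cutoff, classify_dyads, build_families,
                            detect_multi_year_pairs, FamilyAssignment)
from conftest import make_families


def dyad_frame(rows):
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "r"])
    df["flag"] = ""
    return df


class TestCategorySimulation:
    def test_category_means(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.5, 3000)
        d = simulate_category_r(p, estimator="qg", n_sim=300, seed=4)
        assert d.mean("U") == pytest.approx(0.0, abs=0.01)
        assert d.mean("FS") == pytest.approx(0.5, abs=0.01)
        assert d.mean("HS") == pytest.approx(0.25, abs=0.01)
        assert d.mean("PO") == pytest.approx(0.5, abs=0.01)

    def test_deterministic_under_seed(self):
        p = np.full(200, 0.3)
        a = simulate_category_r(p, n_sim=50, seed=9)
        b = simulate_category_r(p, n_sim=50, seed=9)
        for c in sibship.CATEGORIES:
            assert np.array_equal(a.values[c], b.values[c])

    def test_rejects_empty_frequencies(self):
        with pytest.raises(ValueError):
            simulate_category_r(np.array([np.nan]), n_sim=10)


class TestChooseCutoff:
    def _dists(self, fs, hs):
        vals = {"FS": np.asarray(fs, dtype=float), "HS": np.asarray(hs, dtype=float),
                "PO": np.array([0.5]), "U": np.array([0.0])}
        return CategoryDistributions(values=vals, n_sim=len(fs), estimator="qg", seed=0)

    def test_fixed_mode_returns_configured_value(self):
        rng = np.random.default_rng(5)
        d = self._dists(rng.normal(0.5, 0.05, 500), rng.normal(0.25, 0.05, 500))
        rep = choose_cutoff(d, mode="fixed")
        assert rep.cutoff == 0.4
        assert 0 <= rep.fs_false_negative_rate < 0.1
        assert 0 <= rep.hs_false_positive_rate < 0.1

    def test_auto_on_separated_distributions(self):
        d = self._dists([0.5] * 10, [0.25] * 10)
        rep = choose_cutoff(d, mode="auto")
        assert 0.25 < rep.cutoff < 0.5
        assert rep.fs_false_negative_rate == 0.0
        assert rep.hs_false_positive_rate == 0.0

    def test_auto_low_false_negatives_on_simulation(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.5, 1000)
        d = simulate_category_r(p, estimator="qg", n_sim=400, seed=7)
        rep = choose_cutoff(d, mode="auto")
        assert rep.fs_false_negative_rate <= 0.05

    def test_overlapping_distributions_warn(self):
        rng = np.random.default_rng(8)
        same = rng.normal(0.3, 0.2, 300)
        d = self._dists(same, rng.normal(0.3, 0.2, 300))
        rep = choose_cutoff(d, mode="auto")
        assert rep.warning != ""


class TestClassifyDyads:
    def test_strict_threshold(self):
        df = dyad_frame([("a", "b", 0.5), ("a", "c", 0.45), ("b", "c", 0.3)])
        edges = classify_dyads(df, cutoff=0.4)
        assert len(edges) == 2

    def test_empty_input(self):
        edges = classify_dyads(dyad_frame([]), cutoff=0.4)
        assert len(edges) == 0

    def test_flagged_dyads_never_kept(self):
        df = dyad_frame([("a", "b", 0.9)])
        df.loc[0, "flag"] = "too_few_joint_loci"
        assert len(classify_dyads(df, cutoff=0.4)) == 0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=0, max_size=30),
           st.floats(0, 1), st.floats(0, 1))
    def test_raising_cutoff_never_adds_edges(self, rs, c1, c2):
        lo, hi = min(c1, c2), max(c1, c2)
        df = dyad_frame([(f"x{i}", f"y{i}", r) for i, r in enumerate(rs)])
        assert len(classify_dyads(df, cutoff=hi)) <= len(classify_dyads(df, cutoff=lo))

    def test_recovers_planted_fullsib_dyads(self):
        """Family sizes (7,5,3,2) give 21+10+3+1 = 35 true full-sib dyads:
        nearly all recovered at 1000 loci, and no unrelated dyad crosses 0.4."""
        rng = np.random.default_rng(35)
        p = rng.uniform(0.1, 0.5, 1000)
        calls, labels = make_families(p, [7, 5, 3, 2], rng)
        lone = rng.binomial(2, p, (10, p.size)).astype(float)
        calls = np.vstack([calls, lone])
        labels = np.concatenate([labels, -np.arange(1, 11)])
        ids = [f"v{i}" for i in range(len(labels))]
        pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
        ia, ib = np.array([a for a, _ in pairs]), np.array([b for _, b in pairs])
        r, _ = _qg_batch(calls[ia], calls[ib], p)
        df = dyad_frame([(ids[a], ids[b], rv) for (a, b), rv in zip(pairs, r)])
        edges = classify_dyads(df, cutoff=0.4)
        is_fs = labels[ia] == labels[ib]
        assert is_fs.sum() == 35
        kept = set(map(tuple, edges[["id_a", "id_b"]].to_numpy()))
        fs_kept = sum((ids[a], ids[b]) in kept for (a, b), fs in zip(pairs, is_fs) if fs)
        u_kept = sum((ids[a], ids[b]) in kept for (a, b), fs in zip(pairs, is_fs) if not fs)
        assert fs_kept >= 33
        assert u_kept == 0


class TestBuildFamilies:
    YEARS = {"A": 2011, "B": 2011, "C": 2012, "D": 2012}

    def test_components_and_clique_flag(self):
        edges = dyad_frame([("A", "B", 0.5), ("B", "C", 0.5)])
        fams, singles = build_families(edges, self.YEARS)
        assert len(fams) == 1
        assert fams[0].members == ("A", "B", "C")
        assert not fams[0].is_clique
        assert singles == ["D"]

    def test_no_edges_all_singletons(self):
        fams, singles = build_families(dyad_frame([]), self.YEARS)
        assert fams == []
        assert sorted(singles) == ["A", "B", "C", "D"]

    def test_unknown_larva_rejected(self):
        with pytest.raises(KeyError):
            build_families(dyad_frame([("A", "Z", 0.5)]), self.YEARS)

    def test_families_partition_nonsingletons(self):
        edges = dyad_frame([("A", "B", 0.5), ("C", "D", 0.6)])
        fams, singles = build_families(edges, self.YEARS)
        members = [m for f in fams for m in f.members]
        assert sorted(members) == ["A", "B", "C", "D"]
        assert len(set(members)) == len(members)
        assert singles == []

    def test_recovers_truth_partition_at_zero_error(self):
        """With clean genotypes, families equal the true nest partition."""
        cfg = SimConfig(n_loci=1000, n_adult_pairs=25, n_years=2, nests_per_year=5,
                        larvae_per_nest_range=(3, 4), multi_year_pairs=0,
                        genotyping_error_rate=0.0, missing_rate=0.0, seed=77)
        g, meta, truth = simulate_pedigree_and_genotypes(cfg)
        freqs = estimate_allele_frequencies(g)
        from codkin.relatedness import pairwise_relatedness
        dyads = pairwise_relatedness(g, estimator="qg", freqs=freqs)
        edges = classify_dyads(dyads, cutoff=0.4)
        years = dict(zip(meta["larva_id"], meta["year"]))
        fams, singles = build_families(edges, years)
        got = {f.members for f in fams}
        want = {tuple(sorted(grp)) for _, grp in
                truth.larvae.groupby("nest_id")["larva_id"]}
        assert got == want
        assert singles == []


class TestMultiYearDetection:
    def fam(self, fid, years):
        return FamilyAssignment(family_id=fid, members=("x", "y"), years=tuple(years),
                                edges=(("x", "y"),), is_clique=True)

    def test_three_year_sequential(self):
        rep = detect_multi_year_pairs([self.fam("M01", (2011, 2012, 2013))])
        assert len(rep) == 1
        assert rep.iloc[0]["n_years"] == 3 and bool(rep.iloc[0]["sequential"])

    def test_gap_year_non_sequential(self):
        rep = detect_multi_year_pairs([self.fam("M01", (2011, 2013))])
        assert len(rep) == 1 and not bool(rep.iloc[0]["sequential"])

    def test_single_year_families_empty_report(self):
        rep = detect_multi_year_pairs([self.fam("M01", (2011,)),
                                       self.fam("M02", (2012,))])
        assert rep.empty
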