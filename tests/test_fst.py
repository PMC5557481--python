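import numpy as np
import pandas as pd
import pytest

from breedscan.core import MISSING
from breedscan.fst import (
    select_cohorts,
    top_windows,
    top_windows_and_regions,
    wc_fst_per_locus,
    window_fst,
    window_scheme_dispersion,
)
from breedscan.pedigree import Pedigree
from conftest import make_genotypes, make_map
from oracles import wc_theta_transcription


class TestPerLocusTheta:
    def test_identical_groups_no_among_population_variance(self):
        block = np.array([[0], [1], [2], [1], [0]])
        dos = np.vstack([block, block])
        gm = make_genotypes(dos)
        labels = [0] * 5 + [1] * 5
        loci = wc_fst_per_locus(gm, labels)
        # the unbiased estimator subtracts expected sampling variance, so
        # with zero realised among-group variance a (and theta) go negative
        assert loci["a"].iloc[0] <= 0.0
        assert loci["theta"].iloc[0] <= 0.0

    def test_fixed_difference_theta_one(self):
        dos = np.array([[0]] * 6 + [[2]] * 6)
        gm = make_genotypes(dos)
        loci = wc_fst_per_locus(gm, [0] * 6 + [1] * 6)
        assert loci["theta"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_monomorphic_locus_undefined(self):
        dos = np.zeros((8, 1), dtype=np.int8)
        loci = wc_fst_per_locus(make_genotypes(dos), [0] * 4 + [1] * 4)
        assert not loci["defined"].iloc[0]
        assert np.isnan(loci["theta"].iloc[0])

    def test_group_with_no_calls_undefined(self):
        dos = np.array([[0], [2], [MISSING], [MISSING]])
        loci = wc_fst_per_locus(make_genotypes(dos), [0, 0, 1, 1])
        assert not loci["defined"].iloc[0]

    def test_matches_transcription_oracle(self, rng):
        for _ in range(300):
            n1, n2 = int(rng.integers(2, 11)), int(rng.integers(2, 11))
            g1 = rng.choice([0, 1, 2, MISSING], size=n1, p=[0.3, 0.3, 0.3, 0.1])
            g2 = rng.choice([0, 1, 2, MISSING], size=n2, p=[0.3, 0.3, 0.3, 0.1])
            dos = np.concatenate([g1, g2])[:, None].astype(np.int8)
            loci = wc_fst_per_locus(make_genotypes(dos), [0] * n1 + [1] * n2)
            a, b, c, theta = wc_theta_transcription(g1.tolist(), g2.tolist())
            if np.isnan(theta):
                assert not loci["defined"].iloc[0] or np.isnan(loci["theta"].iloc[0])
            else:
                assert loci["a"].iloc[0] == pytest.approx(a, abs=1e-12)
                assert loci["b"].iloc[0] == pytest.approx(b, abs=1e-12)
                assert loci["c"].iloc[0] == pytest.approx(c, abs=1e-12)
                assert loci["theta"].iloc[0] == pytest.approx(theta, abs=1e-12)

    def test_invariant_to_group_order_and_allele_swap(self, rng):
        dos = rng.choice([0, 1, 2], size=(16, 20)).astype(np.int8)
        labels = np.array([0] * 8 + [1] * 8)
        t1 = wc_fst_per_locus(make_genotypes(dos), labels)["theta"]
        t2 = wc_fst_per_locus(make_genotypes(dos), 1 - labels)["theta"]
        t3 = wc_fst_per_locus(make_genotypes(2 - dos), labels)["theta"]
        np.testing.assert_allclose(t1, t2, atol=1e-12)
        np.testing.assert_allclose(t1, t3, atol=1e-12)


class TestWindows:
    def _loci(self, thetas, chrom=None, bp=None):
        n = len(thetas)
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "chrom": chrom if chrom is not None else np.ones(n, dtype=int),
            "bp": bp if bp is not None else 1000 * (np.arange(n) + 1),
            "theta": thetas,
            "a": thetas, "b": np.zeros(n), "c": np.zeros(n),
            "defined": ~np.isnan(np.asarray(thetas)),
        })

    def test_constant_theta_constant_windows(self):
        w = window_fst(self._loci([0.3] * 20), 9)
        np.testing.assert_allclose(w["mean_theta"], 0.3, atol=1e-12)
        assert len(w) == 12

    def test_nine_snp_chromosome_single_central_window(self):
        w = window_fst(self._loci([0.1] * 9), 9)
        assert len(w) == 1
        assert w["center_snp"].iloc[0] == "s4"

    def test_undefined_loci_dropped_before_windowing(self):
        thetas = [0.1] * 5 + [np.nan] + [0.3] * 5
        w = window_fst(self._loci(thetas), 9)
        # 10 usable loci -> 2 windows over the concatenated defined set
        assert len(w) == 2

    def test_matches_rolling_mean_oracle(self, rng):
        thetas = rng.normal(0.05, 0.1, size=60)
        w = window_fst(self._loci(thetas), 13)
        oracle = pd.Series(thetas).rolling(13).mean().dropna().to_numpy()
        np.testing.assert_allclose(w["mean_theta"].to_numpy(), oracle, atol=1e-12)

    def test_windows_never_span_chromosomes(self, rng):
        thetas = rng.normal(0.05, 0.05, size=30)
        chrom = np.array([1] * 15 + [2] * 15)
        bp = np.concatenate([1000 * (np.arange(15) + 1)] * 2)
        w = window_fst(self._loci(thetas, chrom, bp), 9)
        assert len(w) == 14  # 7 per chromosome
        assert set(w["chrom"]) == {1, 2}

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            window_fst(self._loci([0.1] * 20), 8)


class TestTailAndRegions:
    def _windows(self, values, bp=None, chrom=1, k=9):
        n = len(values)
        return pd.DataFrame({
            "chrom": np.full(n, chrom),
            "center_snp": [f"w{i}" for i in range(n)],
            "center_bp": bp if bp is not None else 100_000 * (np.arange(n) + 1),
            "k": k,
            "mean_theta": values,
        })

    def test_tail_size_is_ceiling(self, rng):
        w = self._windows(rng.random(20_000))
        assert len(top_windows(w, 0.0005)) == 10  # ceil(10.0)
        w2 = self._windows(rng.random(1999))
        assert len(top_windows(w2, 0.0005)) == 1  # ceil(0.9995)

    def test_ties_at_cutoff_all_included(self):
        vals = [0.1] * 5 + [0.9, 0.9, 0.9]
        w = self._windows(vals)
        tail = top_windows(w, tail_fraction=1e-9)  # nominal size 1
        assert len(tail) == 3

    def test_merge_distance_rule(self):
        for gap, n_regions in [(800_000, 1), (1_200_000, 2)]:
            w = self._windows([1.0, 1.0], bp=np.array([5_000_000, 5_000_000 + gap]))
            regions = top_windows_and_regions({9: w}, tail_fraction=1.0)
            assert len(regions) == n_regions

    def test_region_reports_max_per_window_size_with_absences(self):
        w9 = self._windows([0.9], bp=np.array([1_000_000]), k=9)
        w13 = self._windows([0.8], bp=np.array([20_000_000]), k=13)
        regions = top_windows_and_regions({9: w9, 13: w13}, tail_fraction=1.0)
        assert len(regions) == 2
        by_start = {r.start_bp: r.max_theta_by_k for r in regions}
        assert by_start[1_000_000] == {9: 0.9}
        assert by_start[20_000_000] == {13: 0.8}

    def test_region_merge_idempotent(self, rng):
        w = self._windows(rng.random(50))
        r1 = top_windows_and_regions({9: w}, tail_fraction=0.2)
        spans1 = [(r.chrom, r.start_bp, r.end_bp) for r in r1]
        # re-merging the tail windows yields the same regions
        tail = pd.concat([r.windows for r in r1], ignore_index=True)
        r2 = top_windows_and_regions({9: tail}, tail_fraction=1.0)
        spans2 = [(r.chrom, r.start_bp, r.end_bp) for r in r2]
        assert spans1 == spans2


class TestCohortSelection:
    def test_unrelated_candidates_top_n(self):
        membership = {f"i{k}": 0.90 + 0.001 * k for k in range(10)}
        membership.update({f"j{k}": 0.02 for k in range(5)})
        sel = select_cohorts(membership, None, threshold=0.5, n_per_cluster=3)
        assert sel.cluster1_ids == ["i9", "i8", "i7"]
        assert len(sel.cluster2_ids) == 3

    def test_full_sibs_not_both_selected(self):
        ped = Pedigree([("s", None, None), ("d", None, None),
                        ("a", "s", "d"), ("b", "s", "d"), ("c", None, None)])
        membership = {"a": 0.99, "b": 0.98, "c": 0.97}
        sel = select_cohorts(membership, ped, threshold=0.9, n_per_cluster=2)
        assert sel.cluster1_ids == ["a", "c"]

    def test_shortfall_reported_not_fatal(self):
        sel = select_cohorts({"a": 0.95}, None, threshold=0.9, n_per_cluster=27)
        assert sel.shortfall[1] == 26
        assert sel.shortfall[2] == 27

    def test_no_shared_parent_property(self, rng):
        # planted half-sib families: exhaustive check of the invariant
        recs, membership = [], {}
        for fam in range(6):
            sire = f"sire{fam}"
            recs.append((sire, None, None))
            for k in range(4):
                iid = f"f{fam}_{k}"
                recs.append((iid, sire, None))
                membership[iid] = float(rng.random())
        ped = Pedigree(recs)
        sel = select_cohorts(membership, ped, threshold=0.0, n_per_cluster=10)
        for cohort in (sel.cluster1_ids, sel.cluster2_ids):
            parents = []
            for i in cohort:
                parents.extend(p for p in ped.parents(i) if p is not None)
            assert len(parents) == len(set(parents))


class TestWindowSchemeDispersion:
    def test_even_map_fixed_snp_point_mass(self):
        mmap = make_map(200, spacing=10_000)
        rep = window_scheme_dispersion(mmap, k_list=(9,), size_list_bp=(100_000,))
        assert rep["fixed_snp"][9]["cv"] == pytest.approx(0.0, abs=1e-12)

    def test_jittered_map_fixed_snp_less_dispersed(self, rng):
        # chip-like density: ~50 SNP/Mb with jittered spacing
        from breedscan.synth import make_marker_map
        mmap = make_marker_map(rng, 2000, 2, 20_000_000)
        rep = window_scheme_dispersion(mmap, k_list=(9, 13, 17),
                                       size_list_bp=(180_000, 260_000, 340_000))
        for k, size in zip((9, 13, 17), (180_000, 260_000, 340_000)):
            assert rep["fixed_snp"][k]["cv"] < rep["fixed_bp"][size]["cv"]

    def test_counts_conserved_by_tiling(self):
        mmap = make_map(500, spacing=7_000)
        rep = window_scheme_dispersion(mmap, k_list=(9,), size_list_bp=(50_000,))
        stats = rep["fixed_bp"][50_000]
        assert stats["n"] * stats["mean"] == pytest.approx(500)
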