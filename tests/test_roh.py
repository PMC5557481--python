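import numpy as np
import pytest

from breedscan.core import MISSING
from breedscan.roh import (
    ROHParams,
    cluster_roh_association,
    detect_roh,
    f_roh,
    pool_overlapping_segments,
)
from breedscan.synth import plant_roh
from conftest import make_genotypes
from oracles import naive_roh_scan, pearson_chi2

SMALL = ROHParams(scan_window_snps=20, min_snps_in_roh=30, min_length_bp=100_000)


def het_background(n_ind, n_snps, spacing=10_000):
    return make_genotypes(np.ones((n_ind, n_snps), dtype=np.int8), spacing=spacing)


class TestDetection:
    def test_fully_heterozygous_genome_has_no_segments(self):
        gm = het_background(3, 400)
        assert detect_roh(gm) == []

    def test_planted_run_with_one_het_detected_whole(self):
        # 150 hom SNPs spanning 1.49 Mb with a single interior het
        gm = het_background(2, 500)
        start, end = gm.map.bp[100], gm.map.bp[249]
        gm = plant_roh(gm, "ind0", 1, start, end, fill_dosage=2)
        gm.dosages[0, 170] = 1
        segs = detect_roh(gm, ROHParams())
        assert len(segs) == 1
        seg = segs[0]
        assert seg.individual == "ind0"
        assert seg.n_het_inside == 1
        # boundaries equal the naive scanner's
        (oracle,) = naive_roh_scan(gm.dosages[0], gm.map.bp, ROHParams())
        assert (seg.start_idx, seg.end_idx) == oracle
        # the detected run sits inside the planted interval and covers its
        # core (the scan proportion rule can shave the outermost SNPs)
        assert 100 <= seg.start_idx <= 103
        assert 246 <= seg.end_idx <= 249

    def test_clustered_hets_break_the_run(self):
        # three heterozygotes close enough that every window over the middle
        # of the run carries >1 het (max_het_per_window = 1): the run splits
        # into two sub-threshold pieces and no segment survives the filters
        gm = het_background(1, 500)
        start, end = gm.map.bp[100], gm.map.bp[249]
        gm = plant_roh(gm, "ind0", 1, start, end, fill_dosage=2)
        gm.dosages[0, [165, 170, 175]] = 1
        assert detect_roh(gm, ROHParams()) == []

    def test_two_disjoint_planted_runs_two_segments(self):
        gm = het_background(1, 1000)
        gm = plant_roh(gm, "ind0", 1, gm.map.bp[50], gm.map.bp[249], fill_dosage=2)
        gm = plant_roh(gm, "ind0", 1, gm.map.bp[600], gm.map.bp[799], fill_dosage=0)
        segs = detect_roh(gm, ROHParams())
        assert len(segs) == 2

    def test_chromosome_shorter_than_window_yields_nothing(self):
        gm = make_genotypes(np.zeros((1, 10), dtype=np.int8))
        assert detect_roh(gm, ROHParams(scan_window_snps=50)) == []

    def test_matches_naive_scan_on_random_instances(self, rng):
        for _ in range(25):
            n_snps = int(rng.integers(60, 300))
            dos = rng.choice([0, 1, 2, MISSING], size=(5, n_snps),
                             p=[0.42, 0.12, 0.42, 0.04]).astype(np.int8)
            gm = make_genotypes(dos, spacing=int(rng.integers(2_000, 20_000)))
            segs = detect_roh(gm, SMALL)
            got = {(s.individual, s.start_idx, s.end_idx) for s in segs}
            want = set()
            for i, iid in enumerate(gm.sample_ids):
                for (a, b) in naive_roh_scan(dos[i], gm.map.bp, SMALL):
                    want.add((iid, a, b))
            assert got == want

    def test_allele_label_swap_invariant(self, rng):
        dos = rng.choice([0, 1, 2], size=(3, 200), p=[0.45, 0.1, 0.45]).astype(np.int8)
        gm = make_genotypes(dos)
        flipped = dos.copy()
        flipped[:, ::2] = 2 - flipped[:, ::2]
        gm2 = make_genotypes(flipped)
        s1 = {(s.individual, s.start_idx, s.end_idx) for s in detect_roh(gm, SMALL)}
        s2 = {(s.individual, s.start_idx, s.end_idx) for s in detect_roh(gm2, SMALL)}
        assert s1 == s2

    def test_every_segment_satisfies_filters(self, rng):
        dos = rng.choice([0, 1, 2], size=(10, 400), p=[0.46, 0.08, 0.46]).astype(np.int8)
        gm = make_genotypes(dos, spacing=5_000)
        for s in detect_roh(gm, SMALL):
            assert s.n_snps >= SMALL.min_snps_in_roh
            assert s.length_bp >= SMALL.min_length_bp


class TestFroh:
    def test_no_segments_zero(self):
        assert f_roh([], sample_ids=["x"]) == {"x": 0.0}

    def test_planted_total_arithmetic(self):
        gm = het_background(1, 1000)
        gm = plant_roh(gm, "ind0", 1, gm.map.bp[50], gm.map.bp[249], fill_dosage=2)
        segs = detect_roh(gm, ROHParams())
        total = sum(s.length_bp for s in segs)
        params = ROHParams(genome_denominator_bp=total * 10)
        froh = f_roh(segs, params, sample_ids=gm.sample_ids)
        assert froh["ind0"] == pytest.approx(0.1)

    def test_monotone_under_additional_disjoint_runs(self):
        gm1 = het_background(1, 1000)
        gm1 = plant_roh(gm1, "ind0", 1, gm1.map.bp[50], gm1.map.bp[249], fill_dosage=2)
        gm2 = plant_roh(gm1, "ind0", 1, gm1.map.bp[600], gm1.map.bp[799], fill_dosage=2)
        f1 = f_roh(detect_roh(gm1), sample_ids=["ind0"])["ind0"]
        f2 = f_roh(detect_roh(gm2), sample_ids=["ind0"])["ind0"]
        assert f2 > f1


class TestPools:
    def _two_carrier_matrix(self, fill_b=2):
        gm = het_background(3, 500)
        start, end = gm.map.bp[100], gm.map.bp[249]
        gm = plant_roh(gm, "ind0", 1, start, end, fill_dosage=2)
        gm = plant_roh(gm, "ind1", 1, start, end, fill_dosage=fill_b)
        return gm

    def test_identical_segments_one_pool_one_subgroup(self):
        gm = self._two_carrier_matrix(fill_b=2)
        segs = detect_roh(gm, ROHParams())
        pools = pool_overlapping_segments(segs, gm)
        assert len(pools) == 1
        assert len(pools[0].subgroups) == 1

    def test_opposite_alleles_two_subgroups(self):
        gm = self._two_carrier_matrix(fill_b=0)
        segs = detect_roh(gm, ROHParams())
        pools = pool_overlapping_segments(segs, gm)
        assert len(pools) == 1
        assert len(pools[0].subgroups) == 2

    def test_two_snp_overlap_is_not_pooled(self):
        gm = het_background(2, 600, spacing=10_000)
        # segments overlapping by exactly 2 SNPs
        gm = plant_roh(gm, "ind0", 1, gm.map.bp[0], gm.map.bp[251], fill_dosage=2)
        gm = plant_roh(gm, "ind1", 1, gm.map.bp[250], gm.map.bp[501], fill_dosage=2)
        segs = detect_roh(gm, ROHParams())
        assert len(segs) == 2
        s0 = [s for s in segs if s.individual == "ind0"][0]
        s1 = [s for s in segs if s.individual == "ind1"][0]
        overlap = min(s0.end_idx, s1.end_idx) - max(s0.start_idx, s1.start_idx) + 1
        assert overlap <= 2
        assert pool_overlapping_segments(segs, gm) == []


class TestAssociation:
    def _pool(self, gm, segs):
        return pool_overlapping_segments(segs, gm)[0]

    def test_equal_proportions_zero_statistic(self):
        gm = het_background(4, 500)
        for iid, fill in [("ind0", 2), ("ind1", 0), ("ind2", 2), ("ind3", 0)]:
            gm = plant_roh(gm, iid, 1, gm.map.bp[100], gm.map.bp[249], fill)
        pool = self._pool(gm, detect_roh(gm, ROHParams()))
        membership = {"ind0": 0.1, "ind1": 0.2, "ind2": 0.9, "ind3": 0.8}
        res = cluster_roh_association(pool, membership)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation(self):
        gm = het_background(20, 500)
        membership = {}
        for i in range(20):
            fill = 2 if i < 10 else 0
            gm = plant_roh(gm, f"ind{i}", 1, gm.map.bp[100], gm.map.bp[249], fill)
            membership[f"ind{i}"] = 0.05 if i < 10 else 0.95
        pool = self._pool(gm, detect_roh(gm, ROHParams()))
        res = cluster_roh_association(pool, membership)
        # 2x2 table [[10,0],[0,10]]: Pearson chi2 = n = 20
        assert res.chi2 == pytest.approx(20.0)
        assert res.p_value < 0.001

    def test_matches_textbook_oracle(self, rng):
        from breedscan.roh import ROHPool, ROHSegment
        for _ in range(20):
            table = rng.integers(1, 12, size=(2, 3))
            segs = [[], [], []]
            membership = {}
            n = 0
            for g in range(3):
                for stratum in range(2):
                    for _k in range(table[stratum, g]):
                        iid = f"i{n}"
                        segs[g].append(ROHSegment(iid, 1, 1, 2, 3, 0, 0))
                        membership[iid] = 0.2 if stratum == 0 else 0.8
                        n += 1
            pool = ROHPool(0, [s for grp in segs for s in grp], 1, -1, -2, -1, -1,
                           subgroups=segs)
            res = cluster_roh_association(pool, membership)
            assert res.chi2 == pytest.approx(pearson_chi2(table), rel=1e-12)

    def test_zero_margin_flagged(self):
        from breedscan.roh import ROHPool, ROHSegment
        segs = [ROHSegment("a", 1, 1, 2, 3, 0, 0), ROHSegment("b", 1, 1, 2, 3, 0, 0)]
        pool = ROHPool(0, segs, 1, -1, -2, -1, -1, subgroups=[segs])
        res = cluster_roh_association(pool, {"a": 0.1, "b": 0.9})
        assert not res.defined
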