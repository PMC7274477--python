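"""Contact quantification, mirrored background, loop detection, TADs."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from t3enh.hic import (ContactMatrix, detect_interactions,
                       nearest_distance_profile, opposite_background,
                       quantify_contact, tad_confinement)

RES = 5000
SIZES = {"chr1": 1_000_000}


def dense_matrix(fn, chrom_size=1_000_000):
    nb = chrom_size // RES
    d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
    return fn(d)


def from_dense(dense, sizes=SIZES):
    mats = {}
    for chrom in sizes:
        upper = np.triu(dense)
        mats[chrom] = sparse.csr_matrix(upper)
    return ContactMatrix(RES, sizes, mats)


def dense_pair_sum(dense, bins_a, bins_b):
    return sum(dense[min(i, j), max(i, j)] + 0 for i in bins_a for j in bins_b)


class TestQuantifyContact:
    def test_zero_matrix(self):
        mat = ContactMatrix(RES, SIZES)
        assert quantify_contact(mat, ("chr1", 100_000), ("chr1", 300_000)) == 0

    def test_single_entry_recovered(self):
        nb = SIZES["chr1"] // RES
        m = sparse.csr_matrix(([7], ([20], [60])), shape=(nb, nb))
        mat = ContactMatrix(RES, SIZES, {"chr1": m})
        a = ("chr1", 20 * RES + RES // 2)
        b = ("chr1", 60 * RES + RES // 2)
        assert quantify_contact(mat, a, b) == 7

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_dense_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nb = SIZES["chr1"] // RES
        dense = np.triu(rng.poisson(1.0, size=(nb, nb)))
        mat = from_dense(dense)
        for _ in range(50):
            mid_a = int(rng.integers(20_000, 900_000))
            mid_b = int(rng.integers(20_000, 900_000))
            got = quantify_contact(mat, ("chr1", mid_a), ("chr1", mid_b))
            bins_a = mat.window_bins("chr1", mid_a, 10_000)
            bins_b = mat.window_bins("chr1", mid_b, 10_000)
            assert got == dense_pair_sum(dense, bins_a, bins_b)

    def test_symmetric_in_anchors(self):
        rng = np.random.default_rng(5)
        nb = SIZES["chr1"] // RES
        mat = from_dense(np.triu(rng.poisson(2.0, size=(nb, nb))))
        a, b = ("chr1", 123_456), ("chr1", 654_321)
        assert quantify_contact(mat, a, b) == quantify_contact(mat, b, a)

    def test_trans_pair_rejected(self):
        mat = ContactMatrix(RES, {"chr1": 100_000, "chr2": 100_000})
        with pytest.raises(ValueError, match="cis"):
            quantify_contact(mat, ("chr1", 50_000), ("chr2", 50_000))


class TestOppositeBackground:
    @pytest.mark.parametrize("mid_a,mid_b", [
        (200_000, 500_000),      # bin-aligned midpoints
        (203_711, 514_137),      # arbitrary midpoints
        (250_001, 250_001 + 137_000),
    ])
    def test_translation_invariant_matrix_exact(self, mid_a, mid_b):
        mat = from_dense(dense_matrix(lambda d: (200 // (1 + d)).astype(int)))
        obs = quantify_contact(mat, ("chr1", mid_a), ("chr1", mid_b))
        bg = opposite_background(mat, ("chr1", mid_a), ("chr1", mid_b))
        assert bg is not None
        assert bg.count == obs

    def test_planted_loop_exceeds_flat_background(self):
        nb = SIZES["chr1"] // RES
        dense = np.triu(np.full((nb, nb), 2))
        dense[40, 100] = 500
        mat = from_dense(dense)
        a = ("chr1", 40 * RES + RES // 2)
        b = ("chr1", 100 * RES + RES // 2)
        obs = quantify_contact(mat, a, b)
        bg = opposite_background(mat, a, b)
        assert obs > bg.count

    def test_mirror_falls_back_to_other_side(self):
        mat = from_dense(dense_matrix(lambda d: (100 // (1 + d)).astype(int)))
        # mirror of b across a lands below zero -> reflect a across b instead
        a, b = ("chr1", 30_000), ("chr1", 400_000)
        bg = opposite_background(mat, a, b)
        assert bg is not None and bg.side == "b"
        obs = quantify_contact(mat, a, b)
        assert bg.count == obs  # still exact by translation invariance

    def test_both_mirrors_off_chromosome_excluded(self):
        small = {"chr1": 200_000}
        mat = ContactMatrix(RES, small)
        assert opposite_background(mat, ("chr1", 50_000), ("chr1", 150_000)) is None

    def test_anchor_order_normalised(self):
        mat = from_dense(dense_matrix(lambda d: (50 // (1 + d)).astype(int)))
        fwd = opposite_background(mat, ("chr1", 200_000), ("chr1", 500_000))
        rev = opposite_background(mat, ("chr1", 500_000), ("chr1", 200_000))
        assert fwd.count == rev.count


class TestDetectInteractions:
    def _regions(self, mids, chrom="chr1"):
        mids = np.asarray(mids)
        return pd.DataFrame({"chrom": chrom, "start": mids - 500,
                             "end": mids + 500,
                             "region_id": [f"r{i}" for i in range(len(mids))]})

    def test_background_only_yields_nothing(self):
        rng = np.random.default_rng(0)
        nb = SIZES["chr1"] // RES
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        dense = np.triu(rng.poisson(20 / (1 + d / 10)))
        mat = from_dense(dense)
        regions = self._regions(np.arange(20) * 45_000 + 50_000)
        pairs = detect_interactions(mat, regions, min_distance=50_000,
                                    max_distance=800_000)
        assert len(pairs) <= 1  # Poisson bound at 1e-5 over ~200 candidates

    def test_planted_loop_detected(self):
        rng = np.random.default_rng(1)
        nb = SIZES["chr1"] // RES
        d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb)))
        dense = np.triu(rng.poisson(20 / (1 + d / 10)))
        dense[40, 100] += 200
        dense[41, 101] += 200
        mat = from_dense(dense)
        regions = self._regions([40 * RES + 2500, 100 * RES + 2500,
                                 150 * RES + 2500])
        pairs = detect_interactions(mat, regions, min_distance=50_000,
                                    max_distance=800_000)
        assert {("r0", "r1")} == set(zip(pairs["region_a"], pairs["region_b"]))

    def test_max_distance_below_loops_yields_nothing(self, default_dataset):
        ds = default_dataset
        hyper = ds.regions[ds.regions["region_id"].isin(
            ds.truth.loc[ds.truth["loop_id"] != "", "region_id"])]
        pairs = detect_interactions(ds.hic, hyper, min_distance=50_000,
                                    max_distance=150_000)
        planted = set(map(tuple, ds.loops[["region_a", "region_b"]].to_numpy()))
        found = set(zip(pairs["region_a"], pairs["region_b"]))
        assert not planted & found  # planted loops all span > 200 kb


class TestTadConfinement:
    def _regions(self, mids, chrom="chr1"):
        mids = np.asarray(mids)
        return pd.DataFrame({"chrom": chrom, "start": mids - 100,
                             "end": mids + 100,
                             "region_id": [f"t{m}" for m in mids]})

    def test_single_tad_containing_everything(self):
        tads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000_000]})
        no = self._regions([100_000, 200_000])
        w = self._regions([300_000])
        pool = self._regions(np.arange(50) * 50_000 + 1_000_000)
        res = tad_confinement(no, w, tads, pool, n_random=20, seed=0)
        assert res.observed_fraction == 1.0

    def test_no_tads_all_unassigned(self):
        tads = pd.DataFrame(columns=["chrom", "start", "end"])
        no = self._regions([100_000])
        w = self._regions([300_000])
        pool = self._regions(np.arange(50) * 50_000 + 1_000_000)
        res = tad_confinement(no, w, tads, pool, n_random=20, seed=0)
        assert res.observed_fraction == 0.0
        assert res.p_value == 1.0

    def test_planted_confinement_enriched(self, default_report):
        res = default_report["hic"]["tad_confinement"]
        assert res["p_value"] < 0.01
        assert res["odds_ratio"] > 1


class TestNearestDistanceProfile:
    def test_identical_sets_all_zero(self, default_dataset):
        regions = default_dataset.regions.head(50)
        prof = nearest_distance_profile(regions, regions,
                                        default_dataset.regions, seed=0)
        assert prof.median_to_target == 0.0

    def test_queries_without_targets_excluded(self):
        a = pd.DataFrame({"chrom": ["chrX"], "start": [0], "end": [100],
                          "region_id": ["a"]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                          "region_id": ["b"]})
        pool = pd.DataFrame({"chrom": ["chr1"] * 10,
                             "start": np.arange(10) * 1000,
                             "end": np.arange(10) * 1000 + 100,
                             "region_id": [f"p{i}" for i in range(10)]})
        prof = nearest_distance_profile(a, b, pool, seed=0)
        assert prof.n_excluded == 1
        assert len(prof.distances_to_target) == 0

    def test_planted_proximity(self, default_report):
        nd = default_report["hic"]["nearest_distance"]
        assert nd["median_to_w_trbs"] < nd["median_to_random"]
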