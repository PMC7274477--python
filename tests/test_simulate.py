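"""Synthetic-data generator: determinism, planted structure, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

import t3enh
from t3enh.simulate import (HYPERACETYLATED_CLASSES, SimConfig,
                            evaluate_recovery, generate_dataset)
from t3enh.stats import wilcoxon_signed_rank
from t3enh.hic import opposite_background, quantify_contact


def test_seed_is_mandatory():
    with pytest.raises(TypeError):
        SimConfig()
    with pytest.raises(ValueError):
        SimConfig(seed=None)


def test_fraction_and_fold_validation():
    with pytest.raises(ValueError, match="sum"):
        SimConfig(seed=1, class_fractions={"type1A": 0.9, "null": 0.9})
    with pytest.raises(ValueError, match="ac_fold"):
        SimConfig(seed=1, ac_fold=0.5)


def test_same_seed_twice_is_identical(small_config):
    ds1 = generate_dataset(small_config)
    ds2 = generate_dataset(small_config)
    pd.testing.assert_frame_equal(ds1.regions, ds2.regions)
    pd.testing.assert_frame_equal(ds1.truth, ds2.truth)
    for target in ds1.counts:
        pd.testing.assert_frame_equal(ds1.counts[target], ds2.counts[target])
    pd.testing.assert_frame_equal(ds1.hic.to_triplets(), ds2.hic.to_triplets())
    pd.testing.assert_frame_equal(ds1.rna_counts, ds2.rna_counts)
    pd.testing.assert_frame_equal(ds1.gene_truth, ds2.gene_truth)


def test_different_seeds_differ(small_config):
    other = SimConfig(**{**small_config.__dict__, "seed": 6})
    ds1 = generate_dataset(small_config)
    ds2 = generate_dataset(other)
    assert not ds1.regions.equals(ds2.regions)


def test_planted_class_fractions(default_dataset):
    counts = default_dataset.truth["class"].value_counts()
    n = counts.sum()
    assert n == 2000
    hyper = sum(counts.get(c, 0) for c in HYPERACETYLATED_CLASSES)
    assert hyper / n == pytest.approx(0.26, abs=0.005)


def test_regions_respect_min_gap_outside_clusters(default_dataset):
    reg = default_dataset.regions.merge(default_dataset.truth, on="region_id")
    reg = reg.sort_values(["chrom", "start"]).reset_index(drop=True)
    for i in range(1, len(reg)):
        a, b = reg.iloc[i - 1], reg.iloc[i]
        if a["chrom"] != b["chrom"]:
            continue
        assert b["start"] >= a["end"], "planted regions must not overlap"
        same_cluster = a["cluster_id"] != "" and a["cluster_id"] == b["cluster_id"]
        if not same_cluster:
            assert b["start"] - a["end"] >= default_dataset.config.min_gap


def test_marginal_count_means_match_configuration(default_dataset):
    """Normalized mean counts track the planted means within 3 standard errors."""
    cfg = default_dataset.config
    sheet = default_dataset.sample_sheet.set_index("sample_id")
    truth = default_dataset.truth.set_index("region_id")["class"]
    k27 = default_dataset.counts["H3K27Ac"]
    null_ids = truth[truth == "null"].index
    for sample in ("H3K27Ac_WT_hypo_rep1", "H3K27Ac_WT_hyper_rep1"):
        s = sheet.loc[sample, "lib_size"] / 1e7
        vals = k27.loc[null_ids, sample] / s
        mu = cfg.baseline_mean
        se = np.sqrt((mu + cfg.dispersion * mu ** 2) / len(vals))
        assert abs(vals.mean() - mu) < 3 * se
    planted = truth[truth.isin(HYPERACETYLATED_CLASSES)].index
    s = sheet.loc["H3K27Ac_WT_hyper_rep1", "lib_size"] / 1e7
    vals = k27.loc[planted, "H3K27Ac_WT_hyper_rep1"] / s
    mu = cfg.baseline_mean * cfg.ac_fold
    se = np.sqrt((mu + cfg.dispersion * mu ** 2) / len(vals))
    assert abs(vals.mean() - mu) < 3 * se


def test_indirect_regions_have_partner_with_trbs(default_dataset):
    truth = default_dataset.truth
    by_cluster = truth[truth["cluster_id"] != ""].groupby("cluster_id")
    for _, grp in by_cluster:
        assert (grp["class"] == "indirect_SE").sum() >= 1
        assert grp["class"].isin(("type1A", "type1B")).sum() >= 1
    loops = default_dataset.loops
    cls = truth.set_index("region_id")["class"]
    for _, row in loops.iterrows():
        pair = {cls[row["region_a"]], cls[row["region_b"]]}
        assert "indirect_loop" in pair
        assert pair & {"type1A", "type1B"}


def test_placement_infeasible_raises():
    cfg = SimConfig(seed=2, n_chrom=1, chrom_len=2_100_000, n_regions=600)
    with pytest.raises(ValueError, match="infeasible"):
        generate_dataset(cfg)


class TestGenerateHic:
    def _loop_pairs(self, ds):
        reg = ds.regions.set_index("region_id")
        mids = (reg["start"] + reg["end"]) // 2
        return [((reg.loc[a, "chrom"], int(mids[a])),
                 (reg.loc[b, "chrom"], int(mids[b])))
                for a, b in zip(ds.loops["region_a"], ds.loops["region_b"])]

    def test_no_boost_indistinguishable_from_background(self, small_config):
        cfg = SimConfig(**{**small_config.__dict__, "loop_boost": 1.0})
        ds = generate_dataset(cfg)
        obs, bg = [], []
        for a, b in self._loop_pairs(ds):
            r = opposite_background(ds.hic, a, b, cfg.hic_window)
            if r is None:
                continue
            obs.append(quantify_contact(ds.hic, a, b, cfg.hic_window))
            bg.append(r.count)
        res = wilcoxon_signed_rank(np.array(obs, float), np.array(bg, float))
        assert res.p_value > 0.05

    def test_planted_loops_exceed_mirrored_background(self, default_dataset):
        ds = default_dataset
        obs, bg = [], []
        for a, b in self._loop_pairs(ds):
            r = opposite_background(ds.hic, a, b, ds.config.hic_window)
            if r is None:
                continue
            obs.append(quantify_contact(ds.hic, a, b, ds.config.hic_window))
            bg.append(r.count)
        res = wilcoxon_signed_rank(np.array(obs, float), np.array(bg, float))
        assert res.p_value < 0.001

    def test_decay_is_monotone_from_diagonal(self, default_dataset):
        mat = default_dataset.hic.matrices["chr1"].tocoo()
        d = mat.col - mat.row
        nb = default_dataset.hic.n_bins["chr1"]
        mean_diag = mat.data[d == 0].sum() / nb
        far = (d > 200) & (d <= 400)
        mean_far = mat.data[far].sum() / (d > 200).size  # upper bound on pairs
        assert mean_diag > mean_far


class TestEvaluateRecovery:
    def test_perfect_labels(self, default_dataset):
        truth = default_dataset.truth.set_index("region_id")["class"]
        table = evaluate_recovery(truth, truth).set_index("class")
        for cls in HYPERACETYLATED_CLASSES:
            assert table.loc[cls, "precision"] == 1.0
            assert table.loc[cls, "recall"] == 1.0

    def test_permuted_labels_recall_matches_class_frequency(self, default_dataset):
        truth = default_dataset.truth.set_index("region_id")["class"]
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(truth.to_numpy()), index=truth.index)
        table = evaluate_recovery(perm, truth).set_index("class")
        freq = truth.value_counts(normalize=True)
        for cls in ("null", "constitutive"):
            assert table.loc[cls, "recall"] == pytest.approx(freq[cls], abs=0.08)

    def test_missing_class_precision_flagged(self):
        truth = pd.Series(["a", "a", "b"], index=["x", "y", "z"])
        pred = pd.Series(["a", "a", "a"], index=["x", "y", "z"])
        table = evaluate_recovery(pred, truth).set_index("class")
        assert np.isnan(table.loc["b", "precision"])
        assert table.loc["b", "undefined_precision"]
        assert table.loc["b", "recall"] == 0.0

    def test_unknown_label_raises(self):
        truth = pd.Series(["a", "b"], index=["x", "y"])
        pred = pd.Series(["a", "c"], index=["x", "y"])
        with pytest.raises(ValueError, match="unknown"):
            evaluate_recovery(pred, truth)

    def test_universe_mismatch_raises(self):
        truth = pd.Series(["a"], index=["x"])
        pred = pd.Series(["a"], index=["y"])
        with pytest.raises(ValueError, match="universes"):
            evaluate_recovery(pred, truth)


def test_write_dataset_roundtrips_key_tables(tmp_path, small_config):
    ds = generate_dataset(small_config)
    ds.write(tmp_path)
    regions = pd.read_csv(tmp_path / "regions.bed", sep="\t", header=None)
    assert len(regions) == len(ds.regions)
    counts = pd.read_csv(tmp_path / "counts_H3K27Ac.tsv", sep="\t", index_col=0)
    pd.testing.assert_frame_equal(counts, ds.counts["H3K27Ac"],
                                  check_names=False)
    trip = pd.read_csv(tmp_path / "hic_triplets.tsv", sep="\t")
    sizes = pd.read_csv(tmp_path / "chrom_sizes.tsv", sep="\t")
    mat = t3enh.ContactMatrix.from_triplets(
        trip, small_config.hic_resolution,
        dict(zip(sizes["chrom"], sizes["size"])))
    pd.testing.assert_frame_equal(mat.to_triplets(), ds.hic.to_triplets())
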