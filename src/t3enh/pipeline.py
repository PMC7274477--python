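"""End-to-end orchestration: simulate -> diff -> classify -> SE -> Hi-C -> genes.

``run_all`` executes every stage on a synthetic dataset and returns a
JSON-serializable report holding each stage's key numbers, every
resampling test (with its seed) and, because the data are synthetic,
per-stage recovery of the planted truth.  Identical config and seed
give byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import classify as cls_mod
from . import genes as genes_mod
from . import hic as hic_mod
from . import regions as reg_mod
from . import superenhancers as se_mod
from .simulate import HYPERACETYLATED_CLASSES, SimConfig, generate_dataset
from .stats import fisher_exact_2x2, wilcoxon_signed_rank


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults follow the standard analysis choices."""

    seed: int
    fdr: float = 0.01
    lfc: float = 1.0
    acute_fdr: float = 0.05
    acute_lfc: float = 0.0
    se_stitch: int = 12500
    hic_window: int = 10000
    hic_min_distance: int = 50_000
    hic_max_distance: int = 2_000_000
    hic_significance: float = 1e-5
    link_distance: int = 100_000
    n_random_regions: int = 600
    n_random_genes: int = 1000
    n_random_gene_sets: int = 10

    def __post_init__(self):
        for name in ("fdr", "lfc", "acute_fdr", "se_stitch", "hic_window",
                     "link_distance", "n_random_regions", "n_random_genes",
                     "n_random_gene_sets"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _sample_cols(sheet: pd.DataFrame, target: str, condition: str,
                 genotype: str = "WT") -> list[str]:
    sel = sheet[(sheet["target"] == target) & (sheet["condition"] == condition) &
                (sheet["genotype"] == genotype)]
    return sel["sample_id"].tolist()


def _depth_factors(sheet: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """Sequencing-depth size factors (tags per 1e7) for ChIP contrasts.

    A quarter of the region universe responds to hormone in one
    direction, which biases data-driven median-ratio factors; ChIP tag
    counts are therefore normalized to library depth, the standard
    tag-normalization for ChIP-seq tracks.
    """
    libs = sheet.set_index("sample_id")["lib_size"].reindex(cols).to_numpy()
    return libs / 1e7


def _paired_signed_rank(high: np.ndarray, low: np.ndarray):
    """Signed-rank of two groups paired by descending rank (common length)."""
    a = np.sort(np.asarray(high, dtype=float))[::-1]
    b = np.sort(np.asarray(low, dtype=float))[::-1]
    n = min(len(a), len(b))
    if n < 6:
        return wilcoxon_signed_rank(a[:n], b[:n]) if n else None
    return wilcoxon_signed_rank(a[:n], b[:n])


def run_all(sim_config: SimConfig, run_config: RunConfig | None = None) -> dict:
    """Run the full pipeline on a synthetic dataset and report every stage."""
    run = run_config or RunConfig(seed=sim_config.seed)
    ds = generate_dataset(sim_config)
    sheet = ds.sample_sheet
    report: dict = {
        "sim_config": _jsonable(asdict(sim_config)),
        "run_config": _jsonable(asdict(run)),
    }

    # --- differential acetylation, both marks, hypo vs hyper ---------------
    diffs = {}
    for mark in ("H3K27Ac", "H3K9Ac"):
        ref = _sample_cols(sheet, mark, "hypo")
        trt = _sample_cols(sheet, mark, "hyper")
        diffs[mark] = reg_mod.differential_regions(
            ds.counts[mark], ref, trt, q_thresh=run.fdr, lfc_thresh=run.lfc,
            size_factors=_depth_factors(sheet, ref + trt))
    hc = reg_mod.high_confidence_intersect(diffs["H3K27Ac"], diffs["H3K9Ac"])
    hc_ids = set(hc.loc[hc["is_high_confidence"], "unit_id"])
    report["differential"] = {
        mark: {"n_tested": int(len(d)), "n_significant": int(d["significant"].sum())}
        for mark, d in diffs.items()}

    truth_map = ds.truth.set_index("region_id")["class"]
    planted_hyper = set(truth_map[truth_map.isin(HYPERACETYLATED_CLASSES)].index)
    tp = len(hc_ids & planted_hyper)
    report["high_confidence"] = {
        "n": len(hc_ids),
        "recall": tp / len(planted_hyper) if planted_hyper else float("nan"),
        "precision": tp / len(hc_ids) if hc_ids else float("nan"),
    }

    # --- TRBS annotation and tertile classification ------------------------
    annotated = cls_mod.annotate_overlaps(ds.regions, ds.peaks)
    annotated["class"] = truth_map.reindex(annotated["region_id"]).to_numpy()
    hyper_regions = annotated[annotated["region_id"].isin(hc_ids)].reset_index(drop=True)
    w_trbs = hyper_regions[hyper_regions["has_trbs"]].reset_index(drop=True)
    no_trbs = hyper_regions[~hyper_regions["has_trbs"]].reset_index(drop=True)

    hdac3_hypo = cls_mod.occupancy_from_counts(
        ds.counts["HDAC3"], sheet, "HDAC3", "hypo")
    trbs = cls_mod.classify_tertiles(
        w_trbs, hdac3_hypo.reindex(w_trbs["region_id"]).to_numpy())
    tert = trbs.set_index("region_id")["tertile_class"]

    def _tert_precision(label: str) -> float:
        pred = set(tert[tert == label].index)
        if not pred:
            return float("nan")
        return len([r for r in pred if truth_map.get(r) == label]) / len(pred)

    dens_1a = trbs.loc[trbs["tertile_class"] == "type1A", "hdac3_density_hypo"]
    dens_1b = trbs.loc[trbs["tertile_class"] == "type1B", "hdac3_density_hypo"]
    sr = _paired_signed_rank(dens_1a.to_numpy(), dens_1b.to_numpy())
    report["trbs"] = {
        "n": int(len(trbs)),
        "frac_hyperacetylated_with_trbs": float(len(w_trbs) / max(len(hyper_regions), 1)),
        "tertile_sizes": {k: int(v) for k, v in
                          trbs["tertile_class"].value_counts().items()},
        "type1a_precision": _tert_precision("type1A"),
        "type1b_precision": _tert_precision("type1B"),
        "hdac3_hypo_1a_vs_1b": {
            "median_1a": float(dens_1a.median()) if len(dens_1a) else float("nan"),
            "median_1b": float(dens_1b.median()) if len(dens_1b) else float("nan"),
            "signed_rank_p": sr.p_value if sr else float("nan"),
        },
    }

    # --- super-enhancers ----------------------------------------------------
    k27_hyper_signal = cls_mod.occupancy_from_counts(
        ds.counts["H3K27Ac"], sheet, "H3K27Ac", "hyper")
    peaks = ds.regions.copy()
    peaks["signal"] = k27_hyper_signal.reindex(peaks["region_id"]).to_numpy()
    peaks["id"] = peaks["region_id"]
    stitched = se_mod.stitch_peaks(peaks, stitch_distance=run.se_stitch)
    ses = se_mod.se_cutoff(stitched)
    supers = ses[ses["is_super"]]

    cluster_ids = sorted(set(ds.truth.loc[ds.truth["cluster_id"] != "", "cluster_id"]))
    reg_ix = ds.regions.set_index("region_id")
    recovered = 0
    for cid in cluster_ids:
        members = ds.truth.loc[ds.truth["cluster_id"] == cid, "region_id"]
        span = reg_ix.loc[members]
        cluster_iv = pd.DataFrame({"chrom": [span["chrom"].iloc[0]],
                                   "start": [int(span["start"].min())],
                                   "end": [int(span["end"].max())]})
        from .intervals import overlaps_any
        if overlaps_any(cluster_iv, supers)[0]:
            recovered += 1
    n_rand = min(run.n_random_regions, len(ds.regions) - len(no_trbs))
    se_enrich = se_mod.se_cooccupancy_enrichment(
        ses, no_trbs, w_trbs, ds.regions, n_random=n_rand, seed=run.seed)
    report["superenhancers"] = {
        "n_stitched": int(len(ses)),
        "n_super": int(len(supers)),
        "mean_super_span": float((supers["end"] - supers["start"]).mean())
        if len(supers) else float("nan"),
        "cluster_recovery": recovered / len(cluster_ids) if cluster_ids else float("nan"),
        "cooccupancy_enrichment": se_enrich.to_dict(),
    }

    # --- Hi-C ---------------------------------------------------------------
    pairs = hic_mod.detect_interactions(
        ds.hic, hyper_regions, min_distance=run.hic_min_distance,
        max_distance=run.hic_max_distance, significance=run.hic_significance,
        window=run.hic_window)
    status = hyper_regions.set_index("region_id")["tr_status"]
    cross = pairs[
        (status.reindex(pairs["region_a"]).to_numpy() !=
         status.reindex(pairs["region_b"]).to_numpy())].reset_index(drop=True)
    contacts, sr_contacts = hic_mod.contacts_vs_background(
        ds.hic, cross, ds.regions, window=run.hic_window)
    planted = {tuple(sorted(p)) for p in
               zip(ds.loops["region_a"], ds.loops["region_b"])}
    found = {tuple(sorted(p)) for p in zip(pairs["region_a"], pairs["region_b"])}
    tad_enrich = hic_mod.tad_confinement(
        no_trbs, w_trbs, ds.tads, ds.regions,
        n_random=n_rand, seed=run.seed + 1)
    dist_prof = hic_mod.nearest_distance_profile(no_trbs, w_trbs, ds.regions,
                                                 seed=run.seed + 2)
    report["hic"] = {
        "n_detected_pairs": int(len(pairs)),
        "n_cross_status_pairs": int(len(cross)),
        "loop_recovery": len(planted & found) / len(planted) if planted else float("nan"),
        "contacts_vs_background": {
            "n_pairs": int(len(contacts)),
            "median_observed": float(contacts["observed"].median()) if len(contacts) else float("nan"),
            "median_background": float(contacts["background"].median()) if len(contacts) else float("nan"),
            "signed_rank_p": sr_contacts.p_value,
        },
        "tad_confinement": tad_enrich.to_dict(),
        "nearest_distance": {
            "median_to_w_trbs": dist_prof.median_to_target,
            "median_to_random": dist_prof.median_to_random,
            "seed": dist_prof.seed,
        },
    }

    # --- explanation tags for no/TRBS regions -------------------------------
    from .intervals import assign_to_containers, overlaps_any
    pos_ses = supers[overlaps_any(supers, w_trbs)] if len(supers) else supers
    in_se = overlaps_any(no_trbs, pos_ses) if len(pos_ses) else np.zeros(len(no_trbs), bool)
    loop_partners = set()
    for _, p in cross.iterrows():
        loop_partners.update((p["region_a"], p["region_b"]))
    in_loop = no_trbs["region_id"].isin(loop_partners).to_numpy()
    w_tads = set(assign_to_containers(w_trbs, ds.tads))
    w_tads.discard(-1)
    tad_assign = assign_to_containers(no_trbs, ds.tads)
    in_tad = np.array([t in w_tads and t != -1 for t in tad_assign], dtype=bool)
    report["no_trbs_explanations"] = {
        "n": int(len(no_trbs)),
        "in_SE_with_TRBS": int(in_se.sum()),
        "loop_to_TRBS": int(in_loop.sum()),
        "TAD_with_TRBS": int(in_tad.sum()),
        "unexplained": int((~(in_se | in_loop | in_tad)).sum()),
    }

    # --- acute kinetics -----------------------------------------------------
    k27 = ds.counts["H3K27Ac"]
    ref = _sample_cols(sheet, "H3K27Ac", "hypo")
    acute = {}
    for cond in ("t3_2h", "t3_6h"):
        cols = _sample_cols(sheet, "H3K27Ac", cond)
        if not cols:
            continue
        acute[cond] = {
            "frac_w_trbs": reg_mod.acute_response_fraction(
                k27, ref, cols, w_trbs["region_id"],
                q_thresh=run.acute_fdr, lfc_thresh=run.acute_lfc,
                size_factors=_depth_factors(sheet, ref + cols)),
            "frac_no_trbs": reg_mod.acute_response_fraction(
                k27, ref, cols, no_trbs["region_id"],
                q_thresh=run.acute_fdr, lfc_thresh=run.acute_lfc,
                size_factors=_depth_factors(sheet, ref + cols)),
        }
    report["acute"] = acute

    # --- corepressor disruption: acetylation at type 1A vs 1B ---------------
    ncor = {}
    for mark in ("H3K27Ac", "H3K9Ac"):
        wt = _sample_cols(sheet, mark, "hypo", "WT")
        mut = _sample_cols(sheet, mark, "hypo", "NCOR1dID")
        if not mut:
            continue
        d = reg_mod.differential_regions(ds.counts[mark], wt, mut,
                                         q_thresh=run.fdr, lfc_thresh=0.0,
                                         size_factors=_depth_factors(sheet, wt + mut))
        d = d.set_index("unit_id")
        lfc_1a = d["log2fc"].reindex(tert[tert == "type1A"].index).dropna()
        lfc_1b = d["log2fc"].reindex(tert[tert == "type1B"].index).dropna()
        ncor[mark] = {
            "median_lfc_type1A": float(lfc_1a.median()) if len(lfc_1a) else float("nan"),
            "median_lfc_type1B": float(lfc_1b.median()) if len(lfc_1b) else float("nan"),
            "frac_significant_type1A": float(
                d["significant"].reindex(lfc_1a.index).mean()) if len(lfc_1a) else float("nan"),
            "frac_significant_type1B": float(
                d["significant"].reindex(lfc_1b.index).mean()) if len(lfc_1b) else float("nan"),
        }
    report["ncor_acetylation"] = ncor

    # --- gene expression and linkage ----------------------------------------
    rna_sheet = ds.rna_sample_sheet
    ref = _sample_cols(rna_sheet, "RNA", "hypo", "WT")
    trt = _sample_cols(rna_sheet, "RNA", "hyper", "WT")
    de, induced, repressed = genes_mod.de_genes(ds.rna_counts, ref, trt,
                                                q_thresh=run.fdr, lfc_thresh=run.lfc)
    did_cols = _sample_cols(rna_sheet, "RNA", "hypo", "NCOR1dID")
    _, did_induced, _ = genes_mod.de_genes(ds.rna_counts, ref, did_cols,
                                           q_thresh=run.fdr, lfc_thresh=0.0)
    did_outcome = pd.Series(ds.genes["gene_id"].isin(set(did_induced)).to_numpy(),
                            index=ds.genes["gene_id"])

    link_regions = hyper_regions.copy()
    link_regions["tertile_class"] = tert.reindex(link_regions["region_id"]).fillna("").to_numpy()
    links = genes_mod.link_regions_to_genes(link_regions, ds.genes,
                                            max_distance=run.link_distance)
    linked_genes = set(links["gene_id"])
    ind_linked = len(set(induced) & linked_genes)
    rep_linked = len(set(repressed) & linked_genes)
    fisher = fisher_exact_2x2([
        [ind_linked, len(induced) - ind_linked],
        [rep_linked, len(repressed) - rep_linked]]) if induced and repressed else None

    genes_1a = sorted(set(links.loc[links["tertile_class"] == "type1A", "gene_id"]))
    genes_1b = sorted(set(links.loc[links["tertile_class"] == "type1B", "gene_id"]))
    n_per_set = min(run.n_random_genes, len(ds.genes))
    enr_1a = genes_mod.random_gene_enrichment(
        genes_1a, did_outcome, ds.genes["gene_id"], n_per_set=n_per_set,
        n_sets=run.n_random_gene_sets, seed=run.seed + 3)
    enr_1b = genes_mod.random_gene_enrichment(
        genes_1b, did_outcome, ds.genes["gene_id"], n_per_set=n_per_set,
        n_sets=run.n_random_gene_sets, seed=run.seed + 4)

    gene_truth = ds.gene_truth.set_index("gene_id")
    true_induced = set(gene_truth[gene_truth["is_induced"]].index)
    report["genes"] = {
        "n_induced": len(induced),
        "n_repressed": len(repressed),
        "induced_recall": len(set(induced) & true_induced) / len(true_induced)
        if true_induced else float("nan"),
        "n_did_induced": len(did_induced),
        "n_linked_genes": len(linked_genes),
        "frac_induced_linked": ind_linked / len(induced) if induced else float("nan"),
        "frac_repressed_linked": rep_linked / len(repressed) if repressed else float("nan"),
        "linkage_fisher_p": fisher.p_value if fisher else float("nan"),
        "linkage_fisher_or": fisher.odds_ratio if fisher else float("nan"),
        "n_genes_type1A_linked": len(genes_1a),
        "n_genes_type1B_linked": len(genes_1b),
        "ncor_fold_type1A": enr_1a.to_dict(),
        "ncor_fold_type1B": enr_1b.to_dict(),
    }

    # --- binary recovery of the hyperacetylation task -----------------------
    from .simulate import evaluate_recovery
    pred = pd.Series(
        np.where(ds.regions["region_id"].isin(hc_ids), "hyperacetylated",
                 "background"),
        index=ds.regions["region_id"])
    tru = pd.Series(
        np.where(truth_map.reindex(ds.regions["region_id"]).isin(
            HYPERACETYLATED_CLASSES), "hyperacetylated", "background"),
        index=ds.regions["region_id"])
    rec = evaluate_recovery(pred, tru)
    report["recovery"] = {
        row["class"]: {"precision": _f(row["precision"]), "recall": _f(row["recall"])}
        for _, row in rec.iterrows()}
    return _jsonable(report)


def _f(x) -> float:
    return float(x)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays so json.dumps is deterministic."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
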