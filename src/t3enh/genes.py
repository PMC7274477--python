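"""Differential expression, RPKM, region-gene linkage, random-gene nulls.

Genes are linked to hyperacetylated regions lying within a fixed
distance of the TSS (default 100 kb, measured TSS to the nearest region
edge, inclusive; distance 0 when the region spans the TSS).  Enrichment
of an outcome (e.g. induction upon corepressor disruption) within a
gene set is expressed as fold change over the mean of random gene sets,
with a one-sample t-test of the random fractions against the observed
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regions import differential_regions


def compute_rpkm(gene_counts: pd.DataFrame, exonic_lengths: pd.Series,
                 library_sizes: pd.Series) -> pd.DataFrame:
    """Reads per kilobase of exon per million library reads."""
    lengths = exonic_lengths.reindex(gene_counts.index)
    if (lengths <= 0).any():
        raise ValueError("exonic lengths must be positive")
    libs = library_sizes.reindex(gene_counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    return gene_counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)


def de_genes(rna_counts: pd.DataFrame, ref_cols: list[str], trt_cols: list[str],
             q_thresh: float = 0.01, lfc_thresh: float = 1.0,
             **test_kwargs) -> tuple[pd.DataFrame, list[str], list[str]]:
    """NB differential expression; returns (full results, induced, repressed).

    Induced: q < q_thresh and log2FC > lfc_thresh.  Repressed:
    q < q_thresh and log2FC < -lfc_thresh.  The hormone contrast uses
    lfc_thresh=1; corepressor-disruption contrasts use lfc_thresh=0.
    """
    res = differential_regions(rna_counts, ref_cols, trt_cols,
                               q_thresh=q_thresh, lfc_thresh=lfc_thresh,
                               **test_kwargs)
    induced = res.loc[res["significant"], "unit_id"].tolist()
    repressed = res.loc[(res["q_value"] < q_thresh) &
                        (res["log2fc"] < -lfc_thresh), "unit_id"].tolist()
    return res, induced, repressed


def tss_distance(region_start: np.ndarray, region_end: np.ndarray,
                 tss: int | np.ndarray) -> np.ndarray:
    """Distance from TSS to the nearest base of [start, end); 0 if spanned."""
    return np.maximum.reduce([region_start - tss, tss - (region_end - 1),
                              np.zeros_like(region_start)])


def link_regions_to_genes(regions: pd.DataFrame, genes: pd.DataFrame,
                          max_distance: int = 100_000) -> pd.DataFrame:
    """All (gene, region) pairs with TSS-to-region distance <= max_distance.

    The bound is inclusive: a region edge exactly ``max_distance`` from
    the TSS still links.  Carries the region's class columns when
    present.
    """
    rows = []
    extra_cols = [c for c in ("class", "tr_status", "tertile_class")
                  if c in regions.columns]
    for chrom, g_sub in genes.groupby("chrom", sort=True):
        r_sub = regions[regions["chrom"] == chrom]
        if len(r_sub) == 0:
            continue
        starts = r_sub["start"].to_numpy()
        ends = r_sub["end"].to_numpy()
        ids = r_sub["region_id"].to_numpy()
        extras = {c: r_sub[c].to_numpy() for c in extra_cols}
        for gene_id, tss in zip(g_sub["gene_id"], g_sub["tss"]):
            d = tss_distance(starts, ends, int(tss))
            hit = np.flatnonzero(d <= max_distance)
            for h in hit:
                rows.append((gene_id, ids[h], int(d[h]),
                             *[extras[c][h] for c in extra_cols]))
    return pd.DataFrame(rows, columns=["gene_id", "region_id", "distance",
                                       *extra_cols])


@dataclass
class GeneSetEnrichment:
    observed_fraction: float
    random_fractions: list
    fold_enrichment: float
    t_p_value: float
    n_gene_set: int
    degenerate: bool = False  # random fractions all zero: fold undefined
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed_fraction": self.observed_fraction,
            "random_fractions": list(self.random_fractions),
            "fold_enrichment": self.fold_enrichment,
            "t_p_value": self.t_p_value,
            "n_gene_set": self.n_gene_set,
            "degenerate": self.degenerate,
            "seed": self.seed,
        }


def random_gene_enrichment(gene_set, outcome: pd.Series, all_genes,
                           n_per_set: int = 1000, n_sets: int = 10,
                           seed: int | None = None) -> GeneSetEnrichment:
    """Fold enrichment of a boolean outcome in a gene set vs random gene sets.

    ``outcome`` is indexed by gene id.  ``n_sets`` sets of ``n_per_set``
    genes are drawn from all genes (without replacement within each
    set); fold = observed fraction / mean random fraction, with a
    two-sided one-sample t-test of the random fractions against the
    observed fraction.
    """
    all_genes = list(all_genes)
    if n_per_set > len(all_genes):
        raise ValueError("n_per_set exceeds the number of annotated genes")
    gene_set = list(gene_set)
    obs = float(outcome.reindex(gene_set).fillna(False).mean()) if gene_set else float("nan")
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_sets):
        draw = rng.choice(len(all_genes), size=n_per_set, replace=False)
        ids = [all_genes[i] for i in draw]
        fracs.append(float(outcome.reindex(ids).fillna(False).mean()))
    fracs = np.array(fracs)
    mean_rand = fracs.mean()
    degenerate = mean_rand == 0
    fold = float("nan") if degenerate else obs / mean_rand
    if np.allclose(fracs, fracs[0]):
        t_p = 0.0 if obs != fracs[0] else 1.0
    else:
        t_p = float(sps.ttest_1samp(fracs, obs).pvalue)
    return GeneSetEnrichment(observed_fraction=obs, random_fractions=fracs.tolist(),
                             fold_enrichment=fold, t_p_value=t_p,
                             n_gene_set=len(gene_set), degenerate=degenerate,
                             seed=seed)
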