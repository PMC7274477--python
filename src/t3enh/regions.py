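"""Acetylation region calling and differential hyperacetylation.

Tracks are per-bin tag counts (DataFrame: chrom, bin_start, count) on a
regular grid.  Region calling scans fixed windows against a Poisson
model of the genome-wide tag density; broad "region" mode merges
significant 1 kb windows closer than a minimum distance, narrow
"factor" mode greedily keeps non-overlapping local-maximum 200 bp
windows.  Differential hyperacetylation wraps the NB Wald test with the
standard (FDR < 0.01, log2FC > 1) decision rule, increase-only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import merge_intervals, overlaps_any, sort_intervals
from .stats import nb_differential_test


def call_regions(track: pd.DataFrame, mode: str = "region",
                 window: int | None = None, min_dist: int = 2500,
                 p_thresh: float = 1e-4, bin_size: int | None = None) -> pd.DataFrame:
    """Call enriched intervals from a binned tag track.

    region mode: sliding windows (default 1000 bp, step = bin size) are
    significant when their tag count beats the genome-wide expectation
    in a Poisson upper tail at ``p_thresh``; significant windows merge
    when separated by less than ``min_dist``.

    factor mode: 200 bp windows, greedy selection of non-overlapping
    local maxima passing the same test; fixed-width peaks centred on
    the maximal window.
    """
    if mode not in ("region", "factor"):
        raise ValueError("mode must be 'region' or 'factor'")
    if window is None:
        window = 1000 if mode == "region" else 200
    cols = ["chrom", "start", "end", "id", "score"]
    if len(track) == 0 or track["count"].sum() == 0:
        return pd.DataFrame(columns=cols)
    if bin_size is None:
        starts = np.sort(track["bin_start"].unique())
        bin_size = int(np.diff(starts).min()) if len(starts) > 1 else window
    if window % bin_size:
        raise ValueError("bin size must divide the window size")
    w_bins = window // bin_size
    total_tags = float(track["count"].sum())
    total_bins = len(track)
    lam = total_tags * w_bins / total_bins  # expectation per window

    out = []
    for chrom, sub in track.groupby("chrom", sort=True):
        sub = sub.sort_values("bin_start")
        grid_start = int(sub["bin_start"].min())
        n_bins = (int(sub["bin_start"].max()) - grid_start) // bin_size + 1
        counts = np.zeros(n_bins)
        counts[(sub["bin_start"].to_numpy() - grid_start) // bin_size] = \
            sub["count"].to_numpy()
        if n_bins < w_bins:
            continue
        win = np.convolve(counts, np.ones(w_bins), mode="valid")
        pvals = sps.poisson.sf(win - 1, lam)
        sig = np.flatnonzero(pvals < p_thresh)
        if len(sig) == 0:
            continue
        win_starts = grid_start + sig * bin_size
        if mode == "region":
            df = pd.DataFrame({"chrom": chrom, "start": win_starts,
                               "end": win_starts + window})
            merged = merge_intervals(df, max_gap=min_dist)
            for _, row in merged.iterrows():
                inside = (win_starts >= row["start"]) & (win_starts + window <= row["end"])
                best = pvals[sig[inside]].min() if inside.any() else pvals[sig].min()
                out.append((chrom, int(row["start"]), int(row["end"]),
                            -np.log10(max(best, 1e-300))))
        else:
            order = sig[np.argsort(win[sig], kind="mergesort")[::-1]]
            taken: list[tuple[int, int]] = []
            for k in order:
                s = grid_start + k * bin_size
                e = s + window
                if any(s < te and e > ts for ts, te in taken):
                    continue
                taken.append((s, e))
                out.append((chrom, s, e, -np.log10(max(pvals[k], 1e-300))))
    res = pd.DataFrame(out, columns=["chrom", "start", "end", "score"])
    res = sort_intervals(res)
    res["id"] = [f"peak{i:05d}" for i in range(len(res))]
    return res[cols]


def concordant_set(peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame) -> pd.DataFrame:
    """Replicate-concordant peaks: rep1 entries overlapping >= 1 bp of rep2.

    Rep1 coordinates are retained.
    """
    keep = overlaps_any(peaks_rep1, peaks_rep2)
    return peaks_rep1[keep].reset_index(drop=True)


def differential_regions(counts: pd.DataFrame, ref_cols: list[str],
                         trt_cols: list[str], q_thresh: float = 0.01,
                         lfc_thresh: float = 1.0, **test_kwargs) -> pd.DataFrame:
    """Per-region NB differential test with the hyperacetylation decision rule.

    ``significant`` is increase-only: q < q_thresh and log2FC >
    lfc_thresh (the object of interest is hyperacetylation; decreases
    are reported but not flagged).
    """
    res = nb_differential_test(counts, ref_cols, trt_cols, **test_kwargs)
    res["significant"] = (res["q_value"] < q_thresh) & (res["log2fc"] > lfc_thresh)
    return res


def high_confidence_intersect(k27: pd.DataFrame, k9: pd.DataFrame) -> pd.DataFrame:
    """Regions significantly hyperacetylated at both H3K27 and H3K9.

    Both inputs are ``differential_regions`` outputs over the same
    region universe; the result carries both marks' statistics and
    ``is_high_confidence`` = significant in both.
    """
    if set(k27["unit_id"]) != set(k9["unit_id"]):
        raise ValueError("K27 and K9 results cover different region universes")
    merged = k27.merge(k9, on="unit_id", suffixes=("_k27", "_k9"))
    merged["is_high_confidence"] = (merged["significant_k27"] &
                                    merged["significant_k9"])
    return merged


def high_confidence_intersect_intervals(sig_k27: pd.DataFrame,
                                        sig_k9: pd.DataFrame) -> pd.DataFrame:
    """Interval variant for independently called mark regions.

    K27 regions overlapping >= 1 bp of a significant K9 region; K27
    coordinates retained.
    """
    keep = overlaps_any(sig_k27, sig_k9)
    return sig_k27[keep].reset_index(drop=True)


def acute_response_fraction(counts: pd.DataFrame, ref_cols: list[str],
                            acute_cols: list[str], region_ids,
                            q_thresh: float = 0.05, lfc_thresh: float = 0.0,
                            **test_kwargs) -> float:
    """Fraction of the given regions with increased signal after acute treatment."""
    res = differential_regions(counts, ref_cols, acute_cols,
                               q_thresh=q_thresh, lfc_thresh=lfc_thresh,
                               **test_kwargs)
    res = res[res["unit_id"].isin(set(region_ids))]
    if len(res) == 0:
        return float("nan")
    return float(res["significant"].mean())
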