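"""Super-enhancer stitching, rank-signal cutoff and co-occupancy enrichment.

Acetylation peaks closer than the stitch distance (default 12.5 kb, the
usual ROSE/stitching convention, matching constituent spacing of
10-15 kb) are merged; stitched regions are ranked by total signal and
the super-enhancer cutoff is the point where the normalized
signal-vs-rank curve leaves slope one — computed as
argmin_i (y_i - x_i) with x the rank fraction and y the signal scaled
to its maximum, a deterministic restatement of the tangent-of-slope-one
rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import overlaps_any, sort_intervals
from .resampling import EnrichmentResult, draw_random_regions, enrichment_vs_random


def stitch_peaks(peaks: pd.DataFrame, stitch_distance: int = 12500,
                 signal_col: str = "signal") -> pd.DataFrame:
    """Transitive closure of the gap-< stitch_distance relation, per chromosome.

    The stitched interval spans min start to max end of its
    constituents; total_signal sums constituent signals.  The gap rule
    is strict: peaks separated by exactly ``stitch_distance`` are not
    stitched.
    """
    if len(peaks) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "total_signal",
                                     "n_constituents", "constituents"])
    df = sort_intervals(peaks)
    rows = []
    cur = None
    for i, (chrom, start, end, sig) in enumerate(zip(
            df["chrom"], df["start"], df["end"], df[signal_col])):
        if cur is not None and chrom == cur["chrom"] and \
                start - cur["end"] < stitch_distance:
            cur["end"] = max(cur["end"], int(end))
            cur["total_signal"] += float(sig)
            cur["constituents"].append(i)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": chrom, "start": int(start), "end": int(end),
                   "total_signal": float(sig), "constituents": [i]}
    rows.append(cur)
    out = pd.DataFrame(rows)
    out["n_constituents"] = out["constituents"].map(len)
    if "id" in df.columns:
        ids = df["id"].to_numpy()
        out["constituents"] = out["constituents"].map(
            lambda idx: [ids[i] for i in idx])
    return out[["chrom", "start", "end", "total_signal", "n_constituents",
                "constituents"]]


def se_cutoff(stitched: pd.DataFrame) -> pd.DataFrame:
    """Rank stitched regions by total signal and mark supers beyond the cutoff.

    With signals sorted ascending, x_i = i/n and y_i = signal_i / max,
    the cutoff index is argmin(y_i - x_i); every region ranked above it
    is a super-enhancer.  slope_at_rank is the discrete derivative of
    the normalized curve.  All-equal signals give no supers (warning).
    """
    if len(stitched) < 3:
        raise ValueError("need >= 3 stitched regions for a rank cutoff")
    out = stitched.copy().reset_index(drop=True)
    order = np.argsort(out["total_signal"].to_numpy(), kind="mergesort")
    n = len(out)
    sig_sorted = out["total_signal"].to_numpy()[order]
    smax = sig_sorted[-1]
    if smax <= 0 or sig_sorted[0] == smax:
        warnings.warn("all stitched signals equal: no super-enhancers called")
        out["rank"] = np.empty(n, dtype=int)
        out.loc[order, "rank"] = np.arange(1, n + 1)
        out["slope_at_rank"] = 0.0
        out["is_super"] = False
        return out
    x = np.arange(1, n + 1) / n
    y = sig_sorted / smax
    cut = int(np.argmin(y - x))  # 0-based index of the cutoff rank
    slope = np.gradient(y, x)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    slope_by_rank = np.empty(n)
    slope_by_rank[order] = slope
    is_super = np.zeros(n, dtype=bool)
    is_super[order[cut + 1:]] = True
    out["rank"] = rank
    out["slope_at_rank"] = slope_by_rank
    out["is_super"] = is_super
    return out


def se_cooccupancy_enrichment(ses: pd.DataFrame, regions_no_trbs: pd.DataFrame,
                              regions_w_trbs: pd.DataFrame,
                              random_pool: pd.DataFrame, n_random: int = 600,
                              seed: int | None = None) -> EnrichmentResult:
    """Do no/TRBS hyperacetylated regions co-occur in SEs with w/TRBS regions?

    A region is positive when it overlaps a super-enhancer that also
    overlaps at least one w/TRBS region.  The null is one draw of
    ``n_random`` regions from the acetylated-region pool (test regions
    excluded), compared by Fisher exact test.
    """
    supers = ses[ses["is_super"]] if "is_super" in ses.columns else ses
    if len(supers) == 0:
        exclude = regions_no_trbs.get("region_id", [])
        rand = draw_random_regions(random_pool, exclude, n_random, seed)
        return enrichment_vs_random(np.zeros(len(regions_no_trbs), dtype=bool),
                                    np.zeros(len(rand), dtype=bool), seed)
    has_w = overlaps_any(supers, regions_w_trbs)
    positive_ses = supers[has_w]

    def positive(df: pd.DataFrame) -> np.ndarray:
        return overlaps_any(df, positive_ses)

    exclude = regions_no_trbs.get("region_id", [])
    rand = draw_random_regions(random_pool, exclude, n_random, seed)
    return enrichment_vs_random(positive(regions_no_trbs), positive(rand), seed)
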