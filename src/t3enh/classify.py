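"""TR-binding-site annotation and poised/established tertile classification.

Hyperacetylated regions are flagged for overlap with TR, HDAC3 and DHS
peak sets; TR-bound regions ("w/TRBS") are then ranked by HDAC3 tag
density in the hypothyroid state and split into tertiles: the top third
(high HDAC3 — poised, type 1A), the bottom third (low HDAC3 —
hormone-established, type 1B), and the middle.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import overlaps_any


def annotate_overlaps(regions: pd.DataFrame, peak_sets: dict) -> pd.DataFrame:
    """Add has_trbs / has_hdac3 / has_dhs flags (>= 1 bp overlap) and tr_status."""
    out = regions.copy()
    key_map = {"TR": "has_trbs", "HDAC3": "has_hdac3", "DHS": "has_dhs"}
    for key, col in key_map.items():
        peaks = peak_sets.get(key)
        out[col] = overlaps_any(out, peaks) if peaks is not None else False
    out["tr_status"] = np.where(out["has_trbs"], "w/TRBS", "no/TRBS")
    out["explanation"] = [set() for _ in range(len(out))]
    return out


def classify_tertiles(trbs: pd.DataFrame, density: pd.Series | np.ndarray,
                      density_col: str = "hdac3_density_hypo") -> pd.DataFrame:
    """Tertile split of TR binding sites by HDAC3 density (descending).

    Stable sort descending on density with (chrom, start) as the tie
    break; the top third becomes type1A, the bottom third type1B, the
    rest mid.  Tertile sizes: floor(n/3), plus one to type1A when
    n mod 3 == 2, so sizes never differ by more than one.
    """
    out = trbs.copy().reset_index(drop=True)
    dens = np.asarray(density, dtype=float)
    if len(dens) != len(out):
        raise ValueError("density vector length does not match TRBS table")
    if (dens < 0).any():
        raise ValueError("densities must be nonnegative")
    out[density_col] = dens
    n = len(out)
    if n < 3:
        warnings.warn("fewer than 3 TRBSs: all assigned to mid tertile")
        out["tertile_class"] = "mid"
        return out
    order = out.sort_values([density_col, "chrom", "start"],
                            ascending=[False, True, True],
                            kind="mergesort").index.to_numpy()
    n_top = n // 3 + (1 if n % 3 == 2 else 0)
    n_bot = n // 3
    labels = np.empty(n, dtype=object)
    labels[order[:n_top]] = "type1A"
    labels[order[n_top:n - n_bot]] = "mid"
    labels[order[n - n_bot:]] = "type1B"
    out["tertile_class"] = labels
    return out


def quantify_occupancy(trbs: pd.DataFrame, tracks: dict, lib_sizes: dict,
                       window: int = 500) -> tuple[pd.DataFrame, pd.Series]:
    """Tag density at TR binding sites from binned tracks.

    For each (target, condition) track — a DataFrame (chrom, bin_start,
    count) — tags falling in a window of +/- ``window`` bp around the
    TRBS centre are summed and scaled to library size per 1e7 tags.
    Returns the density matrix and a per-TRBS flag marking windows
    truncated at a chromosome edge (negative coordinates).
    """
    mids = ((trbs["start"] + trbs["end"]) // 2).to_numpy()
    chroms = trbs["chrom"].to_numpy()
    truncated = pd.Series(mids - window < 0, index=trbs.index)
    data = {}
    for key, track in tracks.items():
        col = np.zeros(len(trbs))
        if len(track):
            starts = np.sort(track["bin_start"].unique())
            bin_size = int(np.diff(starts).min()) if len(starts) > 1 else 1
            for chrom, sub in track.groupby("chrom", sort=False):
                mask = chroms == chrom
                if not mask.any():
                    continue
                bs = sub["bin_start"].to_numpy()
                cnt = sub["count"].to_numpy()
                order = np.argsort(bs)
                bs, cnt = bs[order], cnt[order]
                csum = np.concatenate([[0.0], np.cumsum(cnt)])
                lo = np.maximum(mids[mask] - window, 0)
                hi = mids[mask] + window
                # bins overlapping [lo, hi): bin_start in (lo - bin_size, hi)
                i0 = np.searchsorted(bs, lo - bin_size, side="right")
                i1 = np.searchsorted(bs, hi, side="left")
                col[mask] = csum[i1] - csum[i0]
        scale = 1e7 / float(lib_sizes[key])
        name = key if isinstance(key, str) else "_".join(map(str, key))
        data[name] = col * scale
    return pd.DataFrame(data, index=trbs.index), truncated


def occupancy_from_counts(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
                          target: str, condition: str, genotype: str = "WT"
                          ) -> pd.Series:
    """Replicate-averaged, library-size-normalized tag counts per region.

    Counts are scaled to tags per 1e7 sequenced using the sample
    sheet's library sizes, then averaged across replicates — the
    normalization used for ranking occupancy (e.g. HDAC3 in the
    hypothyroid state).
    """
    sel = sample_sheet[(sample_sheet["target"] == target) &
                       (sample_sheet["condition"] == condition) &
                       (sample_sheet["genotype"] == genotype)]
    if len(sel) == 0:
        raise ValueError(f"no samples for {target}/{condition}/{genotype}")
    norm = []
    for _, row in sel.iterrows():
        norm.append(counts[row["sample_id"]] * (1e7 / float(row["lib_size"])))
    return pd.concat(norm, axis=1).mean(axis=1)
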