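"""Genomic interval primitives.

Intervals are kept in pandas DataFrames with at least the columns
``chrom`` (str), ``start`` and ``end`` (int, 0-based half-open).  All
operations assume ``start < end`` and treat any shared base pair
(>= 1 bp) as an overlap.  Sorted order is (chrom lexicographic, start,
end).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class GenomicInterval(NamedTuple):
    """A single region: chrom plus 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    id: str = ""

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def validate_intervals(df: pd.DataFrame) -> None:
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].index[0]
        raise ValueError(f"interval with start >= end at index {bad}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def midpoints(df: pd.DataFrame) -> np.ndarray:
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it share >= 1 bp with any subject interval?

    Per-chromosome sweep: subjects sorted by start; a query [qs, qe)
    overlaps some subject iff among subjects with start < qe the running
    maximum of ends exceeds qs.
    """
    out = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return out
    q_chrom = query["chrom"].to_numpy()
    q_start = query["start"].to_numpy()
    q_end = query["end"].to_numpy()
    for chrom, sub in subject.groupby("chrom", sort=False):
        mask = q_chrom == chrom
        if not mask.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        ends = sub["end"].to_numpy()[order]
        cummax_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, q_end[mask], side="left")
        hit = np.zeros(mask.sum(), dtype=bool)
        nz = idx > 0
        hit[nz] = cummax_end[idx[nz] - 1] > q_start[mask][nz]
        out[mask] = hit
    return out


def merge_intervals(df: pd.DataFrame, max_gap: int = 0) -> pd.DataFrame:
    """Merge intervals whose gap is strictly smaller than ``max_gap``.

    ``max_gap=0`` merges only book-ended/overlapping intervals; the
    strict inequality means intervals separated by exactly ``max_gap``
    stay apart.
    """
    if len(df) == 0:
        return df.loc[:, ["chrom", "start", "end"]].copy()
    df = sort_intervals(df)
    rows = []
    cur = None
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if cur is not None and chrom == cur[0] and start - cur[2] < max_gap:
            cur[2] = max(cur[2], end)
        else:
            if cur is not None:
                rows.append(tuple(cur))
            cur = [chrom, start, end]
    rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_to_containers(regions: pd.DataFrame, containers: pd.DataFrame) -> np.ndarray:
    """Index of the container whose span holds each region midpoint, -1 if none.

    Containers must be non-overlapping (e.g. TADs); a region straddling a
    boundary is assigned by its midpoint.
    """
    out = np.full(len(regions), -1, dtype=np.int64)
    if len(regions) == 0 or len(containers) == 0:
        return out
    mids = midpoints(regions)
    r_chrom = regions["chrom"].to_numpy()
    for chrom, sub in containers.groupby("chrom", sort=False):
        mask = r_chrom == chrom
        if not mask.any():
            continue
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        rows = sub.index.to_numpy()[order]
        pos = np.searchsorted(starts, mids[mask], side="right") - 1
        ok = (pos >= 0) & (mids[mask] < ends[np.clip(pos, 0, None)])
        idx = np.full(mask.sum(), -1, dtype=np.int64)
        idx[ok] = rows[pos[ok]]
        out[mask] = idx
    return out


def nearest_midpoint_distance(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Midpoint-to-midpoint distance to the nearest same-chromosome subject.

    NaN where the query chromosome holds no subject interval.  A query
    interval that is itself present in the subject set gives distance 0.
    """
    out = np.full(len(query), np.nan)
    if len(query) == 0 or len(subject) == 0:
        return out
    q_mid = midpoints(query).astype(float)
    q_chrom = query["chrom"].to_numpy()
    s_mid = midpoints(subject).astype(float)
    s_chrom = subject["chrom"].to_numpy()
    for chrom in np.unique(q_chrom):
        s = np.sort(s_mid[s_chrom == chrom])
        mask = q_chrom == chrom
        if len(s) == 0:
            continue
        q = q_mid[mask]
        idx = np.searchsorted(s, q)
        left = np.where(idx > 0, np.abs(q - s[np.clip(idx - 1, 0, len(s) - 1)]), np.inf)
        right = np.where(idx < len(s), np.abs(s[np.clip(idx, 0, len(s) - 1)] - q), np.inf)
        out[mask] = np.minimum(left, right)
    return out


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None,
              score_col: str | None = None) -> None:
    out = df.loc[:, ["chrom", "start", "end"]].copy()
    out["name"] = df[name_col] if name_col else "."
    out["score"] = df[score_col] if score_col else 0
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    out.to_csv(path, sep="\t", header=False, index=False)
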