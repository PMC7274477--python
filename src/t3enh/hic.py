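"""Hi-C contact quantification, mirrored backgrounds, loop detection, TADs.

Contacts live in a :class:`ContactMatrix`: per-chromosome sparse
upper-triangular matrices binned at a fixed resolution (cis only).
Region-pair signal is the summed count over the bin pairs covered by a
fixed window around each anchor midpoint, following the common
resolution/window quantification scheme (defaults 5 kb resolution,
10 kb window).

The background for a detected contact is the interaction "in the
opposite direction": the downstream anchor is mirrored to the opposite
side of the upstream anchor (at the bin level, so that on a
translation-invariant matrix the background equals the observed count
exactly); if the mirror falls off the chromosome the other anchor is
mirrored instead, and the pair is excluded when neither side fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .intervals import assign_to_containers, midpoints, nearest_midpoint_distance
from .resampling import EnrichmentResult, draw_random_regions, enrichment_vs_random
from .stats import SignedRankResult, wilcoxon_signed_rank


class ContactMatrix:
    """Cis-only binned contact counts, one sparse upper triangle per chromosome."""

    def __init__(self, resolution: int, chrom_sizes: dict[str, int],
                 matrices: dict[str, sparse.csr_matrix] | None = None,
                 band_bins: int | None = None):
        self.resolution = int(resolution)
        self.chrom_sizes = dict(chrom_sizes)
        self.n_bins = {c: -(-size // self.resolution) for c, size in self.chrom_sizes.items()}
        self.band_bins = band_bins
        self.matrices = {}
        for chrom, nb in self.n_bins.items():
            if matrices and chrom in matrices:
                self.matrices[chrom] = matrices[chrom].tocsr()
            else:
                self.matrices[chrom] = sparse.csr_matrix((nb, nb), dtype=np.int64)

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_entries(cls, resolution: int, chrom_sizes: dict[str, int],
                     entries: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                     band_bins: int | None = None) -> "ContactMatrix":
        mats = {}
        for chrom, (i, j, v) in entries.items():
            nb = -(-chrom_sizes[chrom] // resolution)
            lo = np.minimum(i, j)
            hi = np.maximum(i, j)
            mats[chrom] = sparse.coo_matrix((v, (lo, hi)), shape=(nb, nb)).tocsr()
        return cls(resolution, chrom_sizes, mats, band_bins)

    def _offsets(self) -> dict[str, int]:
        off, cum = {}, 0
        for chrom in self.chrom_sizes:
            off[chrom] = cum
            cum += self.n_bins[chrom]
        return off

    def to_triplets(self) -> pd.DataFrame:
        off = self._offsets()
        frames = []
        for chrom, mat in self.matrices.items():
            coo = mat.tocoo()
            frames.append(pd.DataFrame({
                "bin1": coo.row + off[chrom],
                "bin2": coo.col + off[chrom],
                "count": coo.data,
            }))
        out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["bin1", "bin2", "count"])
        return out.sort_values(["bin1", "bin2"]).reset_index(drop=True)

    @classmethod
    def from_triplets(cls, triplets: pd.DataFrame, resolution: int,
                      chrom_sizes: dict[str, int],
                      band_bins: int | None = None) -> "ContactMatrix":
        obj = cls(resolution, chrom_sizes, band_bins=band_bins)
        off = obj._offsets()
        b1 = triplets["bin1"].to_numpy()
        b2 = triplets["bin2"].to_numpy()
        v = triplets["count"].to_numpy()
        for chrom, nb in obj.n_bins.items():
            o = off[chrom]
            mask = (b1 >= o) & (b1 < o + nb)
            if not mask.any():
                continue
            obj.matrices[chrom] = sparse.coo_matrix(
                (v[mask], (b1[mask] - o, b2[mask] - o)), shape=(nb, nb)).tocsr()
        return obj

    # -- queries -----------------------------------------------------------
    def window_bins(self, chrom: str, mid: int, window: int) -> np.ndarray:
        """Bins overlapping [mid - window/2, mid + window/2), clipped to the chromosome."""
        lo = mid - window // 2
        hi = mid + window // 2
        first = max(lo // self.resolution, 0)
        last = min((hi - 1) // self.resolution, self.n_bins[chrom] - 1)
        if last < first:
            return np.empty(0, dtype=np.int64)
        return np.arange(first, last + 1, dtype=np.int64)

    def pair_sum(self, chrom: str, bins_a: np.ndarray, bins_b: np.ndarray) -> int:
        """Sum of symmetric contact counts over the bin-pair grid A x B."""
        if len(bins_a) == 0 or len(bins_b) == 0:
            return 0
        mat = self.matrices[chrom]
        ii = np.repeat(bins_a, len(bins_b))
        jj = np.tile(bins_b, len(bins_a))
        lo = np.minimum(ii, jj)
        hi = np.maximum(ii, jj)
        return int(np.asarray(mat[lo, hi]).sum())


def quantify_contact(matrix: ContactMatrix, anchor_a, anchor_b,
                     window: int = 10000) -> int:
    """Summed contact count between two cis anchors over the window grid."""
    chrom_a, mid_a = _anchor(anchor_a)
    chrom_b, mid_b = _anchor(anchor_b)
    if chrom_a != chrom_b:
        raise ValueError("cis only: anchors on different chromosomes")
    bins_a = matrix.window_bins(chrom_a, mid_a, window)
    bins_b = matrix.window_bins(chrom_b, mid_b, window)
    return matrix.pair_sum(chrom_a, bins_a, bins_b)


def _anchor(x) -> tuple[str, int]:
    if isinstance(x, tuple) and len(x) == 2:
        return x[0], int(x[1])
    # pandas row / GenomicInterval with chrom/start/end
    chrom = x["chrom"] if not hasattr(x, "chrom") else x.chrom
    start = x["start"] if not hasattr(x, "start") else x.start
    end = x["end"] if not hasattr(x, "end") else x.end
    return chrom, (int(start) + int(end)) // 2


@dataclass(frozen=True)
class BackgroundContact:
    count: int
    side: str  # which anchor was mirrored across: "a" or "b"


def opposite_background(matrix: ContactMatrix, anchor_a, anchor_b,
                        window: int = 10000) -> BackgroundContact | None:
    """Contact count of the mirrored ("opposite direction") pair.

    The downstream anchor's bin set B is reflected about anchor A's bin
    span (bin j maps to min(A)+max(A)-j), preserving the multiset of
    bin distances, so on a translation-invariant matrix the background
    equals the observed count exactly.  If the reflection leaves the
    chromosome, A is reflected about B instead; ``None`` means both
    mirrors fall off the chromosome and the pair must be excluded.
    """
    chrom_a, mid_a = _anchor(anchor_a)
    chrom_b, mid_b = _anchor(anchor_b)
    if chrom_a != chrom_b:
        raise ValueError("cis only: anchors on different chromosomes")
    if mid_b < mid_a:
        (mid_a, mid_b) = (mid_b, mid_a)
    bins_a = matrix.window_bins(chrom_a, mid_a, window)
    bins_b = matrix.window_bins(chrom_a, mid_b, window)
    if len(bins_a) == 0 or len(bins_b) == 0:
        return None
    nb = matrix.n_bins[chrom_a]
    mirror_b = (bins_a.min() + bins_a.max()) - bins_b
    if mirror_b.min() >= 0 and mirror_b.max() < nb:
        return BackgroundContact(matrix.pair_sum(chrom_a, bins_a, mirror_b), side="a")
    mirror_a = (bins_b.min() + bins_b.max()) - bins_a
    if mirror_a.min() >= 0 and mirror_a.max() < nb:
        return BackgroundContact(matrix.pair_sum(chrom_a, mirror_a, bins_b), side="b")
    return None


def distance_decay(matrix: ContactMatrix, n_log_bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Mean count per bin distance, smoothed over log-spaced distance bins.

    Returns (distance_in_bins, expected_count_per_bin_pair) suitable for
    ``np.interp``.  Distances beyond the generated/observed band keep
    the last bin's value.
    """
    max_d = 0
    sums: dict[int, float] = {}
    pairs: dict[int, int] = {}
    for chrom, mat in matrix.matrices.items():
        coo = mat.tocoo()
        d = coo.col - coo.row
        nbins = matrix.n_bins[chrom]
        band = matrix.band_bins if matrix.band_bins is not None else nbins - 1
        band = min(band, nbins - 1)
        max_d = max(max_d, band)
        binc = np.bincount(d, weights=coo.data, minlength=band + 1)
        for dist in range(band + 1):
            sums[dist] = sums.get(dist, 0.0) + binc[dist]
            pairs[dist] = pairs.get(dist, 0) + (nbins - dist)
    if max_d == 0:
        return np.array([0.0]), np.array([sums.get(0, 0.0) / max(pairs.get(0, 1), 1)])
    dists = np.arange(max_d + 1)
    raw = np.array([sums.get(int(t), 0.0) / max(pairs.get(int(t), 1), 1) for t in dists])
    edges = np.unique(np.rint(np.geomspace(1, max_d + 1, n_log_bins + 1)).astype(int))
    centers, means = [0.0], [raw[0]]
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dists >= lo) & (dists < hi)
        if sel.any():
            centers.append(float(dists[sel].mean()))
            means.append(float(raw[sel].mean()))
    return np.array(centers), np.array(means)


def detect_interactions(matrix: ContactMatrix, regions: pd.DataFrame,
                        min_distance: int = 50000, max_distance: int = 2_000_000,
                        significance: float = 1e-5, fold: float = 2.0,
                        window: int = 10000) -> pd.DataFrame:
    """Significant region-region contacts against the distance-decay expectation.

    Candidate pairs are all same-chromosome region pairs with midpoint
    distance in [min_distance, max_distance].  A pair is kept when its
    observed window count exceeds ``fold`` times the expectation
    interpolated from the decay curve and the Poisson upper-tail
    p-value is below ``significance``.
    """
    centers, means = distance_decay(matrix)
    rows = []
    mids = midpoints(regions)
    ids = regions["region_id"].to_numpy() if "region_id" in regions.columns else \
        regions.index.astype(str).to_numpy()
    chroms = regions["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        sel = sel[np.argsort(mids[sel], kind="mergesort")]
        m = mids[sel]
        for ai in range(len(sel)):
            jlo = np.searchsorted(m, m[ai] + min_distance, side="left")
            jhi = np.searchsorted(m, m[ai] + max_distance, side="right")
            for bi in range(jlo, jhi):
                a_bins = matrix.window_bins(chrom, int(m[ai]), window)
                b_bins = matrix.window_bins(chrom, int(m[bi]), window)
                obs = matrix.pair_sum(chrom, a_bins, b_bins)
                dgrid = np.abs(b_bins[None, :] - a_bins[:, None]).ravel()
                exp = float(np.interp(dgrid, centers, means).sum())
                if obs > fold * exp and sps.poisson.sf(obs - 1, exp) < significance:
                    rows.append((ids[sel[ai]], ids[sel[bi]], chrom,
                                 int(m[bi] - m[ai]), obs, exp,
                                 float(sps.poisson.sf(obs - 1, exp))))
    return pd.DataFrame(rows, columns=["region_a", "region_b", "chrom", "distance",
                                       "observed", "expected", "p_value"])


def contacts_vs_background(matrix: ContactMatrix, pairs: pd.DataFrame,
                           regions: pd.DataFrame,
                           window: int = 10000) -> tuple[pd.DataFrame, SignedRankResult]:
    """Observed vs opposite-direction background for detected pairs (paired test)."""
    reg = regions.set_index("region_id")
    rows = []
    for _, p in pairs.iterrows():
        ra = reg.loc[p["region_a"]]
        rb = reg.loc[p["region_b"]]
        a = (ra["chrom"], (int(ra["start"]) + int(ra["end"])) // 2)
        b = (rb["chrom"], (int(rb["start"]) + int(rb["end"])) // 2)
        obs = quantify_contact(matrix, a, b, window)
        bg = opposite_background(matrix, a, b, window)
        if bg is None:
            continue
        rows.append((p["region_a"], p["region_b"], obs, bg.count, bg.side))
    out = pd.DataFrame(rows, columns=["region_a", "region_b", "observed",
                                      "background", "mirror_side"])
    if len(out) == 0:
        return out, SignedRankResult(0.0, 1.0, 0, all_zero=True)
    test = wilcoxon_signed_rank(out["observed"].to_numpy(dtype=float),
                                out["background"].to_numpy(dtype=float))
    return out, test


def tad_confinement(regions_no_trbs: pd.DataFrame, regions_w_trbs: pd.DataFrame,
                    tads: pd.DataFrame, random_pool: pd.DataFrame,
                    n_random: int = 600, seed: int | None = None) -> EnrichmentResult:
    """Fraction of no/TRBS regions sharing a TAD with a w/TRBS region, vs random.

    Regions are assigned to the TAD containing their midpoint
    (unassigned regions count negative).
    """
    w_tads = set(assign_to_containers(regions_w_trbs, tads))
    w_tads.discard(-1)

    def positive(df: pd.DataFrame) -> np.ndarray:
        t = assign_to_containers(df, tads)
        return np.array([x in w_tads and x != -1 for x in t], dtype=bool)

    exclude = regions_no_trbs["region_id"] if "region_id" in regions_no_trbs.columns else []
    rand = draw_random_regions(random_pool, exclude, n_random, seed)
    return enrichment_vs_random(positive(regions_no_trbs), positive(rand), seed)


@dataclass
class DistanceProfile:
    distances_to_target: np.ndarray
    distances_to_random: np.ndarray
    median_to_target: float
    median_to_random: float
    n_excluded: int  # query regions with no same-chromosome target
    seed: int | None = None


def nearest_distance_profile(regions_a: pd.DataFrame, regions_b: pd.DataFrame,
                             random_pool: pd.DataFrame, seed: int | None = None
                             ) -> DistanceProfile:
    """Nearest-neighbour midpoint distances a->b and a->random draw.

    The random comparison set is an equal-size draw from the pool
    (test regions excluded).
    """
    d_target = nearest_midpoint_distance(regions_a, regions_b)
    exclude = regions_a["region_id"] if "region_id" in regions_a.columns else []
    rand = draw_random_regions(random_pool, exclude, min(len(regions_b), len(random_pool)),
                               seed)
    d_rand = nearest_midpoint_distance(regions_a, rand)
    keep_t = ~np.isnan(d_target)
    keep_r = ~np.isnan(d_rand)
    return DistanceProfile(
        distances_to_target=d_target[keep_t],
        distances_to_random=d_rand[keep_r],
        median_to_target=float(np.median(d_target[keep_t])) if keep_t.any() else float("nan"),
        median_to_random=float(np.median(d_rand[keep_r])) if keep_r.any() else float("nan"),
        n_excluded=int((~keep_t).sum()),
        seed=seed,
    )
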