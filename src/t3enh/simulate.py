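"""Truth-labelled synthetic genome for the enhancer-classification pipeline.

The generator plants the regulatory architecture the pipeline is meant
to recover, so every stage can be scored against known labels:

* ``type1A`` — poised TR binding sites: HDAC3/NCOR1-occupied in the
  hypothyroid state (occupancy drops with hormone), TR/CBP
  constitutively bound, acetylation induced by T3.
* ``type1B`` — hormone-established TR sites: HDAC3-free, TR/CBP/MED1
  and DNase accessibility recruited only with T3, acetylation induced.
* ``indirect_SE`` — hyperacetylated without a TR site, sitting inside a
  planted super-enhancer cluster that also contains a TR-bound region.
* ``indirect_loop`` — hyperacetylated without a TR site, connected to a
  TR-bound region by a planted Hi-C loop within the same TAD.
* ``constitutive`` — acetylated in both conditions, no hormone response
  (these populate the random-region pool).
* ``null`` — acetylated background regions with no condition effect.

TADs tile each chromosome; a subset of TADs is "hormone active" and
receives all TR-bound units, clusters and loops, mirroring the
clustering of responsive regulatory regions in real tissue.  Counts are
negative-binomial with per-sample library-size factors; Hi-C counts are
Poisson around a distance-decay background with multiplicative boosts
at planted loop anchors.  One RNG stream per layer (placement, ChIP
counts, Hi-C, RNA), each derived from the single seed, keeps the layers
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hic import ContactMatrix
from .intervals import merge_intervals, sort_intervals, write_bed

HYPERACETYLATED_CLASSES = ("type1A", "type1B", "indirect_SE", "indirect_loop")
ALL_CLASSES = HYPERACETYLATED_CLASSES + ("constitutive", "null")
CHIP_TARGETS = ("H3K27Ac", "H3K9Ac", "H3K4me1", "HDAC3", "NCOR1", "CBP",
                "MED1", "TR", "DNase")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; the defaults are the study conditions."""

    seed: int
    n_chrom: int = 3
    chrom_len: int = 20_000_000
    n_regions: int = 2000
    class_fractions: dict = field(default_factory=lambda: {
        "type1A": 0.10, "type1B": 0.10, "indirect_SE": 0.03,
        "indirect_loop": 0.03, "constitutive": 0.24, "null": 0.50})
    baseline_mean: float = 100.0
    background_mean: float = 5.0
    dispersion: float = 0.05
    ac_fold: float = 4.0           # hyper/hypo acetylation at planted regions
    hdac3_fold_drop: float = 3.0   # type1A HDAC3 hypo -> hyper
    tr_recruit_fold: float = 5.0   # type1B TR/CBP/MED1/DNase hypo -> hyper
    ncor_acetyl_fold: float = 2.5  # type1A acetylation, NCOR1dID vs WT (hypo)
    libsize_jitter: float = 0.3
    se_cluster_size: tuple = (5, 10)
    se_span: int = 12000
    hic_resolution: int = 5000
    hic_window: int = 10000
    hic_base_count: float = 20.0   # Poisson mean at distance zero
    hic_decay_bp: int = 50_000
    hic_max_dist: int = 2_000_000
    loop_boost: float = 6.0
    loop_distance: tuple = (200_000, 800_000)
    tad_length: tuple = (500_000, 2_000_000)
    frac_active_tads: float = 0.35
    min_gap: int = 5000
    n_chip_replicates: int = 2
    n_genes: int = 1500
    frac_induced_genes: float = 0.15
    frac_repressed_genes: float = 0.10
    gene_fold: float = 4.0
    ncor_gene_fold: float = 3.0
    frac_ncor_dependent: float = 0.5  # of type1A-driven induced genes
    n_rna_replicates: int = 4
    link_distance: int = 100_000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.class_fractions.values())
        if total > 1 + 1e-9:
            raise ValueError("class fractions must sum to <= 1")
        for name in ("ac_fold", "hdac3_fold_drop", "tr_recruit_fold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def rng(self, layer: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), layer])


@dataclass
class SyntheticDataset:
    config: SimConfig
    regions: pd.DataFrame           # chrom, start, end, region_id
    truth: pd.DataFrame             # region_id, class, cluster_id, loop_id
    counts: dict                    # target -> DataFrame (regions x samples)
    sample_sheet: pd.DataFrame
    peaks: dict                     # "TR" | "HDAC3" | "DHS" -> BED-like frame
    hic: ContactMatrix
    tads: pd.DataFrame
    loops: pd.DataFrame             # region_a, region_b, distance
    genes: pd.DataFrame             # gene_id, chrom, tss, strand, exonic_length
    rna_counts: pd.DataFrame
    rna_sample_sheet: pd.DataFrame
    gene_truth: pd.DataFrame

    @property
    def chrom_sizes(self) -> dict:
        return {f"chr{i + 1}": self.config.chrom_len
                for i in range(self.config.n_chrom)}

    def write(self, outdir) -> None:
        write_dataset(self, outdir)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _make_tads(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = cfg.tad_length
    res = cfg.hic_resolution
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 0
        while cursor < cfg.chrom_len:
            length = int(rng.integers(lo, hi + 1)) // res * res
            if cfg.chrom_len - (cursor + length) < lo:
                length = cfg.chrom_len - cursor
            rows.append((chrom, cursor, cursor + length))
            cursor += length
    tads = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    tads["tad_id"] = [f"tad{i:04d}" for i in range(len(tads))]
    tads["active"] = rng.random(len(tads)) < cfg.frac_active_tads
    if not tads["active"].any():
        tads.loc[tads.index[0], "active"] = True
    return tads


class _Occupancy:
    """Collision bookkeeping for placed blocks, honouring the minimum gap."""

    def __init__(self, min_gap: int):
        self.min_gap = min_gap
        self.blocks: dict[str, list] = {}

    def collides(self, chrom: str, start: int, end: int) -> bool:
        occ = self.blocks.get(chrom)
        if not occ:
            return False
        arr = np.asarray(occ)
        return bool(((arr[:, 0] < end + self.min_gap) &
                     (arr[:, 1] > start - self.min_gap)).any())

    def add(self, chrom: str, start: int, end: int) -> None:
        self.blocks.setdefault(chrom, []).append((start, end))


def _class_budget(cfg: SimConfig) -> dict:
    n = {cls: int(round(cfg.class_fractions.get(cls, 0.0) * cfg.n_regions))
         for cls in ALL_CLASSES}
    n["null"] += cfg.n_regions - sum(n.values())
    return n


def _place_regions(cfg: SimConfig, tads: pd.DataFrame, rng: np.random.Generator):
    budget = _class_budget(cfg)
    occ = _Occupancy(cfg.min_gap)
    active = tads[tads["active"]].reset_index(drop=True)
    placed = []   # (chrom, start, end, class, cluster_id, loop_id)
    loops = []    # (index_a, index_b) into placed

    def take_tr_class(k: int) -> str:
        cls = "type1A" if k % 2 == 0 else "type1B"
        other = "type1B" if cls == "type1A" else "type1A"
        if budget[cls] <= 0:
            cls = other
        if budget[cls] <= 0:
            raise ValueError("TR-class budget exhausted during placement")
        budget[cls] -= 1
        return cls

    def pick_spot(span: int, tad_pool: pd.DataFrame | None, margin: int = 10_000,
                  tries: int = 300) -> tuple[str, int]:
        for _ in range(tries):
            if tad_pool is not None:
                fit = tad_pool[(tad_pool["end"] - tad_pool["start"]) >= span + 2 * margin]
                if len(fit) == 0:
                    break
                t = fit.iloc[int(rng.integers(len(fit)))]
                start = int(rng.integers(t["start"] + margin, t["end"] - margin - span))
                chrom = t["chrom"]
            else:
                chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
                start = int(rng.integers(0, cfg.chrom_len - span))
            if not occ.collides(chrom, start, start + span):
                return chrom, start
        raise ValueError(
            "class placement infeasible for genome size; increase chrom_len "
            f"above {cfg.chrom_len} or reduce n_regions")

    # super-enhancer clusters: one indirect_SE member each, plus a TR-bound
    # region and constitutive fillers
    n_clusters = budget["indirect_SE"]
    budget["indirect_SE"] = 0
    for k in range(n_clusters):
        size = int(rng.integers(cfg.se_cluster_size[0], cfg.se_cluster_size[1] + 1))
        members = [take_tr_class(k), "indirect_SE"]
        for _ in range(size - 2):
            if budget["constitutive"] > 0:
                budget["constitutive"] -= 1
                members.append("constitutive")
            else:
                budget["null"] -= 1
                members.append("null")
        members = [members[i] for i in rng.permutation(len(members))]
        widths = rng.integers(600, 1001, size=len(members))
        gaps = rng.integers(400, 1001, size=len(members) - 1)
        span = int(widths.sum() + gaps.sum())
        chrom, start = pick_spot(span, active)
        occ.add(chrom, start, start + span)
        cursor = start
        for i, cls in enumerate(members):
            placed.append((chrom, cursor, cursor + int(widths[i]), cls,
                           f"se{k:03d}", ""))
            cursor += int(widths[i]) + (int(gaps[i]) if i < len(gaps) else 0)

    # loop pairs: indirect_loop anchor tied to a TR-bound anchor in one TAD
    n_loops = budget["indirect_loop"]
    budget["indirect_loop"] = 0
    for k in range(n_loops):
        tr_cls = take_tr_class(k + 1)
        dist = int(rng.integers(cfg.loop_distance[0], cfg.loop_distance[1] + 1))
        w_a = int(rng.integers(800, 2001))
        w_b = int(rng.integers(800, 2001))
        margin = 10_000
        fit = active[(active["end"] - active["start"]) >= dist + w_b + 2 * margin]
        if len(fit) == 0:
            raise ValueError(
                "loop placement infeasible: no active TAD long enough; "
                "increase tad_length or shrink loop_distance")
        for attempt in range(500):
            t = fit.iloc[int(rng.integers(len(fit)))]
            start = int(rng.integers(t["start"] + margin,
                                     t["end"] - margin - dist - w_b))
            b_start = start + dist
            chrom = t["chrom"]
            if not occ.collides(chrom, start, start + w_a) and \
               not occ.collides(chrom, b_start, b_start + w_b):
                break
        else:
            raise ValueError("loop placement infeasible for genome size")
        occ.add(chrom, start, start + w_a)
        occ.add(chrom, b_start, b_start + w_b)
        pair_cls = [tr_cls, "indirect_loop"]
        if rng.random() < 0.5:
            pair_cls = pair_cls[::-1]
        ia = len(placed)
        placed.append((chrom, start, start + w_a, pair_cls[0], "", f"loop{k:03d}"))
        placed.append((chrom, b_start, b_start + w_b, pair_cls[1], "", f"loop{k:03d}"))
        loops.append((ia, ia + 1))

    # remaining singles: TR-bound classes in active TADs, the rest anywhere
    singles = ([("type1A", True)] * budget["type1A"] +
               [("type1B", True)] * budget["type1B"] +
               [("constitutive", False)] * budget["constitutive"] +
               [("null", False)] * budget["null"])
    order = rng.permutation(len(singles))
    for idx in order:
        cls, in_active = singles[idx]
        width = int(rng.integers(800, 2001))
        chrom, start = pick_spot(width, active if in_active else None,
                                 margin=5_000 if in_active else 0)
        occ.add(chrom, start, start + width)
        placed.append((chrom, start, start + width, cls, "", ""))

    df = pd.DataFrame(placed, columns=["chrom", "start", "end", "class",
                                       "cluster_id", "loop_id"])
    df["placement_index"] = np.arange(len(df))
    df = sort_intervals(df)
    df["region_id"] = [f"r{i:05d}" for i in range(len(df))]
    idx_to_id = dict(zip(df["placement_index"], df["region_id"]))
    loops_df = pd.DataFrame(
        [(idx_to_id[a], idx_to_id[b]) for a, b in loops],
        columns=["region_a", "region_b"])
    df = df.drop(columns="placement_index")
    return df, loops_df


# ---------------------------------------------------------------------------
# ChIP count layer
# ---------------------------------------------------------------------------

def _occupancy_mean(cfg: SimConfig, target: str, condition: str, genotype: str,
                    cls: str) -> float:
    """Planted mean normalized tag count for one region class and track."""
    B, L = cfg.baseline_mean, cfg.background_mean
    hyper_like = condition in ("hyper", "t3_2h", "t3_6h")
    if target in ("H3K27Ac", "H3K9Ac"):
        if genotype == "NCOR1dID" and condition == "hypo":
            return B * cfg.ncor_acetyl_fold if cls == "type1A" else B
        if hyper_like and cls in HYPERACETYLATED_CLASSES:
            return B * cfg.ac_fold
        return B
    if target == "H3K4me1":
        if cls == "type1B" and not hyper_like:
            return 2 * L
        return B
    if target in ("HDAC3", "NCOR1"):
        if cls == "type1A":
            return B / cfg.hdac3_fold_drop if hyper_like else B
        return L
    if target in ("TR", "CBP"):
        if cls == "type1A":
            return B
        if cls == "type1B":
            return L * cfg.tr_recruit_fold if hyper_like else L
        return L
    if target == "MED1":
        if cls in ("type1A", "type1B"):
            return L * cfg.tr_recruit_fold if hyper_like else L
        return L
    if target == "DNase":
        if cls == "type1B":
            return L * cfg.tr_recruit_fold if hyper_like else L
        return B
    raise ValueError(f"unknown target {target}")


def _chip_design(cfg: SimConfig) -> list[tuple[str, str, str]]:
    design = []
    for target in CHIP_TARGETS:
        design.append((target, "hypo", "WT"))
        design.append((target, "hyper", "WT"))
    design.append(("H3K27Ac", "t3_2h", "WT"))
    design.append(("H3K27Ac", "t3_6h", "WT"))
    design.append(("H3K27Ac", "hypo", "NCOR1dID"))
    design.append(("H3K9Ac", "hypo", "NCOR1dID"))
    return design


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mean) * dispersion)
    return rng.poisson(lam)


def _generate_counts(cfg: SimConfig, regions: pd.DataFrame, rng: np.random.Generator):
    classes = regions["class"].to_numpy()
    sheet_rows = []
    counts: dict[str, dict[str, np.ndarray]] = {t: {} for t in CHIP_TARGETS}
    for target, condition, genotype in _chip_design(cfg):
        mu_class = {cls: _occupancy_mean(cfg, target, condition, genotype, cls)
                    for cls in ALL_CLASSES}
        mu = np.array([mu_class[c] for c in classes])
        for rep in range(1, cfg.n_chip_replicates + 1):
            s = float(np.exp(rng.uniform(np.log(1 - cfg.libsize_jitter),
                                         np.log(1 + cfg.libsize_jitter))))
            sample_id = f"{target}_{genotype}_{condition}_rep{rep}"
            counts[target][sample_id] = _nb_draw(rng, mu * s, cfg.dispersion)
            sheet_rows.append((sample_id, target, condition, genotype, rep,
                               s * 1e7))
    sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "target", "condition",
                                              "genotype", "replicate", "lib_size"])
    tables = {}
    for target in CHIP_TARGETS:
        tables[target] = pd.DataFrame(counts[target],
                                      index=pd.Index(regions["region_id"], name="region_id"))
    return tables, sheet


# ---------------------------------------------------------------------------
# Hi-C layer
# ---------------------------------------------------------------------------

def generate_hic(cfg: SimConfig, chrom_sizes: dict[str, int],
                 loop_anchors: pd.DataFrame | None = None,
                 rng: np.random.Generator | None = None) -> ContactMatrix:
    """Distance-decay Poisson background plus boosted planted loop anchors.

    ``loop_anchors`` needs columns chrom, mid_a, mid_b.  The background
    bin-pair mean at bin distance d is ``hic_base_count / (1 + d*res /
    hic_decay_bp)``; loop anchor bin pairs get an additional Poisson
    component worth ``(loop_boost - 1)`` times the local background, so
    their expectation is ``loop_boost`` times the decay curve.
    """
    if rng is None:
        rng = cfg.rng(3)
    res = cfg.hic_resolution
    band = cfg.hic_max_dist // res
    entries = {}
    for chrom in chrom_sizes:
        nb = -(-chrom_sizes[chrom] // res)
        d_max = min(band, nb - 1)
        ii, jj, vv = [], [], []
        for d in range(d_max + 1):
            mean = cfg.hic_base_count / (1.0 + d * res / cfg.hic_decay_bp)
            row = rng.poisson(mean, size=nb - d)
            nz = np.flatnonzero(row)
            ii.append(nz)
            jj.append(nz + d)
            vv.append(row[nz])
        entries[chrom] = (np.concatenate(ii), np.concatenate(jj),
                          np.concatenate(vv))
    mat = ContactMatrix.from_entries(res, chrom_sizes, entries, band_bins=band)
    if loop_anchors is not None and cfg.loop_boost > 1:
        for _, row in loop_anchors.iterrows():
            chrom = row["chrom"]
            bins_a = mat.window_bins(chrom, int(row["mid_a"]), cfg.hic_window)
            bins_b = mat.window_bins(chrom, int(row["mid_b"]), cfg.hic_window)
            extra_i, extra_j, extra_v = [], [], []
            for i in bins_a:
                for j in bins_b:
                    lo, hi = (int(i), int(j)) if i <= j else (int(j), int(i))
                    mean = cfg.hic_base_count / (1.0 + (hi - lo) * res / cfg.hic_decay_bp)
                    extra = int(rng.poisson(mean * (cfg.loop_boost - 1.0)))
                    if extra:
                        extra_i.append(lo)
                        extra_j.append(hi)
                        extra_v.append(extra)
            if extra_i:
                nb = mat.n_bins[chrom]
                from scipy import sparse
                add = sparse.coo_matrix((extra_v, (extra_i, extra_j)),
                                        shape=(nb, nb)).tocsr()
                mat.matrices[chrom] = (mat.matrices[chrom] + add).tocsr()
    return mat


# ---------------------------------------------------------------------------
# RNA layer
# ---------------------------------------------------------------------------

def _sample_outside(rng, chrom_sizes: dict, forbidden: pd.DataFrame, n: int
                    ) -> list[tuple[str, int]]:
    """Uniform positions in the complement of the forbidden intervals."""
    allowed = []
    for chrom, size in chrom_sizes.items():
        sub = forbidden[forbidden["chrom"] == chrom]
        cursor = 0
        for s, e in zip(sub["start"], sub["end"]):
            s = max(int(s), 0)
            if s > cursor:
                allowed.append((chrom, cursor, s))
            cursor = max(cursor, min(int(e), size))
        if cursor < size:
            allowed.append((chrom, cursor, size))
    lengths = np.array([e - s for _, s, e in allowed], dtype=float)
    if len(allowed) == 0 or lengths.sum() <= 0:
        raise ValueError("no genomic space left outside hyperacetylated windows")
    probs = lengths / lengths.sum()
    out = []
    for _ in range(n):
        k = int(rng.choice(len(allowed), p=probs))
        chrom, s, e = allowed[k]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def _generate_genes(cfg: SimConfig, regions: pd.DataFrame, rng: np.random.Generator):
    hyper = regions[regions["class"].isin(HYPERACETYLATED_CLASSES)].reset_index(drop=True)
    n_ind = int(round(cfg.frac_induced_genes * cfg.n_genes))
    n_rep = int(round(cfg.frac_repressed_genes * cfg.n_genes))
    n_null = cfg.n_genes - n_ind - n_rep
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chrom)}

    drivers = hyper.iloc[rng.choice(len(hyper), size=min(n_ind, len(hyper)),
                                    replace=False)].reset_index(drop=True)
    rows = []
    for _, drv in drivers.iterrows():
        mid = (int(drv["start"]) + int(drv["end"])) // 2
        offset = int(rng.integers(10_000, 80_001)) * (1 if rng.random() < 0.5 else -1)
        tss = int(np.clip(mid + offset, 0, cfg.chrom_len - 1))
        ncor_dep = bool(drv["class"] == "type1A" and
                        rng.random() < cfg.frac_ncor_dependent)
        rows.append((drv["chrom"], tss, "induced", drv["region_id"],
                     drv["class"], ncor_dep))

    # repressed genes are kept clear of hyperacetylated windows so that the
    # induced-vs-repressed linkage contrast reflects planted structure
    forbidden = hyper.copy()
    forbidden["start"] = forbidden["start"] - (cfg.link_distance + cfg.min_gap)
    forbidden["end"] = forbidden["end"] + (cfg.link_distance + cfg.min_gap)
    forbidden = merge_intervals(forbidden)
    for chrom, tss in _sample_outside(rng, chrom_sizes, forbidden, n_rep):
        rows.append((chrom, tss, "repressed", "", "", False))
    for _ in range(n_null):
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        rows.append((chrom, int(rng.integers(cfg.chrom_len)), "null", "", "", False))

    genes = pd.DataFrame(rows, columns=["chrom", "tss", "status", "driver_region",
                                        "driver_class", "is_ncor_dependent"])
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    genes["exonic_length"] = np.exp(rng.uniform(np.log(500), np.log(10_000),
                                                len(genes))).astype(int)
    genes = genes.sort_values(["chrom", "tss"], kind="mergesort").reset_index(drop=True)
    genes["gene_id"] = [f"g{i:04d}" for i in range(len(genes))]

    base = np.exp(rng.uniform(np.log(50), np.log(2000), len(genes)))
    conditions = ([("WT", "hypo")] + [("WT", "hyper")] + [("NCOR1dID", "hypo")])
    counts = {}
    sheet_rows = []
    for genotype, condition in conditions:
        mu = base.copy()
        if condition == "hyper":
            mu = np.where(genes["status"] == "induced", mu * cfg.gene_fold, mu)
            mu = np.where(genes["status"] == "repressed", mu / cfg.gene_fold, mu)
        if genotype == "NCOR1dID":
            mu = np.where(genes["is_ncor_dependent"], mu * cfg.ncor_gene_fold, mu)
        for rep in range(1, cfg.n_rna_replicates + 1):
            s = float(np.exp(rng.uniform(np.log(1 - cfg.libsize_jitter),
                                         np.log(1 + cfg.libsize_jitter))))
            sample_id = f"RNA_{genotype}_{condition}_rep{rep}"
            counts[sample_id] = _nb_draw(rng, mu * s, cfg.dispersion)
            sheet_rows.append((sample_id, "RNA", condition, genotype, rep, s * 1e7))
    rna_counts = pd.DataFrame(counts, index=pd.Index(genes["gene_id"], name="gene_id"))
    rna_sheet = pd.DataFrame(sheet_rows, columns=["sample_id", "target", "condition",
                                                  "genotype", "replicate", "lib_size"])
    gene_truth = genes[["gene_id", "status", "driver_region", "driver_class",
                        "is_ncor_dependent"]].copy()
    gene_truth["is_induced"] = gene_truth["status"] == "induced"
    gene_table = genes[["gene_id", "chrom", "tss", "strand", "exonic_length"]].copy()
    return gene_table, rna_counts, rna_sheet, gene_truth


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full truth-labelled dataset; deterministic under the seed."""
    rng_place = cfg.rng(1)
    tads = _make_tads(cfg, rng_place)
    regions, loops = _place_regions(cfg, tads, rng_place)
    counts, sheet = _generate_counts(cfg, regions, cfg.rng(2))

    reg_ix = regions.set_index("region_id")
    mids = ((reg_ix["start"] + reg_ix["end"]) // 2)
    loop_anchors = pd.DataFrame({
        "chrom": reg_ix.loc[loops["region_a"], "chrom"].to_numpy(),
        "mid_a": mids.loc[loops["region_a"]].to_numpy(),
        "mid_b": mids.loc[loops["region_b"]].to_numpy(),
    }) if len(loops) else None
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chrom)}
    hic = generate_hic(cfg, chrom_sizes, loop_anchors, cfg.rng(3))
    loops = loops.copy()
    if len(loops):
        loops["distance"] = (mids.loc[loops["region_b"]].to_numpy() -
                             mids.loc[loops["region_a"]].to_numpy())

    peaks = _make_peaks(regions)
    genes, rna_counts, rna_sheet, gene_truth = _generate_genes(cfg, regions, cfg.rng(4))
    truth = regions[["region_id", "class", "cluster_id", "loop_id"]].copy()
    return SyntheticDataset(
        config=cfg,
        regions=regions[["chrom", "start", "end", "region_id"]].copy(),
        truth=truth, counts=counts, sample_sheet=sheet, peaks=peaks, hic=hic,
        tads=tads[["chrom", "start", "end", "tad_id", "active"]].copy(),
        loops=loops, genes=genes, rna_counts=rna_counts,
        rna_sample_sheet=rna_sheet, gene_truth=gene_truth)


def _make_peaks(regions: pd.DataFrame) -> dict:
    mids = (regions["start"] + regions["end"]) // 2
    trbs = regions["class"].isin(("type1A", "type1B"))
    tr = pd.DataFrame({
        "chrom": regions.loc[trbs, "chrom"],
        "start": mids[trbs] - 100,
        "end": mids[trbs] + 100,
        "name": ["trbs_" + r for r in regions.loc[trbs, "region_id"]],
    }).reset_index(drop=True)
    hd = regions["class"] == "type1A"
    hdac3 = pd.DataFrame({
        "chrom": regions.loc[hd, "chrom"],
        "start": mids[hd] - 250,
        "end": mids[hd] + 250,
        "name": ["hdac3_" + r for r in regions.loc[hd, "region_id"]],
    }).reset_index(drop=True)
    open_chrom = regions["class"] != "null"
    dhs = pd.DataFrame({
        "chrom": regions.loc[open_chrom, "chrom"],
        "start": mids[open_chrom] - 150,
        "end": mids[open_chrom] + 150,
        "name": ["dhs_" + r for r in regions.loc[open_chrom, "region_id"]],
    }).reset_index(drop=True)
    return {"TR": tr, "HDAC3": hdac3, "DHS": dhs}


def evaluate_recovery(predicted: pd.Series, truth: pd.Series) -> pd.DataFrame:
    """Per-class precision/recall of predicted labels against planted truth.

    Index universes must match; predicted labels outside the truth's
    label set raise.  Precision of an unpredicted class is NaN and
    flagged ``undefined_precision``.
    """
    predicted = pd.Series(predicted)
    truth = pd.Series(truth)
    if set(predicted.index) != set(truth.index):
        raise ValueError("label universes do not match")
    predicted = predicted.reindex(truth.index)
    labels = sorted(set(truth))
    unknown = set(predicted) - set(labels)
    if unknown:
        raise ValueError(f"unknown predicted labels: {sorted(unknown)}")
    rows = []
    for cls in labels:
        tp = int(((predicted == cls) & (truth == cls)).sum())
        fp = int(((predicted == cls) & (truth != cls)).sum())
        fn = int(((predicted != cls) & (truth == cls)).sum())
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        rows.append((cls, tp, fp, fn, precision, recall, tp + fp == 0))
    out = pd.DataFrame(rows, columns=["class", "tp", "fp", "fn", "precision",
                                      "recall", "undefined_precision"])
    macro = pd.DataFrame([{
        "class": "macro", "tp": out["tp"].sum(), "fp": out["fp"].sum(),
        "fn": out["fn"].sum(),
        "precision": out["precision"].mean(),
        "recall": out["recall"].mean(),
        "undefined_precision": bool(out["undefined_precision"].any()),
    }])
    return pd.concat([out, macro], ignore_index=True)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(ds.regions, out / "regions.bed", name_col="region_id")
    for name, df in ds.peaks.items():
        write_bed(df, out / f"peaks_{name}.bed", name_col="name")
    for target, table in ds.counts.items():
        table.to_csv(out / f"counts_{target}.tsv", sep="\t")
    ds.sample_sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    ds.hic.to_triplets().to_csv(out / "hic_triplets.tsv", sep="\t", index=False)
    pd.DataFrame(list(ds.chrom_sizes.items()), columns=["chrom", "size"]).to_csv(
        out / "chrom_sizes.tsv", sep="\t", index=False)
    write_bed(ds.tads, out / "tads.bed", name_col="tad_id")
    ds.loops.to_csv(out / "loops.tsv", sep="\t", index=False)
    ds.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    ds.rna_counts.to_csv(out / "rna_counts.tsv", sep="\t")
    ds.rna_sample_sheet.to_csv(out / "rna_sample_sheet.tsv", sep="\t", index=False)
    ds.truth.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    ds.gene_truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    cfg = asdict(ds.config)
    cfg["se_cluster_size"] = list(ds.config.se_cluster_size)
    cfg["loop_distance"] = list(ds.config.loop_distance)
    cfg["tad_length"] = list(ds.config.tad_length)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
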