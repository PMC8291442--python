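"""Synthetic multi-stage bisulfite methylomes with truth labels.

The generator emulates the statistical architectures seen across animal
methylomes so that every analysis stage in the package can be exercised —
and its estimates checked against known truth — without any sequencing data:

* **mosaic** architectures (sea-anemone-, honey-bee-, sea-urchin-like):
  contiguous runs of CpGs ("domains", geometric length) are either highly
  methylated or essentially unmethylated, giving the characteristic
  bimodal per-site level distribution and patchy browser tracks;
* **global** architectures (zebrafish-, mammal-like): nearly all CpGs are
  highly methylated except dense, unmethylated CpG-island (CGI) clusters;
* **gamete asymmetry**: a fraction of domains switch state between the
  sperm and oocyte truths, with a configurable hypo/hyper balance;
* **stage trajectories**: stable inheritance (invertebrates), maternal
  remodeling toward the paternal pattern by the mid-blastula transition
  (fish), or genome-wide demethylation at an intermediate stage followed
  by remethylation (mammals);
* an unmethylated **control contig** for conversion-rate estimation, and a
  designed gene annotation carrying a HOX-like cluster, non-HOX homeobox
  and signaling gene sets, and optional designed differentially methylated
  promoters (DMPs).

Counts are drawn per site as ``n_total ~ NegBin(coverage_mean,
coverage_dispersion)`` and ``n_meth ~ Binomial(n_total, m(1-g) + (1-m)f)``
where ``m`` is the true methylation level, ``f`` the bisulfite
non-conversion rate (unmethylated C read as methylated) and ``g`` the
over-conversion rate. Everything is bit-reproducible given the spec seed;
count noise for replicates is drawn from per-(stage, replicate) substreams
over a shared truth, so replicates differ only by sampling noise.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .model import AnnotationSet, MethylomeTable, add_tss, make_promoters

#: Architecture presets calibrated so the closed-form expected global ML
#: lands on the species-level values the analyses are checked against
#: (anemone ~0.11, bee ~0.01, deuterostome ~0.27, chicken ~0.42,
#: fish/mammal ~0.795).
PRESETS: dict[str, dict] = {
    "anemone_mosaic": dict(
        architecture="mosaic",
        p_dom=0.115,
        domain_ml=0.92,
        background_ml=0.005,
        cgi_fraction=0.0,
        stages=("sperm", "oocyte", "blastula", "gastrula"),
        trajectory="stable",
        gamete_asymmetry=0.0,
        asymmetry_hypo_fraction=0.5,
        nonconversion_rate=0.0074,
        hox_clusters=(("HOX", 12),),
    ),
    "bee_sparse": dict(
        architecture="mosaic",
        p_dom=0.008,
        domain_ml=0.85,
        background_ml=0.003,
        cgi_fraction=0.0,
        stages=("sperm", "oocyte", "blastoderm", "larva"),
        trajectory="stable",
        gamete_asymmetry=0.0,
        asymmetry_hypo_fraction=0.5,
        nonconversion_rate=0.0,
        hox_clusters=(("HOX", 12),),
    ),
    "deutero_mosaic": dict(
        architecture="mosaic",
        p_dom=0.29,
        domain_ml=0.92,
        background_ml=0.005,
        cgi_fraction=0.0,
        stages=("sperm", "oocyte", "blastula", "gastrula"),
        trajectory="stable",
        gamete_asymmetry=0.08,
        asymmetry_hypo_fraction=0.7,
        nonconversion_rate=0.0074,
        hox_clusters=(("HOX", 12),),
    ),
    "chicken_intermediate": dict(
        architecture="mosaic",
        p_dom=0.45,
        domain_ml=0.92,
        background_ml=0.01,
        cgi_fraction=0.0,
        stages=("sperm", "oocyte", "embryo"),
        trajectory="stable",
        gamete_asymmetry=0.05,
        asymmetry_hypo_fraction=0.6,
        nonconversion_rate=0.0,
        hox_clusters=(("HOXA", 11), ("HOXB", 10), ("HOXC", 9), ("HOXD", 9)),
    ),
    "fish_global": dict(
        architecture="global",
        p_dom=1.0,
        domain_ml=0.88,
        background_ml=0.88,
        cgi_fraction=0.10,
        cgi_ml=0.03,
        stages=("sperm", "oocyte", "mbt", "gastrula"),
        trajectory="maternal_to_paternal",
        gamete_asymmetry=0.15,
        asymmetry_hypo_fraction=0.8,
        nonconversion_rate=0.0074,
        hox_clusters=(("HOXA", 11), ("HOXB", 10), ("HOXC", 9), ("HOXD", 9)),
    ),
    "mammal_global": dict(
        architecture="global",
        p_dom=1.0,
        domain_ml=0.88,
        background_ml=0.88,
        cgi_fraction=0.10,
        cgi_ml=0.03,
        stages=("sperm", "oocyte", "icm", "embryo", "placenta"),
        trajectory="demethylation_remethylation",
        gamete_asymmetry=0.20,
        asymmetry_hypo_fraction=0.7,
        nonconversion_rate=0.0074,
        hox_clusters=(("HOXA", 11), ("HOXB", 10), ("HOXC", 9), ("HOXD", 9)),
    ),
}

_GAMETES = ("sperm", "oocyte")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one species-preset multi-stage methylome.

    Use :func:`make_spec` to start from a preset and override fields.
    """

    preset: str
    architecture: str = "mosaic"  # "mosaic" or "global"
    n_cpgs: int = 50_000
    genome_length: int = 5_000_000
    n_chroms: int = 2
    p_dom: float = 0.115  # fraction of CpGs inside methylated domains
    domain_ml: float = 0.92
    background_ml: float = 0.005
    cgi_fraction: float = 0.0  # fraction of CpGs in unmethylated CGI clusters
    cgi_ml: float = 0.03
    cgi_island_sites: int = 50  # CpGs per island
    cgi_spacing: int = 10  # bp between CpGs inside an island
    domain_run_mean: float = 10.0  # mean CpGs per landscape unit (geometric)
    stages: tuple[str, ...] = ("sperm", "oocyte", "blastula", "gastrula")
    trajectory: str = "stable"
    gamete_asymmetry: float = 0.0  # fraction of units switched in the oocyte
    asymmetry_hypo_fraction: float = 0.5  # of switched units, share going down
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    nonconversion_rate: float = 0.0074  # f: unmethylated C read as methylated
    overconversion_rate: float = 0.001  # g: methylated C read as unmethylated
    n_control_sites: int = 10_000
    # designed annotation
    n_genes: int = 100  # regular genes (DMP candidates)
    n_dmps: int = 0  # designed differentially methylated promoters
    dmp_high: float = 0.90
    dmp_low: float = 0.05
    n_homeobox: int = 20
    n_signaling: int = 20
    hox_clusters: tuple[tuple[str, int], ...] = (("HOX", 12),)
    gene_length: int = 1000
    promoter_upstream: int = 1000
    promoter_downstream: int = 500
    cgi_tss_fraction: float = 0.7  # global presets: genes with CGI promoters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}"
            )
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for name in (
            "p_dom",
            "domain_ml",
            "background_ml",
            "cgi_fraction",
            "cgi_ml",
            "gamete_asymmetry",
            "asymmetry_hypo_fraction",
            "nonconversion_rate",
            "overconversion_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.architecture not in ("mosaic", "global"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if len(self.stages) < 1:
            raise ValueError("at least one stage required")

    @property
    def n_hox(self) -> int:
        return sum(size for _, size in self.hox_clusters)


def make_spec(preset: str, **overrides) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a named preset plus overrides."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    if "stages" in params:
        params["stages"] = tuple(params["stages"])
    if "hox_clusters" in params:
        params["hox_clusters"] = tuple(
            (str(n), int(s)) for n, s in params["hox_clusters"]
        )
    return SyntheticSpec(preset=preset, **params)


def expected_global_ml(spec: SyntheticSpec, observed: bool = False) -> float:
    """Closed-form expected global CpG methylation level of the base
    (sperm) architecture.

    ``observed=True`` folds in the read-level error model:
    ``E[obs] = E[m] (1 - g - f) + f``. Designed gene-set overrides (a few
    percent of sites) are not included.
    """
    if spec.architecture == "mosaic":
        m = spec.p_dom * spec.domain_ml + (1.0 - spec.p_dom) * spec.background_ml
    else:
        m = (1.0 - spec.cgi_fraction) * spec.domain_ml + spec.cgi_fraction * spec.cgi_ml
    if observed:
        m = m * (1.0 - spec.overconversion_rate - spec.nonconversion_rate) + spec.nonconversion_rate
    return float(m)


# -- landscape ----------------------------------------------------------------


def _run_length_partition(n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """Partition ``n`` items into geometric runs; return a run-id array."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    lengths = []
    total = 0
    while total < n:
        draw = rng.geometric(1.0 / mean, size=max(16, int(n / mean) + 8))
        lengths.append(draw)
        total += int(draw.sum())
    lengths = np.concatenate(lengths)
    csum = np.cumsum(lengths)
    k = int(np.searchsorted(csum, n)) + 1
    lengths = lengths[:k]
    lengths[-1] -= int(csum[k - 1] - n)
    return np.repeat(np.arange(k), lengths)


def build_cpg_landscape(spec: SyntheticSpec) -> pd.DataFrame:
    """Place CpG sites on the synthetic genome.

    Background CpGs get geometric inter-CpG spacing; CGI clusters are dense
    runs (``cgi_spacing`` bp apart) covering ``cgi_fraction`` of CpGs, which
    reproduces the inverse density-methylation relationship once truth is
    assigned. Returns a frame with columns chrom, pos, is_cgi, unit_id;
    ``unit_id`` indexes contiguous landscape units (domain-scale runs for
    background CpGs, one unit per island) used for truth assignment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    chrom_len = spec.genome_length // spec.n_chroms
    frames = []
    unit_offset = 0
    for c in range(spec.n_chroms):
        n = spec.n_cpgs // spec.n_chroms + (1 if c < spec.n_cpgs % spec.n_chroms else 0)
        if n == 0:
            continue
        n_cgi = int(round(spec.cgi_fraction * n))
        n_bg = n - n_cgi
        n_islands = max(1, int(round(n_cgi / spec.cgi_island_sites))) if n_cgi else 0
        island_sizes = np.full(n_islands, n_cgi // max(n_islands, 1), dtype=np.int64)
        if n_islands:
            island_sizes[: n_cgi % n_islands] += 1
            island_sizes = island_sizes[island_sizes > 0]
            n_islands = len(island_sizes)
        cgi_span = int(n_cgi * spec.cgi_spacing)
        if n_bg > 0:
            s_bg = (chrom_len - cgi_span) / n_bg
            if s_bg < 4:
                raise ValueError(
                    f"infeasible CpG density: {n} CpGs do not fit in {chrom_len} bp"
                )
            gaps = rng.geometric(1.0 / max(s_bg - 1.0, 1.0), size=n_bg) + 1
        else:
            gaps = np.zeros(0, dtype=np.int64)

        is_cgi_parts, gap_parts = [], []
        if n_islands:
            insert_at = np.sort(rng.choice(n_bg + 1, size=n_islands, replace=False))
        else:
            insert_at = np.zeros(0, dtype=np.int64)
        prev = 0
        for k, cut in enumerate(insert_at):
            gap_parts.append(gaps[prev:cut])
            is_cgi_parts.append(np.zeros(cut - prev, dtype=bool))
            size = int(island_sizes[k])
            g = np.full(size, spec.cgi_spacing, dtype=np.int64)
            g[0] = int(rng.geometric(1.0 / max(s_bg - 1.0, 1.0)) + 1) if n_bg else spec.cgi_spacing
            gap_parts.append(g)
            is_cgi_parts.append(np.ones(size, dtype=bool))
            prev = cut
        gap_parts.append(gaps[prev:])
        is_cgi_parts.append(np.zeros(n_bg - prev, dtype=bool))
        gap_all = np.concatenate(gap_parts)
        is_cgi = np.concatenate(is_cgi_parts)
        pos = np.cumsum(gap_all) - 1

        # landscape units: background CpGs partitioned into geometric runs,
        # each island its own unit
        unit_id = np.empty(n, dtype=np.int64)
        bg_units = _run_length_partition(int((~is_cgi).sum()), spec.domain_run_mean, rng)
        n_bg_units = int(bg_units.max()) + 1 if len(bg_units) else 0
        unit_id[~is_cgi] = bg_units
        if n_islands:
            island_ids = np.repeat(np.arange(n_islands) + n_bg_units, island_sizes)
            unit_id[is_cgi] = island_ids
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c + 1}",
                    "pos": pos,
                    "is_cgi": is_cgi,
                    "unit_id": unit_id + unit_offset,
                }
            )
        )
        unit_offset += int(unit_id.max()) + 1
    return pd.concat(frames, ignore_index=True)


# -- truth --------------------------------------------------------------------


@dataclass
class TruthSet:
    """Ground truth for one synthetic dataset."""

    spec: SyntheticSpec
    landscape: pd.DataFrame  # chrom, pos, is_cgi, unit_id
    stage_ml: dict[str, np.ndarray] = field(default_factory=dict)
    annotation: AnnotationSet | None = None
    designed_dmps: pd.DataFrame | None = None  # gene_id, direction, ml_sperm, ml_oocyte
    control: pd.DataFrame | None = None  # chrom, pos (all truly unmethylated)

    def site_state(self, stage: str, threshold: float = 0.5) -> np.ndarray:
        """Boolean methylated/unmethylated truth label per CpG."""
        return self.stage_ml[stage] >= threshold

    def domain_intervals(self, stage: str, threshold: float = 0.5) -> pd.DataFrame:
        """Truth domains: maximal runs of constant state per chromosome."""
        state = self.site_state(stage, threshold)
        rows = []
        offset = 0
        for chrom, sub in self.landscape.groupby("chrom", sort=False):
            s = state[offset : offset + len(sub)]
            pos = sub["pos"].to_numpy()
            breaks = np.flatnonzero(np.diff(s.astype(np.int8))) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(s)]])
            for a, b in zip(starts, ends):
                rows.append(
                    (
                        chrom,
                        int(pos[a]),
                        int(pos[b - 1]) + 1,
                        "methylated" if s[a] else "unmethylated",
                        int(b - a),
                    )
                )
            offset += len(sub)
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "n_cpgs"])

    def promoter_truth_ml(self, stage: str) -> pd.Series:
        """Mean truth ML over each gene's promoter window."""
        ml = self.stage_ml[stage]
        out = {}
        for row in self.annotation.promoters.itertuples():
            idx = _site_slice(self.landscape, row.chrom, row.start, row.end)
            out[row.gene_id] = float(ml[idx].mean()) if len(idx) else np.nan
        return pd.Series(out, name=stage)


def _site_slice(landscape: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Global row indices of landscape CpGs inside [start, end) on chrom."""
    mask = landscape["chrom"].to_numpy() == chrom
    idx = np.flatnonzero(mask)
    pos = landscape["pos"].to_numpy()[idx]
    lo, hi = np.searchsorted(pos, [start, end])
    return idx[lo:hi]


class _ChromIndex:
    """Cached per-chromosome searchsorted index over the landscape."""

    def __init__(self, landscape: pd.DataFrame):
        self.ranges: dict[str, tuple[int, np.ndarray]] = {}
        offset = 0
        for chrom, sub in landscape.groupby("chrom", sort=False):
            self.ranges[str(chrom)] = (offset, sub["pos"].to_numpy())
            offset += len(sub)

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self.ranges:
            return np.zeros(0, dtype=np.int64)
        offset, pos = self.ranges[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        return np.arange(offset + lo, offset + hi)

    def nearest(self, chrom: str, target: int, within: np.ndarray | None = None) -> int:
        """Global index of the CpG nearest to ``target`` (optionally among
        a subset of global indices)."""
        offset, pos = self.ranges[chrom]
        if within is not None and len(within):
            cand = within
            cpos = pos[cand - offset]
        else:
            cand = np.arange(offset, offset + len(pos))
            cpos = pos
        return int(cand[np.argmin(np.abs(cpos - target))])


def _design_genes(spec: SyntheticSpec, landscape: pd.DataFrame, rng: np.random.Generator):
    """Lay out HOX cluster(s), homeobox, signaling and regular genes."""
    index = _ChromIndex(landscape)
    chrom_len = spec.genome_length // spec.n_chroms
    chroms = [f"chr{c + 1}" for c in range(spec.n_chroms)]

    gene_rows = []  # (gene_id, category, cluster)
    for cname, size in spec.hox_clusters:
        for i in range(size):
            gene_rows.append((f"{cname}{i + 1}", "hox", cname))
    for i in range(spec.n_homeobox):
        gene_rows.append((f"HB{i + 1}", "homeobox", "-"))
    for i in range(spec.n_signaling):
        gene_rows.append((f"SIG{i + 1}", "signaling", "-"))
    for i in range(spec.n_genes):
        gene_rows.append((f"G{i + 1:04d}", "regular", "-"))
    total = len(gene_rows)

    # one slot per gene, tiled across chromosomes in order
    per_chrom = [total // spec.n_chroms] * spec.n_chroms
    for i in range(total % spec.n_chroms):
        per_chrom[i] += 1
    slots = []
    for c, n_slots in enumerate(per_chrom):
        width = chrom_len // max(n_slots, 1)
        for s in range(n_slots):
            slots.append((chroms[c], s * width + width // 2))

    pad = spec.promoter_upstream + spec.gene_length
    rows = []
    is_cgi = landscape["is_cgi"].to_numpy()
    for (gene_id, category, cluster), (chrom, center) in zip(gene_rows, slots):
        center = int(np.clip(center, pad, chrom_len - pad))
        offset, pos = index.ranges[chrom]
        lo, hi = np.searchsorted(pos, [center - 20_000, center + 20_000])
        window = np.arange(offset + lo, offset + hi)
        prefer_cgi = spec.architecture == "global" and (
            category == "hox" or rng.random() < spec.cgi_tss_fraction
        )
        if prefer_cgi and is_cgi[window].any():
            window = window[is_cgi[window]]
        tss = landscape["pos"].to_numpy()[index.nearest(chrom, center, window)]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, min(tss + spec.gene_length, chrom_len)
        else:
            start, end = max(tss - spec.gene_length + 1, 0), tss + 1
        rows.append((gene_id, chrom, int(start), int(end), strand, category, cluster))
    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "category", "cluster"]
    )
    return add_tss(genes), index


def assign_truth(spec: SyntheticSpec) -> TruthSet:
    """Assign per-CpG true methylation levels for every stage.

    Mosaic presets put a quota of landscape units summing to ``p_dom`` of
    CpGs at ``domain_ml`` and the rest at ``background_ml``; global presets
    put every background CpG at ``domain_ml`` and CGI CpGs at ``cgi_ml``.
    The oocyte truth switches the state of ``gamete_asymmetry`` of the
    units; embryonic stages follow the preset trajectory. The designed gene
    annotation overlays a HOX-like cluster, homeobox/signaling sets, and
    (optionally) designed DMPs on the promoter truth.
    """
    landscape = build_cpg_landscape(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = len(landscape)
    unit_id = landscape["unit_id"].to_numpy()
    is_cgi = landscape["is_cgi"].to_numpy()
    n_units = int(unit_id.max()) + 1
    unit_sizes = np.bincount(unit_id, minlength=n_units)

    def units_by_site_quota(pool: np.ndarray, target_sites: float) -> np.ndarray:
        """Random units from ``pool`` whose sizes accumulate to ~target_sites."""
        if target_sites <= 0 or len(pool) == 0:
            return np.zeros(0, dtype=np.int64)
        perm = rng.permutation(pool)
        csum = np.cumsum(unit_sizes[perm])
        k = min(int(np.searchsorted(csum, target_sites)) + 1, len(perm))
        return perm[:k]

    # base (sperm) architecture
    if spec.architecture == "mosaic":
        meth_units = np.zeros(n_units, dtype=bool)
        meth_units[units_by_site_quota(np.arange(n_units), spec.p_dom * n)] = True
        unit_ml = np.where(meth_units, spec.domain_ml, spec.background_ml)
        low_value = spec.background_ml
    else:
        cgi_units = np.zeros(n_units, dtype=bool)
        cgi_units[np.unique(unit_id[is_cgi])] = True
        meth_units = ~cgi_units
        unit_ml = np.where(meth_units, spec.domain_ml, spec.cgi_ml)
        low_value = spec.cgi_ml
    sperm = unit_ml[unit_id].astype(float)

    # oocyte: switch the state of units covering ``gamete_asymmetry`` of
    # CpGs, split between hypo- and hyper-methylating switches
    oocyte_unit_ml = unit_ml.copy()
    if spec.gamete_asymmetry > 0:
        down_sites = spec.gamete_asymmetry * spec.asymmetry_hypo_fraction * n
        up_sites = spec.gamete_asymmetry * (1.0 - spec.asymmetry_hypo_fraction) * n
        down_ids = units_by_site_quota(np.flatnonzero(meth_units), down_sites)
        up_ids = units_by_site_quota(np.flatnonzero(~meth_units), up_sites)
        oocyte_unit_ml[down_ids] = low_value
        oocyte_unit_ml[up_ids] = spec.domain_ml
    oocyte = oocyte_unit_ml[unit_id].astype(float)

    # designed annotation
    genes, index = _design_genes(spec, landscape, rng)
    annotation = AnnotationSet(
        genes=genes[["gene_id", "chrom", "start", "end", "strand", "tss"]],
        gene_sets={
            "HOX": genes.loc[genes["category"] == "hox", ["gene_id", "cluster"]].reset_index(drop=True),
            "homeobox": genes.loc[genes["category"] == "homeobox", ["gene_id", "cluster"]].reset_index(drop=True),
            "signaling": genes.loc[genes["category"] == "signaling", ["gene_id", "cluster"]].reset_index(drop=True),
        },
    )
    annotation = make_promoters(annotation, spec.promoter_upstream, spec.promoter_downstream)
    annotation.validate()
    promoters = annotation.promoters.set_index("gene_id")

    def gene_span_idx(gene_id: str) -> np.ndarray:
        g = genes.set_index("gene_id").loc[gene_id]
        p = promoters.loc[gene_id]
        lo = min(int(g["start"]), int(p["start"]))
        hi = max(int(g["end"]), int(p["end"]))
        return index.slice(str(g["chrom"]), lo, hi)

    def promoter_idx(gene_id: str) -> np.ndarray:
        p = promoters.loc[gene_id]
        return index.slice(str(p["chrom"]), int(p["start"]), int(p["end"]))

    # homeobox: per-gene constant level (mostly unmethylated, a minority
    # medium/high), identical in both gametes, no dynamics
    hb_ids = genes.loc[genes["category"] == "homeobox", "gene_id"].tolist()
    hb_levels = rng.choice([0.02, 0.5, 0.9], size=len(hb_ids), p=[0.7, 0.15, 0.15])
    for gid, level in zip(hb_ids, hb_levels):
        idx = gene_span_idx(gid)
        sperm[idx] = level
        oocyte[idx] = level
    # signaling: unmethylated promoters and bodies in both gametes
    for gid in genes.loc[genes["category"] == "signaling", "gene_id"]:
        idx = gene_span_idx(gid)
        sperm[idx] = 0.01
        oocyte[idx] = 0.01

    # promoters carry no accidental sperm/oocyte differences ...
    for gid in genes["gene_id"]:
        idx = promoter_idx(gid)
        oocyte[idx] = sperm[idx]

    # ... except designed DMPs
    regular_ids = genes.loc[genes["category"] == "regular", "gene_id"].to_numpy()
    if spec.n_dmps > len(regular_ids):
        raise ValueError("n_dmps exceeds the number of regular genes")
    dmp_ids = np.sort(rng.choice(regular_ids, size=spec.n_dmps, replace=False))
    dmp_rows = []
    for i, gid in enumerate(dmp_ids):
        idx = promoter_idx(gid)
        if i % 2 == 0:
            sperm[idx], oocyte[idx] = spec.dmp_high, spec.dmp_low
            dmp_rows.append((gid, "hyper_in_sperm", spec.dmp_high, spec.dmp_low))
        else:
            sperm[idx], oocyte[idx] = spec.dmp_low, spec.dmp_high
            dmp_rows.append((gid, "hypo_in_sperm", spec.dmp_low, spec.dmp_high))
    designed_dmps = pd.DataFrame(
        dmp_rows, columns=["gene_id", "direction", "ml_sperm", "ml_oocyte"]
    )

    # HOX cluster truth per gamete
    hox_ids = genes.loc[genes["category"] == "hox", "gene_id"].tolist()
    if spec.trajectory == "maternal_to_paternal":
        hox_sperm = np.full(len(hox_ids), 0.03)
        hox_oocyte = np.full(len(hox_ids), 0.85)
    elif spec.trajectory == "demethylation_remethylation":
        hox_sperm = rng.uniform(0.2, 0.8, size=len(hox_ids))
        hox_oocyte = hox_sperm.copy()
    else:
        hox_sperm = np.full(len(hox_ids), 0.01)
        hox_oocyte = hox_sperm.copy()
    for gid, ms, mo in zip(hox_ids, hox_sperm, hox_oocyte):
        idx = gene_span_idx(gid)
        sperm[idx] = ms
        oocyte[idx] = mo

    # stage trajectories
    stage_ml: dict[str, np.ndarray] = {}
    gamete_mean = 0.5 * (sperm + oocyte)
    post_gamete_seen = 0
    for stage in spec.stages:
        if stage == "sperm":
            stage_ml[stage] = sperm
            continue
        if stage == "oocyte":
            stage_ml[stage] = oocyte
            continue
        post_gamete_seen += 1
        if spec.trajectory == "stable":
            stage_ml[stage] = sperm.copy()
        elif spec.trajectory == "maternal_to_paternal":
            stage_ml[stage] = sperm.copy()  # maternal pattern remodeled to paternal
        elif spec.trajectory == "demethylation_remethylation":
            if post_gamete_seen == 1:  # demethylated intermediate (ICM-like)
                stage_ml[stage] = 0.3 * gamete_mean
            else:
                stage_ml[stage] = gamete_mean.copy()
        else:
            raise ValueError(f"unknown trajectory {spec.trajectory!r}")

    # stage-specific gene-set overrides (mammal-like presets)
    if spec.trajectory == "demethylation_remethylation":
        hox_placenta = rng.uniform(0.15, 0.7, size=len(hox_ids))
        for stage in spec.stages:
            if stage in _GAMETES:
                continue
            arr = stage_ml[stage]
            for j, gid in enumerate(hox_ids):
                idx = gene_span_idx(gid)
                arr[idx] = hox_placenta[j] if stage == "placenta" else 0.03
            if stage == "placenta":
                for gid in hb_ids:
                    arr[promoter_idx(gid)] = 0.45

    for stage, arr in stage_ml.items():
        stage_ml[stage] = np.clip(arr, 0.0, 1.0)

    control = pd.DataFrame(
        {"chrom": "chrL", "pos": np.arange(spec.n_control_sites) * 10 + 5}
    )
    return TruthSet(
        spec=spec,
        landscape=landscape,
        stage_ml=stage_ml,
        annotation=annotation,
        designed_dmps=designed_dmps,
        control=control,
    )


# -- count simulation ---------------------------------------------------------


def _draw_counts(
    m: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    r = spec.coverage_dispersion
    p = r / (r + spec.coverage_mean)
    n_total = rng.negative_binomial(r, p, size=len(m))
    prob = m * (1.0 - spec.overconversion_rate) + (1.0 - m) * spec.nonconversion_rate
    n_meth = rng.binomial(n_total, prob)
    return n_meth, n_total


def simulate_counts(
    truth: TruthSet, spec: SyntheticSpec, stage: str, replicate: int = 1
) -> MethylomeTable:
    """Simulate a per-CpG count table for one stage/replicate.

    Replicates share the truth and differ only in the count noise stream.
    """
    if stage not in truth.stage_ml:
        raise ValueError(f"unknown stage {stage!r}; have {list(truth.stage_ml)}")
    stage_idx = list(truth.stage_ml).index(stage)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 2, stage_idx, replicate])
    )
    n_meth, n_total = _draw_counts(truth.stage_ml[stage], spec, rng)
    df = pd.DataFrame(
        {
            "chrom": truth.landscape["chrom"],
            "pos": truth.landscape["pos"],
            "strand": "+",
            "context": "CG",
            "n_meth": n_meth,
            "n_total": n_total,
        }
    )
    return MethylomeTable.new(
        df,
        sample_id=f"{spec.preset}_{stage}_rep{replicate}",
        species=spec.preset,
        stage=stage,
    )


def simulate_control(
    spec: SyntheticSpec, replicate: int = 1, n_sites: int | None = None
) -> MethylomeTable:
    """Simulate the unmethylated control contig (true ML 0 at every site)."""
    n = spec.n_control_sites if n_sites is None else n_sites
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, replicate]))
    m = np.zeros(n)
    n_meth, n_total = _draw_counts(m, spec, rng)
    df = pd.DataFrame(
        {
            "chrom": "chrL",
            "pos": np.arange(n) * 10 + 5,
            "strand": "+",
            "context": "CHH",
            "n_meth": n_meth,
            "n_total": n_total,
        }
    )
    return MethylomeTable.new(
        df,
        sample_id=f"{spec.preset}_control_rep{replicate}",
        species=spec.preset,
        stage="control",
    )


def simulate_expression(
    truth: TruthSet, stages: list[str] | None = None, noise_sd: float = 0.5
) -> pd.DataFrame:
    """Simulate an FPKM expression table anti-correlated with promoter
    methylation: ``log2(FPKM + 1) = max(0, 5.5 - 6 * promoter_ML + noise)``.
    """
    spec = truth.spec
    stages = list(truth.stage_ml) if stages is None else stages
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 4]))
    rows = []
    for stage in stages:
        prom_ml = truth.promoter_truth_ml(stage)
        noise = rng.normal(0.0, noise_sd, size=len(prom_ml))
        log2 = np.maximum(0.0, 5.5 - 6.0 * prom_ml.to_numpy() + noise)
        fpkm = np.exp2(log2) - 1.0
        for gid, v in zip(prom_ml.index, fpkm):
            rows.append((gid, stage, float(max(v, 0.0))))
    return pd.DataFrame(rows, columns=["gene_id", "sample", "fpkm"])


@dataclass
class SimulatedDataset:
    spec: SyntheticSpec
    truth: TruthSet
    tables: dict[str, MethylomeTable]
    control: MethylomeTable
    expression: pd.DataFrame | None = None


def simulate_dataset(
    spec: SyntheticSpec, with_expression: bool = False
) -> SimulatedDataset:
    """Generate truth plus one count table per stage and the control contig."""
    truth = assign_truth(spec)
    tables = {s: simulate_counts(truth, spec, s) for s in spec.stages}
    control = simulate_control(spec)
    expression = simulate_expression(truth) if with_expression else None
    return SimulatedDataset(spec, truth, tables, control, expression)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write a simulated dataset as plain-text files readable by methreprog."""
    from pathlib import Path

    import yaml

    from . import io as mio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage, table in dataset.tables.items():
        mio.write_cytosine_report(table, out / f"{stage}.CX_report.txt")
    mio.write_cytosine_report(dataset.control, out / "control.CX_report.txt")
    mio.write_bed6_genes(dataset.truth.annotation.genes, out / "genes.bed")
    mio.write_gene_sets(dataset.truth.annotation.gene_sets, out / "gene_sets.tsv")
    truth_df = dataset.truth.landscape.copy()
    for stage, arr in dataset.truth.stage_ml.items():
        truth_df[f"ml_{stage}"] = arr
    mio.write_tsv(truth_df, out / "truth_sites.tsv")
    if dataset.truth.designed_dmps is not None:
        mio.write_tsv(dataset.truth.designed_dmps, out / "truth_dmps.tsv", coord_comment=False)
    if dataset.expression is not None:
        dataset.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    spec_dict = dataclasses.asdict(dataset.spec)
    spec_dict["stages"] = list(spec_dict["stages"])
    spec_dict["hox_clusters"] = [list(x) for x in spec_dict["hox_clusters"]]
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=True)
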