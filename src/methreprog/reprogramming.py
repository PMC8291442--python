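"""Between-sample and across-stage comparisons.

Sperm-oocyte divergence, differentially methylated promoter (DMP) calling
by Fisher's exact test on pooled promoter counts with Benjamini-Hochberg
correction, qualitative stage-dynamics classification, and the
genome-wide-demethylation flag.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import MethylomeTable, chrom_site_arrays
from .stats import global_ml

#: upper bounds on the maximum pairwise global-ML difference for the
#: none / minor / moderate classes; anything larger is "dramatic".
DYNAMICS_THRESHOLDS = (0.02, 0.05, 0.15)
DMP_COLUMNS = [
    "gene_id", "ml_a", "ml_b", "delta", "n_cpgs_used", "p", "q", "status",
]


@dataclass
class ReprogrammingSummary:
    stages: list[str]
    stage_ml: dict[str, float]
    max_delta: float
    divergence: float | None  # |sperm - oocyte| global ML, if both present
    dynamics_class: str | None  # none / minor / moderate / dramatic
    demethylation_flag: bool
    thresholds: tuple[float, float, float] = DYNAMICS_THRESHOLDS


def sperm_oocyte_divergence(
    table_s: MethylomeTable,
    table_o: MethylomeTable,
    bin_bp: int = 1000,
    min_cov: int = 5,
    context: str | None = "CG",
) -> tuple[float, float]:
    """Two views of gamete methylome divergence.

    Returns ``(global_delta, mean_abs_bin_delta)``: the difference of
    global (site-mean) methylation levels, and the mean absolute
    difference of binned methylation over bins covered in both gametes.
    """
    gs = global_ml(table_s, context=context, min_cov=min_cov).site_mean
    go = global_ml(table_o, context=context, min_cov=min_cov).site_mean

    def bin_means(t):
        df = t.df
        if context is not None:
            df = df[df["context"] == context]
        df = df[df["n_total"] >= min_cov].copy()
        df["ml"] = df["n_meth"] / df["n_total"]
        df["bin"] = df["pos"] // bin_bp
        return df.groupby(["chrom", "bin"])["ml"].mean()

    a = bin_means(table_s)
    b = bin_means(table_o)
    joined = pd.concat([a.rename("s"), b.rename("o")], axis=1, join="inner")
    if len(joined) == 0:
        raise ValueError("no bins covered in both samples")
    mean_abs = float((joined["s"] - joined["o"]).abs().mean())
    return float(gs - go), mean_abs


def call_dmps(
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    promoters: pd.DataFrame,
    min_cov: int = 5,
    min_cpgs: int = 3,
    delta_min: float = 0.2,
    alpha: float = 0.05,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Call differentially methylated promoters between two samples.

    Per promoter, methylated/unmethylated read counts are pooled across
    its covered CpGs (coverage >= ``min_cov``; at least ``min_cpgs`` such
    CpGs required in *both* samples) into a 2x2 table tested with a
    two-sided Fisher exact test; p-values are Benjamini-Hochberg adjusted
    across tested promoters. A promoter is a DMP when ``q <= alpha`` and
    the pooled-level difference ``|ml_a - ml_b| >= delta_min``; the status
    is ``hyper_in_a`` or ``hypo_in_a`` by the sign of the difference.
    """
    def pooled(table):
        df = table.df
        if context is not None:
            df = df[df["context"] == context]
        df = df[df["n_total"] >= min_cov].copy()
        df["ml"] = df["n_meth"] / df["n_total"]
        out = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            out[str(chrom)] = (
                sub["pos"].to_numpy(),
                sub["n_meth"].to_numpy(),
                sub["n_total"].to_numpy(),
            )
        return out

    sites_a = pooled(table_a)
    sites_b = pooled(table_b)
    rows = []
    for prom in promoters.itertuples():
        stats = []
        for sites in (sites_a, sites_b):
            if prom.chrom not in sites:
                stats.append(None)
                continue
            pos, nm, nt = sites[prom.chrom]
            lo, hi = np.searchsorted(pos, [prom.start, prom.end])
            if hi - lo < min_cpgs:
                stats.append(None)
            else:
                stats.append((int(nm[lo:hi].sum()), int(nt[lo:hi].sum()), hi - lo))
        if stats[0] is None or stats[1] is None:
            continue
        (ma, ta, na), (mb, tb, nb) = stats
        ml_a, ml_b = ma / ta, mb / tb
        _, p = sps.fisher_exact([[ma, ta - ma], [mb, tb - mb]], alternative="two-sided")
        rows.append((prom.gene_id, ml_a, ml_b, ml_a - ml_b, int(min(na, nb)), p))
    if not rows:
        raise ValueError(
            f"no promoter testable with >= {min_cpgs} CpGs at coverage >= "
            f"{min_cov} in both samples"
        )
    out = pd.DataFrame(
        rows, columns=["gene_id", "ml_a", "ml_b", "delta", "n_cpgs_used", "p"]
    )
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    significant = (out["q"] <= alpha) & (out["delta"].abs() >= delta_min)
    out["status"] = np.where(
        significant & (out["delta"] > 0),
        "hyper_in_a",
        np.where(significant & (out["delta"] < 0), "hypo_in_a", "ns"),
    )
    return out[DMP_COLUMNS]


def classify_dynamics(
    stage_mls: Sequence[tuple[str, float]] | Mapping[str, float],
    thresholds: tuple[float, float, float] = DYNAMICS_THRESHOLDS,
    demethylation_factor: float = 0.5,
) -> ReprogrammingSummary:
    """Classify across-stage methylome dynamics.

    ``D`` is the maximum pairwise absolute difference of global
    methylation across the ordered stages; the class is none / minor /
    moderate / dramatic by the documented thresholds. The genome-wide
    demethylation flag is set when some non-gamete (embryo) stage falls
    below ``demethylation_factor`` times the gamete mean. Stages named
    "sperm"/"oocyte" (case-insensitive) are the gametes.
    """
    items = list(stage_mls.items()) if isinstance(stage_mls, Mapping) else list(stage_mls)
    stages = [s for s, _ in items]
    mls = {s: float(v) for s, v in items}
    if len(items) < 2:
        warnings.warn("fewer than 2 stages; dynamics class undefined")
        return ReprogrammingSummary(
            stages=stages,
            stage_ml=mls,
            max_delta=0.0,
            divergence=None,
            dynamics_class=None,
            demethylation_flag=False,
            thresholds=thresholds,
        )
    values = np.array([v for _, v in items])
    max_delta = float(values.max() - values.min())
    t_none, t_minor, t_moderate = thresholds
    if max_delta < t_none:
        cls = "none"
    elif max_delta < t_minor:
        cls = "minor"
    elif max_delta < t_moderate:
        cls = "moderate"
    else:
        cls = "dramatic"
    gametes = [v for s, v in items if s.lower() in ("sperm", "oocyte")]
    embryo = [v for s, v in items if s.lower() not in ("sperm", "oocyte")]
    divergence = None
    demeth = False
    if len(gametes) == 2:
        divergence = float(abs(gametes[0] - gametes[1]))
        gmean = float(np.mean(gametes))
        demeth = any(v < demethylation_factor * gmean for v in embryo)
    return ReprogrammingSummary(
        stages=stages,
        stage_ml=mls,
        max_delta=max_delta,
        divergence=divergence,
        dynamics_class=cls,
        demethylation_flag=demeth,
        thresholds=thresholds,
    )


def dmp_heatmap_matrix(
    samples: Mapping[str, MethylomeTable],
    dmps: pd.DataFrame,
    promoters: pd.DataFrame,
    min_cov: int = 5,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Promoter x sample matrix of pooled methylation levels for DMPs.

    Rows are ordered by descending ``delta``; entries are pooled
    ``sum n_meth / sum n_total`` over each promoter's covered CpGs, NaN
    where a sample has no coverage there.
    """
    called = dmps[dmps["status"] != "ns"] if "status" in dmps.columns else dmps
    if len(called) == 0:
        raise ValueError("no DMPs to tabulate")
    ordered = called.sort_values("delta", ascending=False)["gene_id"].tolist()
    prom = promoters.set_index("gene_id").loc[ordered]
    matrix = pd.DataFrame(index=ordered, columns=list(samples), dtype=float)
    for name, table in samples.items():
        df = table.df
        if context is not None:
            df = df[df["context"] == context]
        df = df[df["n_total"] >= min_cov]
        per_chrom = {
            str(chrom): (
                sub.sort_values("pos")["pos"].to_numpy(),
                sub.sort_values("pos")["n_meth"].to_numpy(),
                sub.sort_values("pos")["n_total"].to_numpy(),
            )
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        for gid, row in prom.iterrows():
            if row["chrom"] not in per_chrom:
                continue
            pos, nm, nt = per_chrom[row["chrom"]]
            lo, hi = np.searchsorted(pos, [row["start"], row["end"]])
            total = nt[lo:hi].sum()
            if total > 0:
                matrix.loc[gid, name] = nm[lo:hi].sum() / total
    matrix.index.name = "gene_id"
    return matrix
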