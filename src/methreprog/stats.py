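"""Global and distributional methylation statistics.

Covers the sample-level summaries used for cross-species comparison:
global methylation level, bisulfite conversion rate from an unmethylated
control, non-conversion-corrected non-CpG methylation, the bimodal
per-site level distribution, the CpG-density/methylation relationship,
and between-replicate correlation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import MethylomeTable


@dataclass
class GlobalSummary:
    sample_id: str
    context: str
    n_sites_used: int
    global_ml: float
    weighting: str
    site_mean: float
    count_weighted: float


@dataclass
class DistributionSummary:
    """Histogram of per-site methylation levels over bins of width 0.1.

    ``bimodality = frac_low + frac_high`` is the fraction of sites that are
    essentially unmethylated (ML <= 0.2) or fully methylated (ML >= 0.8);
    values near 1 indicate the bimodal all-or-nothing regime.
    """

    sample_id: str
    n_sites: int
    bin_edges: np.ndarray
    frequencies: np.ndarray
    frac_low: float
    frac_high: float

    @property
    def bimodality(self) -> float:
        return self.frac_low + self.frac_high


def _covered(table: MethylomeTable, context, min_cov: int) -> pd.DataFrame:
    df = table.df
    if context is not None:
        if isinstance(context, str):
            context = (context,)
        df = df[df["context"].isin(context)]
    df = df[df["n_total"] >= min_cov].copy()
    df["ml"] = df["n_meth"] / df["n_total"]
    return df


def global_ml(
    table: MethylomeTable,
    context: str | tuple | None = "CG",
    min_cov: int = 5,
    weighting: str = "site_mean",
) -> GlobalSummary:
    """Global methylation level of a sample.

    ``site_mean`` (default) is the arithmetic mean of per-site levels over
    retained sites; ``count_weighted`` is pooled ``sum n_meth / sum n_total``.
    Both are always reported on the summary.
    """
    if weighting not in ("site_mean", "count_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = _covered(table, context, min_cov)
    if len(df) == 0:
        raise ValueError(
            f"no sites retained for context={context!r} at min_cov={min_cov}"
        )
    site_mean = float(df["ml"].mean())
    count_weighted = float(df["n_meth"].sum() / df["n_total"].sum())
    return GlobalSummary(
        sample_id=table.sample_id,
        context=",".join(context) if isinstance(context, tuple) else str(context),
        n_sites_used=int(len(df)),
        global_ml=site_mean if weighting == "site_mean" else count_weighted,
        weighting=weighting,
        site_mean=site_mean,
        count_weighted=count_weighted,
    )


def conversion_rate(control: MethylomeTable) -> float:
    """Bisulfite conversion rate from a truly-unmethylated control.

    Pooled over all control sites: ``sum(n_total - n_meth) / sum(n_total)``.
    The complement is the non-conversion rate, i.e. the pooled apparent
    methylation of the control.
    """
    total = int(control.df["n_total"].sum())
    if total == 0:
        raise ValueError("control table has zero total coverage")
    meth = int(control.df["n_meth"].sum())
    return float((total - meth) / total)


def corrected_noncpg_ml(
    table: MethylomeTable, conv_rate: float, min_cov: int = 5
) -> float:
    """Non-CpG methylation corrected for bisulfite non-conversion.

    Subtracts the non-conversion rate ``1 - conv_rate`` from the raw mean
    CHG/CHH methylation level and floors at zero.
    """
    if not 0.0 <= conv_rate <= 1.0:
        raise ValueError("conv_rate must be in [0, 1]")
    df = _covered(table, ("CHG", "CHH"), min_cov)
    if len(df) == 0:
        raise ValueError("no covered CHG/CHH sites")
    raw = float(df["ml"].mean())
    return max(0.0, raw - (1.0 - conv_rate))


def ml_distribution(
    table: MethylomeTable, min_cov: int = 5, context: str | None = "CG"
) -> DistributionSummary:
    """Normalized histogram of per-site levels plus the bimodality index."""
    df = _covered(table, context, min_cov)
    if len(df) == 0:
        raise ValueError(f"no sites retained at min_cov={min_cov}")
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(df["ml"], bins=edges)
    ml = df["ml"].to_numpy()
    return DistributionSummary(
        sample_id=table.sample_id,
        n_sites=int(len(df)),
        bin_edges=edges,
        frequencies=counts / len(df),
        frac_low=float((ml <= 0.2).mean()),
        frac_high=float((ml >= 0.8).mean()),
    )


def density_ml_relationship(
    table: MethylomeTable,
    window_bp: int = 1000,
    min_cov: int = 5,
    min_cpgs: int = 3,
    context: str | None = "CG",
) -> tuple[pd.DataFrame, float]:
    """Per-window CpG density vs mean methylation, with Pearson r.

    The genome is tiled in non-overlapping ``window_bp`` windows per
    chromosome; windows with at least ``min_cpgs`` covered CpGs are scored.
    Returns ``(windows, r)`` where windows has columns chrom, window_start,
    cpg_density (covered CpGs per bp) and mean_ml.
    """
    if window_bp < 100:
        raise ValueError("window_bp must be >= 100")
    df = _covered(table, context, min_cov)
    df["window"] = df["pos"] // window_bp
    grouped = df.groupby(["chrom", "window"], sort=True).agg(
        n_cpgs=("ml", "size"), mean_ml=("ml", "mean")
    )
    grouped = grouped[grouped["n_cpgs"] >= min_cpgs].reset_index()
    if len(grouped) < 2:
        raise ValueError(
            f"fewer than 2 windows with >= {min_cpgs} covered CpGs"
        )
    grouped["cpg_density"] = grouped["n_cpgs"] / window_bp
    grouped["window_start"] = grouped["window"] * window_bp
    out = grouped[["chrom", "window_start", "cpg_density", "mean_ml"]]
    if out["cpg_density"].nunique() == 1 or out["mean_ml"].nunique() == 1:
        warnings.warn("density or methylation constant across windows; r undefined")
        return out, float("nan")
    r = float(sps.pearsonr(out["cpg_density"], out["mean_ml"]).statistic)
    return out, r


def _bin_means(table: MethylomeTable, bin_bp: int, min_cov: int, context) -> pd.Series:
    df = _covered(table, context, min_cov)
    df["bin"] = df["pos"] // bin_bp
    return df.groupby(["chrom", "bin"], sort=True)["ml"].mean()


def replicate_correlation(
    table_a: MethylomeTable,
    table_b: MethylomeTable,
    bin_bp: int = 1000,
    min_cov: int = 5,
    context: str | None = "CG",
) -> float:
    """Pearson correlation of binned methylation between two samples,
    over bins covered in both."""
    a = _bin_means(table_a, bin_bp, min_cov, context)
    b = _bin_means(table_b, bin_bp, min_cov, context)
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1, join="inner")
    if len(joined) < 2:
        raise ValueError("fewer than 2 bins covered in both samples")
    if joined["a"].nunique() == 1 or joined["b"].nunique() == 1:
        warnings.warn("binned methylation constant; correlation undefined")
        return float("nan")
    return float(sps.pearsonr(joined["a"], joined["b"]).statistic)
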