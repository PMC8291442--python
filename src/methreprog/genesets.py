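"""Gene-set methylation dynamics and methylation-expression association.

HOX clusters, non-HOX homeobox genes and developmental signaling genes
are tracked as named gene sets: per-gene promoter and genic methylation
across samples, a paired Wilcoxon signed-rank test for between-sample
promoter shifts, and Spearman association between promoter methylation
and expression.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import AnnotationSet, MethylomeTable, chrom_site_arrays


def _region_mean(
    sites: dict, chrom: str, start: int, end: int, exclude: tuple[int, int] | None,
    min_cpgs: int,
) -> tuple[float, int]:
    if chrom not in sites:
        return np.nan, 0
    pos, ml = sites[chrom]
    lo, hi = np.searchsorted(pos, [start, end])
    keep = np.ones(hi - lo, dtype=bool)
    if exclude is not None:
        p = pos[lo:hi]
        keep &= (p < exclude[0]) | (p >= exclude[1])
    vals = ml[lo:hi][keep]
    if len(vals) < min_cpgs:
        return np.nan, int(len(vals))
    return float(vals.mean()), int(len(vals))


def gene_set_ml(
    tables: Mapping[str, MethylomeTable] | MethylomeTable,
    annotation: AnnotationSet,
    set_name: str,
    region: str = "promoter",
    min_cpgs: int = 3,
    min_cov: int = 5,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Per-gene, per-sample methylation for a named gene set.

    ``region`` is ``promoter`` (the derived promoter window) or ``genic``
    (the gene span excluding the promoter window, so promoter signal
    cannot dilute gene-body contrasts). Genes with fewer than ``min_cpgs``
    covered CpGs in the region get NaN. Tidy output: one row per
    (gene, sample).
    """
    if region not in ("promoter", "genic"):
        raise ValueError(f"region must be 'promoter' or 'genic', got {region!r}")
    if annotation.promoters is None:
        raise ValueError("annotation has no promoters; call make_promoters first")
    if isinstance(tables, MethylomeTable):
        tables = {tables.sample_id or "sample": tables}
    members = annotation.set_members(set_name)
    genes = annotation.genes.set_index("gene_id")
    promoters = annotation.promoters.set_index("gene_id")
    rows = []
    for sample, table in tables.items():
        df = table.df
        if context is not None:
            df = df[df["context"] == context]
        df = df[df["n_total"] >= min_cov].copy()
        df["ml"] = df["n_meth"] / df["n_total"]
        sites = chrom_site_arrays(df, "ml")
        for m in members.itertuples():
            gene = genes.loc[m.gene_id]
            prom = promoters.loc[m.gene_id]
            if region == "promoter":
                mean, n = _region_mean(
                    sites, str(prom["chrom"]), int(prom["start"]), int(prom["end"]),
                    None, min_cpgs,
                )
            else:
                mean, n = _region_mean(
                    sites, str(gene["chrom"]), int(gene["start"]), int(gene["end"]),
                    (int(prom["start"]), int(prom["end"])), min_cpgs,
                )
            rows.append((set_name, m.cluster, m.gene_id, sample, region, mean, n))
    return pd.DataFrame(
        rows,
        columns=["set_name", "cluster", "gene_id", "sample", "region", "mean_ml", "n_cpgs"],
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments via subset-sum DP.

    Ranks may be half-integers (average ranks under ties), so the DP runs
    on doubled integer ranks.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    dist = np.zeros(int(r2.sum()) + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    total = dist.sum()  # == 2^n
    w2 = int(np.rint(2 * w_plus))
    cdf = dist[: w2 + 1].sum() / total
    sf = dist[w2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def paired_promoter_test(
    mls_a: Sequence[float], mls_b: Sequence[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (classic Wilcoxon convention; with small
    gene sets this is visible, hence explicit). The null distribution is
    exact (all sign assignments) for up to ``exact_max_n`` non-zero
    differences and a normal approximation with continuity and tie
    correction above. Returns ``(W+, p)``; if every difference is zero,
    ``p = 1`` with a warning. NaN pairs are ignored.
    """
    a = np.asarray(mls_a, dtype=float)
    b = np.asarray(mls_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    if sigma2 <= 0:
        warnings.warn("degenerate rank variance; p = 1")
        return w_plus, 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2) if diff != 0 else 0.0
    return w_plus, float(2.0 * sps.norm.sf(abs(z)))


def methylation_expression_association(
    ml_table: pd.DataFrame,
    expression: pd.DataFrame,
    expressed_min_fpkm: float = 1.0,
    methylated_min_ml: float = 0.5,
) -> pd.DataFrame:
    """Per-sample association between promoter methylation and expression.

    ``ml_table`` is the tidy output of :func:`gene_set_ml`; ``expression``
    has columns gene_id, sample, fpkm. For each sample present in both,
    reports Spearman's rho between methylation and log2(FPKM + 1), plus a
    2x2 contingency summary of expressed (FPKM >= threshold) against
    methylated (ML >= threshold) genes.
    """
    shared_samples = sorted(
        set(ml_table["sample"]).intersection(expression["sample"])
    )
    if not shared_samples:
        raise ValueError("no sample shared between methylation and expression tables")
    rows = []
    for sample in shared_samples:
        ml = ml_table[ml_table["sample"] == sample][["gene_id", "mean_ml"]].dropna()
        ex = expression[expression["sample"] == sample][["gene_id", "fpkm"]]
        merged = ml.merge(ex, on="gene_id")
        if len(merged) < 3:
            raise ValueError(
                f"sample {sample!r}: fewer than 3 genes shared between "
                "methylation and expression"
            )
        log_expr = np.log2(merged["fpkm"] + 1.0)
        if merged["mean_ml"].nunique() == 1 or log_expr.nunique() == 1:
            warnings.warn(f"sample {sample!r}: constant input; rho undefined")
            rho, p = float("nan"), float("nan")
        else:
            res = sps.spearmanr(merged["mean_ml"], log_expr)
            rho, p = float(res.statistic), float(res.pvalue)
        expressed = merged["fpkm"] >= expressed_min_fpkm
        methylated = merged["mean_ml"] >= methylated_min_ml
        rows.append(
            (
                sample,
                len(merged),
                rho,
                p,
                int((expressed & methylated).sum()),
                int((expressed & ~methylated).sum()),
                int((~expressed & methylated).sum()),
                int((~expressed & ~methylated).sum()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "n_genes",
            "spearman_rho",
            "p",
            "n_expressed_methylated",
            "n_expressed_unmethylated",
            "n_silent_methylated",
            "n_silent_unmethylated",
        ],
    )
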