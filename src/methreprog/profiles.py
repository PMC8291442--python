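"""Positional methylation structure.

TSS metaprofiles (strand-oriented 100-bp bins over +-6 kb), per-element
methylation, mosaic-domain segmentation by smoothed thresholding, and
promoter CpG-density classes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnnotationSet, MethylomeTable, chrom_site_arrays


@dataclass
class BinProfile:
    """Mean methylation per fixed-width bin around the TSS.

    Bin ``k`` covers strand-oriented offsets
    ``[-flank + k * bin_bp, -flank + (k+1) * bin_bp)``; the offset of a site
    at position p from a gene with TSS t is ``p - t`` on + strand genes and
    ``t - p`` on - strand genes.
    """

    flank_bp: int
    bin_bp: int
    mean_ml: np.ndarray  # NaN where a bin has no sites
    n_sites: np.ndarray

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bp // self.bin_bp

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the TSS."""
        return -self.flank_bp + np.arange(self.n_bins) * self.bin_bp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.offsets,
                "bin_end": self.offsets + self.bin_bp,
                "mean_ml": self.mean_ml,
                "n_sites": self.n_sites,
            }
        )


def tss_metaprofile(
    table: MethylomeTable,
    annotation: AnnotationSet,
    flank: int = 6000,
    bin_bp: int = 100,
    min_cov: int = 5,
    context: str | None = "CG",
) -> BinProfile:
    """Average methylation around TSSs in strand-oriented bins.

    Averages over (gene, site) pairs, i.e. every covered CpG within
    ``flank`` of a TSS contributes once per gene it is near.
    """
    if (2 * flank) % bin_bp != 0:
        raise ValueError("2 * flank must be a multiple of bin_bp")
    n_bins = 2 * flank // bin_bp
    df = table.df
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] >= min_cov].copy()
    df["ml"] = df["n_meth"] / df["n_total"]
    sites = chrom_site_arrays(df, "ml")
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in annotation.genes.itertuples():
        if gene.chrom not in sites:
            continue
        pos, ml = sites[gene.chrom]
        lo, hi = np.searchsorted(pos, [gene.tss - flank, gene.tss + flank + 1])
        p = pos[lo:hi]
        v = ml[lo:hi]
        off = p - gene.tss if gene.strand == "+" else gene.tss - p
        keep = (off >= -flank) & (off < flank)
        idx = (off[keep] + flank) // bin_bp
        np.add.at(sums, idx, v[keep])
        np.add.at(counts, idx, 1)
    if counts.sum() == 0:
        raise ValueError("no covered CpGs within the TSS flanks of any gene")
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinProfile(flank_bp=flank, bin_bp=bin_bp, mean_ml=mean, n_sites=counts)


def element_ml(
    table: MethylomeTable,
    intervals: pd.DataFrame,
    min_cpgs: int = 3,
    min_cov: int = 5,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Mean per-site methylation within each interval.

    ``intervals`` needs columns chrom, start, end (0-based half-open);
    other columns are carried through. Intervals with fewer than
    ``min_cpgs`` covered CpGs get NaN.
    """
    df = table.df
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] >= min_cov].copy()
    df["ml"] = df["n_meth"] / df["n_total"]
    sites = chrom_site_arrays(df, "ml")
    means = np.full(len(intervals), np.nan)
    n_cpgs = np.zeros(len(intervals), dtype=np.int64)
    for i, iv in enumerate(intervals.itertuples()):
        if iv.chrom not in sites:
            continue
        pos, ml = sites[iv.chrom]
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        n_cpgs[i] = hi - lo
        if hi - lo >= min_cpgs:
            means[i] = ml[lo:hi].mean()
    out = intervals.copy()
    out["mean_ml"] = means
    out["n_cpgs"] = n_cpgs
    return out


def _merge_short_runs(runs: list[list], min_len: int) -> list[list]:
    """Merge runs shorter than min_len into the flanking longer run
    (ties go to the preceding run), coalescing equal states."""

    def coalesce(rs):
        out = []
        for state, count in rs:
            if out and out[-1][0] == state:
                out[-1][1] += count
            else:
                out.append([state, count])
        return out

    runs = coalesce(runs)
    while len(runs) > 1:
        short = [i for i, (_, c) in enumerate(runs) if c < min_len]
        if not short:
            break
        i = short[0]
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[j][1] += runs[i][1]
        del runs[i]
        runs = coalesce(runs)
    return runs


def segment_domains(
    table: MethylomeTable,
    smooth_w: int = 5,
    state_threshold: float = 0.5,
    min_cpgs_per_domain: int = 5,
    min_cov: int = 5,
    context: str | None = "CG",
) -> pd.DataFrame:
    """Segment each chromosome into methylated/unmethylated domains.

    Per-site levels are smoothed with a centered running mean over
    ``smooth_w`` CpGs (windows truncated at chromosome ends); sites are
    called methylated where the smoothed level is >= ``state_threshold``;
    maximal constant-state runs are emitted, with runs shorter than
    ``min_cpgs_per_domain`` merged into the flanking longer run (ties to
    the preceding run). The final state of each domain is re-derived from
    its mean raw methylation, so ``state == methylated`` iff
    ``mean_ml >= state_threshold``.

    Deterministic, and suited to the bimodal all-or-nothing methylation
    these genomes show; not a general change-point method.
    """
    df = table.df
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] >= min_cov].copy()
    df["ml"] = df["n_meth"] / df["n_total"]
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        ml = sub["ml"].to_numpy()
        if len(sub) == 0:
            continue
        if len(sub) < smooth_w:
            warnings.warn(
                f"{chrom}: fewer covered CpGs ({len(sub)}) than smooth_w "
                f"({smooth_w}); emitting a single domain"
            )
            runs = [[bool(ml.mean() >= state_threshold), len(ml)]]
        else:
            smoothed = (
                pd.Series(ml).rolling(smooth_w, center=True, min_periods=1).mean().to_numpy()
            )
            state = smoothed >= state_threshold
            breaks = np.flatnonzero(np.diff(state.astype(np.int8))) + 1
            bounds = np.concatenate([[0], breaks, [len(state)]])
            runs = [
                [bool(state[a]), int(b - a)] for a, b in zip(bounds[:-1], bounds[1:])
            ]
            runs = _merge_short_runs(runs, min_cpgs_per_domain)
        start_idx = 0
        pending = []
        for meth_state, count in runs:
            a, b = start_idx, start_idx + count
            mean_ml = float(ml[a:b].mean())
            pending.append(
                [
                    chrom,
                    int(pos[a]),
                    int(pos[b - 1]) + 1,
                    "methylated" if mean_ml >= state_threshold else "unmethylated",
                    int(count),
                    mean_ml,
                ]
            )
            start_idx = b
        # re-deriving the state from raw means can make neighbors agree;
        # coalesce them so domains stay maximal
        merged_rows = []
        for row in pending:
            if merged_rows and merged_rows[-1][3] == row[3]:
                prev = merged_rows[-1]
                n = prev[4] + row[4]
                prev[5] = (prev[5] * prev[4] + row[5] * row[4]) / n
                prev[4] = n
                prev[2] = row[2]
            else:
                merged_rows.append(row)
        rows.extend(merged_rows)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "n_cpgs", "mean_ml"]
    )


def promoter_density_classes(
    annotation: AnnotationSet,
    cpg_positions: MethylomeTable | pd.DataFrame,
    low_q: float = 0.25,
    high_q: float = 0.75,
) -> pd.DataFrame:
    """Classify promoters as low/intermediate/high CpG density.

    Density is CpGs per promoter bp; class cutoffs are the ``low_q`` and
    ``high_q`` quantiles of the density distribution within the dataset.
    A promoter is ``low`` if strictly below the low cutoff and ``high`` if
    strictly above the high cutoff, so ties at the quantiles resolve to
    ``intermediate``.
    """
    if annotation.promoters is None:
        raise ValueError("annotation has no promoters; call make_promoters first")
    df = cpg_positions.df if isinstance(cpg_positions, MethylomeTable) else cpg_positions
    sites = {
        chrom: np.sort(sub["pos"].to_numpy()) for chrom, sub in df.groupby("chrom")
    }
    promoters = annotation.promoters
    counts = np.zeros(len(promoters), dtype=np.int64)
    for i, p in enumerate(promoters.itertuples()):
        if p.chrom not in sites:
            continue
        lo, hi = np.searchsorted(sites[p.chrom], [p.start, p.end])
        counts[i] = hi - lo
    length = (promoters["end"] - promoters["start"]).to_numpy()
    density = counts / np.maximum(length, 1)
    ql, qh = np.quantile(density, [low_q, high_q])
    cls = np.where(density < ql, "low", np.where(density > qh, "high", "intermediate"))
    out = promoters.copy()
    out["n_cpgs"] = counts
    out["cpg_density"] = density
    out["density_class"] = cls
    return out
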