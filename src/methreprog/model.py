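"""Core data model: per-CpG methylation call tables and gene annotation.

All coordinates inside the package are 0-based, half-open. Readers and
writers (:mod:`methreprog.io`) convert at the boundary, so no other module
ever has to think about format conventions.

The central container is :class:`MethylomeTable`, a thin wrapper around a
pandas DataFrame with one row per cytosine and columns
``chrom, pos, strand, context, n_meth, n_total``. The per-site methylation
level (ML) is ``n_meth / n_total``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

METH_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
CONTEXTS = ("CG", "CHG", "CHH")
#: "." marks records without strand information (bedGraph dialect, merged dyads).
STRANDS = ("+", "-", ".")


@dataclass
class SampleMeta:
    """Per-library metadata attached to a methylation call table."""

    sample_id: str
    species: str = ""
    stage: str = ""
    replicate: int = 1
    conversion_rate: float | None = None
    source_format: str | None = None

    def __post_init__(self) -> None:
        if self.conversion_rate is not None and not 0.0 <= self.conversion_rate <= 1.0:
            raise ValueError(
                f"conversion_rate must be in [0, 1], got {self.conversion_rate!r}"
            )


@dataclass
class MethylomeTable:
    """Per-cytosine methylation counts for one sample/stage.

    Invariants (checked by :meth:`validate`):

    * ``0 <= n_meth <= n_total`` for every record,
    * ``(chrom, pos, strand)`` unique,
    * records sorted by ``(chrom, pos)``,
    * ``context`` in {CG, CHG, CHH} and ``strand`` in {+, -, .}.
    """

    df: pd.DataFrame
    sample_id: str = ""
    species: str = ""
    stage: str = ""

    @classmethod
    def new(
        cls,
        df: pd.DataFrame,
        sample_id: str = "",
        species: str = "",
        stage: str = "",
    ) -> "MethylomeTable":
        """Build a table from a raw frame: sort, re-index, validate."""
        df = df[METH_COLUMNS].copy()
        df["pos"] = df["pos"].astype(np.int64)
        df["n_meth"] = df["n_meth"].astype(np.int64)
        df["n_total"] = df["n_total"].astype(np.int64)
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        df = df.reset_index(drop=True)
        table = cls(df=df, sample_id=sample_id, species=species, stage=stage)
        table.validate()
        return table

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], sample_id: str = "", species: str = "", stage: str = ""
    ) -> "MethylomeTable":
        """Build from an iterable of (chrom, pos, strand, context, n_meth, n_total)."""
        df = pd.DataFrame(list(records), columns=METH_COLUMNS)
        return cls.new(df, sample_id=sample_id, species=species, stage=stage)

    def validate(self) -> "MethylomeTable":
        df = self.df
        missing = [c for c in METH_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"methylome table missing columns {missing}")
        if len(df) == 0:
            return self
        if (df["n_meth"] < 0).any() or (df["n_total"] < 0).any():
            raise ValueError("negative counts in methylome table")
        if (df["n_meth"] > df["n_total"]).any():
            raise ValueError("n_meth exceeds n_total in methylome table")
        bad_ctx = set(df["context"].unique()) - set(CONTEXTS)
        if bad_ctx:
            raise ValueError(f"unknown cytosine context(s) {sorted(bad_ctx)}")
        bad_strand = set(df["strand"].unique()) - set(STRANDS)
        if bad_strand:
            raise ValueError(f"unknown strand value(s) {sorted(bad_strand)}")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom, pos, strand) records")
        grouped = df.groupby("chrom", sort=False)["pos"]
        if not grouped.apply(lambda s: s.is_monotonic_increasing).all():
            raise ValueError("records not sorted by (chrom, pos)")
        return self

    # -- convenience accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ml(self) -> pd.Series:
        """Per-site methylation level; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            ml = self.df["n_meth"] / self.df["n_total"]
        return ml.where(self.df["n_total"] > 0)

    def subset_context(self, contexts: str | Sequence[str]) -> "MethylomeTable":
        if isinstance(contexts, str):
            contexts = (contexts,)
        df = self.df[self.df["context"].isin(contexts)].reset_index(drop=True)
        return dataclasses.replace(self, df=df)

    def covered(self, min_cov: int) -> pd.DataFrame:
        """Records with n_total >= min_cov, with an ``ml`` column attached."""
        df = self.df[self.df["n_total"] >= min_cov].copy()
        df["ml"] = df["n_meth"] / df["n_total"]
        return df


def filter_by_coverage(table: MethylomeTable, min_cov: int) -> MethylomeTable:
    """Keep only records with ``n_total >= min_cov`` (order preserved)."""
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    df = table.df[table.df["n_total"] >= min_cov].reset_index(drop=True)
    return dataclasses.replace(table, df=df)


def merge_cpg_dyads(table: MethylomeTable) -> MethylomeTable:
    """Pool symmetric CpG counts: a + strand record at ``p`` and the - strand
    record at ``p + 1`` are summed into a single record at ``p`` (strand "+").

    Unpaired records and non-CG contexts pass through unchanged. Counts are
    conserved genome-wide (``sum n_meth`` and ``sum n_total`` are invariant).
    """
    df = table.df
    cg = df[df["context"] == "CG"]
    rest = df[df["context"] != "CG"]
    plus = cg[cg["strand"] == "+"]
    minus = cg[cg["strand"] == "-"]
    dot = cg[cg["strand"] == "."]

    m_shift = minus.assign(pos=minus["pos"] - 1)
    joined = plus[["chrom", "pos", "n_meth", "n_total"]].merge(
        m_shift[["chrom", "pos", "n_meth", "n_total"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("_p", "_m"),
        indicator=True,
    )
    paired = joined[joined["_merge"] == "both"]
    merged = pd.DataFrame(
        {
            "chrom": paired["chrom"],
            "pos": paired["pos"],
            "strand": "+",
            "context": "CG",
            "n_meth": paired["n_meth_p"] + paired["n_meth_m"],
            "n_total": paired["n_total_p"] + paired["n_total_m"],
        }
    )
    lone_plus = joined[joined["_merge"] == "left_only"]
    lone_plus = pd.DataFrame(
        {
            "chrom": lone_plus["chrom"],
            "pos": lone_plus["pos"],
            "strand": "+",
            "context": "CG",
            "n_meth": lone_plus["n_meth_p"],
            "n_total": lone_plus["n_total_p"],
        }
    )
    lone_minus = joined[joined["_merge"] == "right_only"]
    lone_minus = pd.DataFrame(
        {
            "chrom": lone_minus["chrom"],
            "pos": lone_minus["pos"] + 1,  # restore original - strand coordinate
            "strand": "-",
            "context": "CG",
            "n_meth": lone_minus["n_meth_m"],
            "n_total": lone_minus["n_total_m"],
        }
    )
    out = pd.concat([merged, lone_plus, lone_minus, dot, rest], ignore_index=True)
    return MethylomeTable.new(
        out, sample_id=table.sample_id, species=table.species, stage=table.stage
    )


# -- annotation ---------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Attach the 0-based TSS coordinate: ``start`` on +, ``end - 1`` on -."""
    genes = genes.copy()
    if (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "gene_id"].tolist()
        raise ValueError(f"gene(s) without strand: {bad[:5]}")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return genes


@dataclass
class AnnotationSet:
    """Genes, derived promoters, named gene sets and optional repeats.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss.
    ``promoters`` columns: gene_id, chrom, start, end, strand.
    ``gene_sets`` maps set name -> DataFrame(gene_id, cluster).
    """

    genes: pd.DataFrame
    promoters: pd.DataFrame | None = None
    gene_sets: dict[str, pd.DataFrame] = field(default_factory=dict)
    repeats: pd.DataFrame | None = None

    def validate(self) -> "AnnotationSet":
        g = self.genes
        if (g["start"] < 0).any() or (g["start"] >= g["end"]).any():
            raise ValueError("gene intervals must satisfy 0 <= start < end")
        if "tss" not in g.columns:
            raise ValueError("genes lack a tss column; use add_tss()")
        plus = g["strand"] == "+"
        if not (g.loc[plus, "tss"] == g.loc[plus, "start"]).all():
            raise ValueError("tss must equal start on + strand genes")
        if not (g.loc[~plus, "tss"] == g.loc[~plus, "end"] - 1).all():
            raise ValueError("tss must equal end - 1 on - strand genes")
        known = set(g["gene_id"])
        for name, members in self.gene_sets.items():
            unknown = set(members["gene_id"]) - known
            if unknown:
                raise ValueError(
                    f"gene set {name!r} has members not in the annotation: "
                    f"{sorted(unknown)[:5]}"
                )
        return self

    def set_members(self, set_name: str) -> pd.DataFrame:
        if set_name not in self.gene_sets:
            raise KeyError(
                f"unknown gene set {set_name!r}; available: {sorted(self.gene_sets)}"
            )
        return self.gene_sets[set_name]


def make_promoters(
    annotation: AnnotationSet, upstream: int = 1000, downstream: int = 500
) -> AnnotationSet:
    """Derive promoter intervals around each TSS.

    On the + strand the promoter is ``[tss - upstream, tss + downstream)``;
    on the - strand the numerically mirrored window
    ``[tss - downstream, tss + upstream)``. Intervals are clipped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    genes = annotation.genes
    if (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("cannot derive promoters for genes without strand")
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - upstream, genes["tss"] - downstream)
    end = np.where(plus, genes["tss"] + downstream, genes["tss"] + upstream)
    promoters = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "start": np.maximum(start, 0).astype(np.int64),
            "end": np.maximum(end, 0).astype(np.int64),
            "strand": genes["strand"],
        }
    )
    return dataclasses.replace(annotation, promoters=promoters.reset_index(drop=True))


def chrom_site_arrays(
    df: pd.DataFrame, value_col: str = "ml"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Split a site frame into per-chromosome (positions, values) arrays.

    Positions are sorted within each chromosome, so downstream interval
    queries reduce to ``np.searchsorted`` range lookups.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        val = sub[value_col].to_numpy(dtype=float)
        order = np.argsort(pos, kind="mergesort")
        out[str(chrom)] = (pos[order], val[order])
    return out
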