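"""Readers and writers for standard methylation-call and annotation formats.

Two call dialects are supported:

* Bismark-style cytosine report: TSV, 1-based positions, columns
  chrom / pos / strand / count_methylated / count_unmethylated / context
  (an optional trailing trinucleotide column is tolerated and ignored).
* count-bearing bedGraph: 0-based half-open, columns
  chrom / start / end / methylation percent / count_meth / count_unmeth.

Positions are converted to the package's 0-based convention on read and
restored exactly on write, so read -> write -> read is the identity on the
fields each dialect carries.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AnnotationSet, MethylomeTable, SampleMeta, add_tss

COORD_HEADER = "# coordinates: 0-based, half-open"


class ParseError(ValueError):
    pass


def _meta_kwargs(sample_meta: SampleMeta | None) -> dict:
    if sample_meta is None:
        return {}
    return {
        "sample_id": sample_meta.sample_id,
        "species": sample_meta.species,
        "stage": sample_meta.stage,
    }


def _read_tsv(path, names, numeric):
    """Read a headerless TSV, skipping comment/track lines; report the
    1-based line number of the first malformed row."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype=str,
        skip_blank_lines=True,
    )
    df = df[~df[0].astype(str).str.startswith("track")]
    if df.shape[1] < len(names):
        raise ParseError(
            f"{path}: expected >= {len(names)} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    df = df.iloc[:, : len(names)]
    df.columns = names
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise ParseError(
                f"{path}: malformed value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}"
            )
        df[col] = converted
    return df.reset_index(drop=True)


def read_cytosine_report(
    path, sample_meta: SampleMeta | None = None
) -> MethylomeTable:
    """Read a Bismark-style cytosine report (1-based on disk)."""
    df = _read_tsv(
        path,
        ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context"],
        numeric=["pos", "count_meth", "count_unmeth"],
    )
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise ParseError(f"{path}: negative counts")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"].astype(np.int64) - 1,  # 1-based -> 0-based
            "strand": df["strand"],
            "context": df["context"],
            "n_meth": df["count_meth"].astype(np.int64),
            "n_total": (df["count_meth"] + df["count_unmeth"]).astype(np.int64),
        }
    )
    return MethylomeTable.new(out, **_meta_kwargs(sample_meta))


def write_cytosine_report(table: MethylomeTable, path) -> None:
    df = table.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["pos"] + 1,  # restore 1-based
            "strand": df["strand"],
            "count_meth": df["n_meth"],
            "count_unmeth": df["n_total"] - df["n_meth"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_counts(
    path, sample_meta: SampleMeta | None = None, context: str = "CG"
) -> MethylomeTable:
    """Read the count-bearing bedGraph dialect (0-based half-open on disk).

    The percent column is ignored in favor of the counts; a disagreement of
    more than 0.5 percentage points triggers a warning.
    """
    try:
        df = _read_tsv(
            path,
            ["chrom", "start", "end", "percent", "count_meth", "count_unmeth"],
            numeric=["start", "end", "percent", "count_meth", "count_unmeth"],
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(
            columns=["chrom", "start", "end", "percent", "count_meth", "count_unmeth"]
        )
    if len(df) == 0:
        empty = pd.DataFrame(
            {c: [] for c in ["chrom", "pos", "strand", "context", "n_meth", "n_total"]}
        )
        return MethylomeTable.new(empty, **_meta_kwargs(sample_meta))
    if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
        raise ParseError(f"{path}: negative counts")
    total = df["count_meth"] + df["count_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_from_counts = 100.0 * df["count_meth"] / total
    mismatch = (pct_from_counts - df["percent"]).abs() > 0.5
    mismatch &= total > 0
    if mismatch.any():
        warnings.warn(
            f"{path}: {int(mismatch.sum())} record(s) with percent column "
            "inconsistent with counts by > 0.5 points; counts win",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"].astype(np.int64),
            "strand": ".",
            "context": context,
            "n_meth": df["count_meth"].astype(np.int64),
            "n_total": total.astype(np.int64),
        }
    )
    return MethylomeTable.new(out, **_meta_kwargs(sample_meta))


def write_bedgraph_counts(table: MethylomeTable, path) -> None:
    df = table.df
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * df["n_meth"] / df["n_total"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "percent": pct.fillna(0.0).round(6),
            "count_meth": df["n_meth"],
            "count_unmeth": df["n_total"] - df["n_meth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph_ml(table: MethylomeTable, path, min_cov: int = 1) -> None:
    """Export a per-site methylation-level track (browser-style bedGraph)."""
    df = table.df[table.df["n_total"] >= min_cov]
    ml = df["n_meth"] / df["n_total"]
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 1, "ml": ml.round(6)}
    )
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{table.sample_id} ML"\n')
        out.to_csv(fh, sep="\t", header=False, index=False)


# -- annotation ---------------------------------------------------------------


def read_bed6_genes(path) -> pd.DataFrame:
    """Read genes from BED6 (chrom, start, end, name, score, strand)."""
    df = _read_tsv(
        path,
        ["chrom", "start", "end", "gene_id", "score", "strand"],
        numeric=["start", "end"],
    )
    genes = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64),
            "end": df["end"].astype(np.int64),
            "strand": df["strand"],
        }
    )
    return add_tss(genes)


def write_bed6_genes(genes: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "gene_id": genes["gene_id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3_genes(path) -> pd.DataFrame:
    """Read gene features from GFF3 (1-based inclusive on disk)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        gid = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("gene_id", [None])[0]
            or feat.attributes.get("Name", [feat.id])[0]
        )
        rows.append((gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return add_tss(genes)


def read_gene_sets(path) -> dict[str, pd.DataFrame]:
    """Read gene sets from TSV with columns set_name, cluster, gene_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"set_name", "cluster", "gene_id"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: gene-set TSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    sets = {}
    for name, sub in df.groupby("set_name", sort=False):
        sets[str(name)] = sub[["gene_id", "cluster"]].reset_index(drop=True)
    return sets


def write_gene_sets(gene_sets: dict[str, pd.DataFrame], path) -> None:
    frames = []
    for name, members in gene_sets.items():
        out = members[["gene_id", "cluster"]].copy()
        out.insert(0, "set_name", name)
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Read an expression table: TSV with columns gene_id, sample, fpkm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "sample", "fpkm"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: expression TSV needs columns {sorted(required)}"
        )
    if (df["fpkm"] < 0).any():
        raise ParseError(f"{path}: negative FPKM values")
    return df[["gene_id", "sample", "fpkm"]].copy()


def write_domains_bed(domains: pd.DataFrame, path) -> None:
    """Write methylation domains as BED4 with the state in the name field."""
    out = pd.DataFrame(
        {
            "chrom": domains["chrom"],
            "start": domains["start"],
            "end": domains["end"],
            "name": domains["state"],
        }
    )
    with open(path, "w") as fh:
        fh.write(COORD_HEADER + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, coord_comment: bool = True) -> None:
    """Write a result table as TSV with the coordinate-convention header."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if coord_comment:
            fh.write(COORD_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False)
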