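"""Config-driven orchestration of the full analysis.

A run is described by a single YAML config (sample manifest, annotation
paths, per-module parameters, output directory, seed) and executes
global statistics -> profiles/segmentation -> reprogramming -> gene-set
analysis, writing TSV/BED/JSON outputs plus a machine-readable summary.
Identical config + inputs give byte-identical summaries.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .genesets import gene_set_ml, methylation_expression_association
from .model import AnnotationSet, MethylomeTable, make_promoters, merge_cpg_dyads
from .profiles import segment_domains, tss_metaprofile
from .reprogramming import (
    DYNAMICS_THRESHOLDS,
    call_dmps,
    classify_dynamics,
    dmp_heatmap_matrix,
    sperm_oocyte_divergence,
)
from .stats import conversion_rate, corrected_noncpg_ml, global_ml, ml_distribution

log = logging.getLogger("methreprog")

DEFAULT_PARAMS = dict(
    min_cov=5,
    merge_dyads=True,
    promoter_upstream=1000,
    promoter_downstream=500,
    flank_bp=6000,
    profile_bin_bp=100,
    divergence_bin_bp=1000,
    dmp_min_cpgs=3,
    dmp_delta_min=0.2,
    dmp_alpha=0.05,
    dynamics_thresholds=list(DYNAMICS_THRESHOLDS),
)


@dataclass
class RunConfig:
    samples: list[dict]
    output_dir: str
    annotation_genes: str | None = None
    annotation_format: str = "bed6"
    gene_sets_path: str | None = None
    expression_path: str | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ann = raw.get("annotation", {}) or {}
        cfg = cls(
            samples=raw["samples"],
            output_dir=raw.get("output_dir", "methreprog_out"),
            annotation_genes=ann.get("genes"),
            annotation_format=ann.get("format", "bed6"),
            gene_sets_path=ann.get("gene_sets"),
            expression_path=raw.get("expression"),
            params=raw.get("parameters", {}) or {},
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> "RunConfig":
        def resolve(p):
            p = Path(p)
            if not p.is_absolute() and base is not None:
                p = base / p
            return p

        if not self.samples:
            raise ValueError("config lists no samples")
        for s in self.samples:
            for key in ("path", "sample_id", "stage"):
                if key not in s:
                    raise ValueError(f"sample entry missing {key!r}: {s}")
            s["path"] = str(resolve(s["path"]))
            if not Path(s["path"]).exists():
                raise FileNotFoundError(f"sample file not found: {s['path']}")
            s.setdefault("format", "cytosine_report")
            s.setdefault("replicate", 1)
        for attr in ("annotation_genes", "gene_sets_path", "expression_path"):
            val = getattr(self, attr)
            if val is not None:
                val = str(resolve(val))
                if not Path(val).exists():
                    raise FileNotFoundError(f"{attr} not found: {val}")
                setattr(self, attr, val)
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        if merged["min_cov"] < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0 < merged["dmp_alpha"] <= 1:
            raise ValueError("dmp_alpha must be in (0, 1]")
        self.params = merged
        return self


def _load_sample(entry: dict, merge: bool) -> MethylomeTable:
    from .model import SampleMeta

    meta = SampleMeta(
        sample_id=entry["sample_id"],
        species=entry.get("species", ""),
        stage=entry["stage"],
        replicate=int(entry.get("replicate", 1)),
        source_format=entry["format"],
    )
    if entry["format"] == "cytosine_report":
        table = mio.read_cytosine_report(entry["path"], meta)
    elif entry["format"] == "bedgraph_counts":
        table = mio.read_bedgraph_counts(entry["path"], meta)
    else:
        raise ValueError(f"unknown sample format {entry['format']!r}")
    return merge_cpg_dyads(table) if merge else table


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the machine-readable summary."""
    p = config.params
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "samples": {}, "parameters": p}

    tables: dict[str, MethylomeTable] = {}
    controls: dict[str, MethylomeTable] = {}
    for entry in config.samples:
        table = _load_sample(entry, p["merge_dyads"])
        if entry.get("is_control") or entry["stage"] == "control":
            controls[entry["sample_id"]] = table
        else:
            tables[entry["sample_id"]] = table

    annotation = None
    if config.annotation_genes:
        if config.annotation_format == "bed6":
            genes = mio.read_bed6_genes(config.annotation_genes)
        elif config.annotation_format == "gff3":
            genes = mio.read_gff3_genes(config.annotation_genes)
        else:
            raise ValueError(f"unknown annotation format {config.annotation_format!r}")
        gene_sets = (
            mio.read_gene_sets(config.gene_sets_path) if config.gene_sets_path else {}
        )
        annotation = AnnotationSet(genes=genes, gene_sets=gene_sets)
        annotation = make_promoters(
            annotation, p["promoter_upstream"], p["promoter_downstream"]
        ).validate()

    # conversion rate from control libraries
    conv = None
    for name, ctrl in controls.items():
        conv = conversion_rate(ctrl)
        summary.setdefault("conversion_rate", {})[name] = round(conv, 6)

    # global statistics per sample
    glob_rows = []
    for name, table in tables.items():
        g = global_ml(table, min_cov=p["min_cov"])
        dist = ml_distribution(table, min_cov=p["min_cov"])
        row = {
            "sample_id": name,
            "stage": table.stage,
            "n_sites": g.n_sites_used,
            "global_ml_site_mean": g.site_mean,
            "global_ml_count_weighted": g.count_weighted,
            "bimodality": dist.bimodality,
        }
        noncpg = table.subset_context(("CHG", "CHH"))
        if conv is not None and len(noncpg.df[noncpg.df["n_total"] >= p["min_cov"]]):
            row["corrected_noncpg_ml"] = corrected_noncpg_ml(noncpg, conv, p["min_cov"])
        glob_rows.append(row)
        summary["samples"][name] = {
            "stage": table.stage,
            "global_ml": round(g.site_mean, 6),
            "bimodality": round(dist.bimodality, 6),
        }
    mio.write_tsv(pd.DataFrame(glob_rows), out / "global_summary.tsv")

    # profiles + segmentation
    for name, table in tables.items():
        if annotation is not None:
            profile = tss_metaprofile(
                table, annotation, flank=p["flank_bp"], bin_bp=p["profile_bin_bp"],
                min_cov=p["min_cov"],
            )
            mio.write_tsv(profile.to_frame(), out / "profiles" / f"{name}.tsv")
        domains = segment_domains(table, min_cov=p["min_cov"])
        (out / "domains").mkdir(exist_ok=True, parents=True)
        mio.write_domains_bed(domains, out / "domains" / f"{name}.bed")

    # stage dynamics: mean global ML per stage in manifest order
    stage_order: list[str] = []
    stage_values: dict[str, list[float]] = {}
    for entry in config.samples:
        name = entry["sample_id"]
        if name not in tables:
            continue
        stage = entry["stage"]
        if stage not in stage_order:
            stage_order.append(stage)
        stage_values.setdefault(stage, []).append(
            summary["samples"][name]["global_ml"]
        )
    if len(stage_order) >= 2:
        stage_mls = [(s, float(np.mean(stage_values[s]))) for s in stage_order]
        dyn = classify_dynamics(
            stage_mls, thresholds=tuple(p["dynamics_thresholds"])
        )
        summary["dynamics"] = {
            "stage_ml": {k: round(v, 6) for k, v in dyn.stage_ml.items()},
            "max_delta": round(dyn.max_delta, 6),
            "class": dyn.dynamics_class,
            "demethylation_flag": bool(dyn.demethylation_flag),
        }
        with open(out / "dynamics.json", "w") as fh:
            json.dump(summary["dynamics"], fh, indent=2, sort_keys=True)

    # sperm vs oocyte: divergence + DMPs
    def first_of_stage(stage):
        for entry in config.samples:
            if entry["stage"] == stage and entry["sample_id"] in tables:
                return tables[entry["sample_id"]]
        return None

    sperm, oocyte = first_of_stage("sperm"), first_of_stage("oocyte")
    if sperm is not None and oocyte is not None:
        gdelta, bindelta = sperm_oocyte_divergence(
            sperm, oocyte, bin_bp=p["divergence_bin_bp"], min_cov=p["min_cov"]
        )
        summary["divergence"] = {
            "global_delta": round(gdelta, 6),
            "mean_abs_bin_delta": round(bindelta, 6),
        }
        if annotation is not None:
            dmps = call_dmps(
                sperm, oocyte, annotation.promoters,
                min_cov=p["min_cov"], min_cpgs=p["dmp_min_cpgs"],
                delta_min=p["dmp_delta_min"], alpha=p["dmp_alpha"],
            )
            mio.write_tsv(dmps, out / "dmps.tsv", coord_comment=False)
            n_called = int((dmps["status"] != "ns").sum())
            summary["dmps"] = {
                "n_tested": int(len(dmps)),
                "n_called": n_called,
                "n_hyper_in_sperm": int((dmps["status"] == "hyper_in_a").sum()),
                "n_hypo_in_sperm": int((dmps["status"] == "hypo_in_a").sum()),
            }
            if n_called:
                matrix = dmp_heatmap_matrix(tables, dmps, annotation.promoters,
                                            min_cov=p["min_cov"])
                mio.write_tsv(matrix.reset_index(), out / "dmp_matrix.tsv",
                              coord_comment=False)

    # gene sets
    if annotation is not None and annotation.gene_sets:
        expr = (
            mio.read_expression(config.expression_path)
            if config.expression_path
            else None
        )
        summary["gene_sets"] = {}
        for set_name in annotation.gene_sets:
            frames = [
                gene_set_ml(tables, annotation, set_name, region=region,
                            min_cpgs=p["dmp_min_cpgs"], min_cov=p["min_cov"])
                for region in ("promoter", "genic")
            ]
            tidy = pd.concat(frames, ignore_index=True)
            mio.write_tsv(tidy, out / "gene_sets" / f"{set_name}.tsv",
                          coord_comment=False)
            prom = tidy[tidy["region"] == "promoter"]
            summary["gene_sets"][set_name] = {
                sample: round(float(sub["mean_ml"].mean()), 6)
                for sample, sub in prom.groupby("sample")
                if sub["mean_ml"].notna().any()
            }
            if expr is not None:
                prom_by_stage = prom.copy()
                # expression samples are keyed by stage
                prom_by_stage["sample"] = prom_by_stage["sample"].map(
                    {name: tables[name].stage for name in tables}
                )
                shared = set(prom_by_stage["sample"]).intersection(expr["sample"])
                if shared:
                    assoc = methylation_expression_association(prom_by_stage, expr)
                    mio.write_tsv(assoc, out / "gene_sets" / f"{set_name}_expression.tsv",
                                  coord_comment=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def simulate_cmd(spec_path, outdir, seed: int | None = None):
    """Generate a synthetic dataset directory from a spec YAML file."""
    from .simulate import make_spec, simulate_dataset, write_dataset

    with open(spec_path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "preset" not in raw:
        raise ValueError("spec file must name a 'preset'")
    preset = raw.pop("preset")
    raw.pop("architecture", None)  # derived from the preset
    if seed is not None:
        raw["seed"] = int(seed)
    known = {f.name for f in dataclasses.fields(__import__(
        "methreprog.simulate", fromlist=["SyntheticSpec"]).SyntheticSpec)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown spec field(s): {sorted(unknown)}")
    spec = make_spec(preset, **raw)
    dataset = simulate_dataset(spec, with_expression=True)
    write_dataset(dataset, outdir)
    return dataset
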