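"""TSS metaprofiles, element methylation, domain segmentation, density classes."""
import itertools

import numpy as np
import pandas as pd
import pytest

import methreprog as mr


def _annotation(rows):
    genes = mr.add_tss(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    return mr.AnnotationSet(genes=genes)


def test_metaprofile_uniform_methylome_is_flat():
    records = [("chr1", p, "+", "CG", 5, 10) for p in range(0, 30_000, 90)]
    table = mr.MethylomeTable.from_records(records)
    ann = _annotation([("g", "chr1", 15_000, 16_000, "+")])
    prof = mr.tss_metaprofile(table, ann, min_cov=5)
    assert prof.n_bins == 120
    np.testing.assert_allclose(prof.mean_ml[prof.n_sites > 0], 0.5)


def test_metaprofile_matches_hand_mapped_oracle():
    """Strand-oriented offsets: p - tss on +, tss - p on -; bin k covers
    [-6000 + 100k, -6000 + 100(k+1)). Checked against a brute-force loop
    over a 5-gene layout."""
    rng = np.random.default_rng(11)
    pos = np.sort(rng.choice(np.arange(1, 60_000, 7), size=400, replace=False))
    mls = rng.integers(0, 11, size=400)
    table = mr.MethylomeTable.from_records(
        [("chr1", int(p), "+", "CG", int(m), 10) for p, m in zip(pos, mls)]
    )
    genes = [
        ("g1", "chr1", 9_001, 12_000, "+"),
        ("g2", "chr1", 20_000, 23_001, "-"),
        ("g3", "chr1", 30_503, 31_000, "+"),
        ("g4", "chr1", 38_000, 40_250, "-"),
        ("g5", "chr1", 50_001, 52_000, "+"),
    ]
    ann = _annotation(genes)
    prof = mr.tss_metaprofile(table, ann, min_cov=1)

    sums = np.zeros(120)
    counts = np.zeros(120)
    for gid, chrom, start, end, strand in genes:
        tss = start if strand == "+" else end - 1
        for p, m in zip(pos, mls):
            off = p - tss if strand == "+" else tss - p
            if -6000 <= off < 6000:
                k = (off + 6000) // 100
                sums[k] += m / 10
                counts[k] += 1
    expected = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.testing.assert_allclose(prof.mean_ml, expected, equal_nan=True)
    np.testing.assert_array_equal(prof.n_sites, counts)


def test_metaprofile_mirror_symmetry():
    """Flipping every gene's strand (TSS fixed) mirrors the profile:
    bin i <-> bin 119 - i (offsets chosen off the bin boundaries)."""
    rng = np.random.default_rng(5)
    offs = rng.choice([o for o in range(-5999, 6000) if o % 100 != 0], 300, replace=False)
    tss = 50_000
    table = mr.MethylomeTable.from_records(
        sorted(
            ("chr1", int(tss + o), "+", "CG", int(rng.integers(0, 11)), 10)
            for o in offs
        )
    )
    plus = _annotation([("g", "chr1", tss, tss + 1000, "+")])
    minus_genes = mr.add_tss(
        pd.DataFrame(
            [("g", "chr1", tss - 999, tss + 1, "-")],
            columns=["gene_id", "chrom", "start", "end", "strand"],
        )
    )
    minus = mr.AnnotationSet(genes=minus_genes)
    assert minus.genes.tss.iloc[0] == tss
    p_plus = mr.tss_metaprofile(table, plus, min_cov=1)
    p_minus = mr.tss_metaprofile(table, minus, min_cov=1)
    np.testing.assert_allclose(
        p_plus.mean_ml, p_minus.mean_ml[::-1], equal_nan=True
    )


def test_metaprofile_promoter_dip_on_global_methylome(fish):
    _, truth, tables = fish
    prof = mr.tss_metaprofile(tables["sperm"], truth.annotation)
    center = np.nanmean(prof.mean_ml[55:65])
    outer = np.nanmean(np.concatenate([prof.mean_ml[:10], prof.mean_ml[-10:]]))
    assert center < outer - 0.2


def test_metaprofile_errors_without_covered_sites():
    table = mr.MethylomeTable.from_records([("chr9", 5, "+", "CG", 1, 10)])
    ann = _annotation([("g", "chr1", 50_000, 51_000, "+")])
    with pytest.raises(ValueError, match="no covered CpGs"):
        mr.tss_metaprofile(table, ann)


def test_element_ml_basics():
    table = mr.MethylomeTable.from_records(
        [("chr1", 10, "+", "CG", 10, 10), ("chr1", 20, "+", "CG", 0, 10)]
    )
    intervals = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [0, 0], "end": [100, 15]}
    )
    out = mr.element_ml(table, intervals, min_cpgs=2, min_cov=5)
    assert out.mean_ml.iloc[0] == pytest.approx(0.5)
    assert np.isnan(out.mean_ml.iloc[1])  # below min_cpgs -> missing


def test_element_ml_recovers_truth_domains(anemone):
    spec, truth, tables = anemone
    doms = truth.domain_intervals("sperm")
    doms = doms[doms.n_cpgs >= 5]
    scored = mr.element_ml(tables["sperm"], doms, min_cpgs=3, min_cov=5)
    meth = scored[scored.state == "methylated"].mean_ml.dropna()
    unmeth = scored[scored.state == "unmethylated"].mean_ml.dropna()
    assert (meth >= 0.8).mean() > 0.98
    assert (unmeth <= 0.1).mean() > 0.98


def _segment_oracle(mls, smooth_w=5, threshold=0.5, min_len=5):
    """Independent re-derivation: explicit truncated-window means, groupby
    run-length encoding, naive shortest-run merging."""
    n = len(mls)
    half = smooth_w // 2
    smoothed = [
        float(np.mean(mls[max(0, i - half): min(n, i + half + 1)])) for i in range(n)
    ]
    states = [s >= threshold for s in smoothed]
    runs = [[k, len(list(g))] for k, g in itertools.groupby(states)]
    while len(runs) > 1:
        shorts = [i for i, (_, c) in enumerate(runs) if c < min_len]
        if not shorts:
            break
        i = shorts[0]
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if runs[i - 1][1] >= runs[i + 1][1] else i + 1
        runs[j][1] += runs[i][1]
        del runs[i]
        runs = [[k, sum(c for _, c in g)] for k, g in
                itertools.groupby(runs, key=lambda r: r[0])]
    return runs


def test_segmentation_thirty_cpg_toy_matches_run_length_oracle():
    mls = [0.9] * 10 + [0.0] * 10 + [0.9] * 10
    table = mr.MethylomeTable.from_records(
        [("chr1", 10 * i, "+", "CG", int(m * 10), 10) for i, m in enumerate(mls)]
    )
    doms = mr.segment_domains(table, min_cov=5)
    oracle = _segment_oracle(mls)
    assert [(d.state == "methylated", d.n_cpgs) for d in doms.itertuples()] == [
        (bool(k), c) for k, c in oracle
    ]
    # three domains with boundaries within (smooth_w - 1) / 2 sites of design
    assert len(doms) == 3
    assert abs(doms.n_cpgs.iloc[0] - 10) <= 2 and abs(doms.n_cpgs.iloc[1] - 10) <= 4


def test_segmentation_trivial_and_degenerate_inputs():
    flat = mr.MethylomeTable.from_records(
        [(c, 10 * i, "+", "CG", 0, 10) for c in ("chr1", "chr2") for i in range(20)]
    )
    doms = mr.segment_domains(flat, min_cov=5)
    assert len(doms) == 2 and (doms.state == "unmethylated").all()
    tiny = mr.MethylomeTable.from_records(
        [("chr1", 10 * i, "+", "CG", 10, 10) for i in range(3)]
    )
    with pytest.warns(UserWarning, match="single domain"):
        doms = mr.segment_domains(tiny, min_cov=5)
    assert len(doms) == 1 and doms.state.iloc[0] == "methylated"


def test_segmentation_conserves_site_mean(deutero):
    _, _, tables = deutero
    table = tables["sperm"]
    doms = mr.segment_domains(table, min_cov=5)
    weighted = (doms.mean_ml * doms.n_cpgs).sum() / doms.n_cpgs.sum()
    site_mean = mr.global_ml(table, min_cov=5).site_mean
    assert weighted == pytest.approx(site_mean, abs=1e-12)
    # domain states agree with their mean methylation by construction
    meth = doms.state == "methylated"
    assert (doms.mean_ml[meth] >= 0.5).all() and (doms.mean_ml[~meth] < 0.5).all()


def test_segmentation_recovers_generator_states(deutero):
    spec, truth, tables = deutero
    table = tables["sperm"]
    doms = mr.segment_domains(table, min_cov=5)
    state = truth.site_state("sperm")
    covmask = (table.df.n_total >= 5).to_numpy()
    correct = total = 0
    for chrom, sub in doms.groupby("chrom", sort=False):
        inland = truth.landscape.chrom.to_numpy() == chrom
        pos = truth.landscape.pos.to_numpy()[inland]
        idx = np.searchsorted(sub.start.to_numpy(), pos, side="right") - 1
        ok = (idx >= 0) & covmask[inland]
        pred = (sub.state.to_numpy() == "methylated")[np.clip(idx, 0, None)]
        correct += int(((pred == state[inland]) & ok).sum())
        total += int(ok.sum())
    assert correct / total >= 0.90


def test_promoter_density_classes_quantile_rules():
    # equal densities -> everything intermediate (ties resolve downward)
    genes = [("g%d" % i, "chr1", 10_000 * i + 2000, 10_000 * i + 3000, "+") for i in range(4)]
    ann = mr.make_promoters(_annotation(genes), 1000, 500)
    sites = []
    for i, n in enumerate([3, 3, 3, 3]):
        start = 10_000 * i + 1000
        sites += [("chr1", start + 100 * j, "+", "CG", 1, 1) for j in range(n)]
    table = mr.MethylomeTable.from_records(sorted(sites))
    out = mr.promoter_density_classes(ann, table)
    assert (out.density_class == "intermediate").all()
    # densities 1, 2, 3, 4 per kb -> low, intermediate, intermediate, high
    sites = []
    for i, n in enumerate([1, 2, 3, 4]):
        start = 10_000 * i + 1000
        sites += [("chr1", start + 100 * j, "+", "CG", 1, 1) for j in range(n)]
    table = mr.MethylomeTable.from_records(sorted(sites))
    out = mr.promoter_density_classes(ann, table)
    # promoter span is 1500 bp here, but the ordering is what matters
    assert out.density_class.tolist() == ["low", "intermediate", "intermediate", "high"]


def test_cgi_promoters_enriched_in_high_density_class(fish):
    _, truth, tables = fish
    ann = truth.annotation
    out = mr.promoter_density_classes(ann, tables["sperm"])
    land = truth.landscape
    cgi_pos = {
        chrom: sub.pos.to_numpy()[sub.is_cgi.to_numpy()]
        for chrom, sub in land.groupby("chrom")
    }
    overlaps = []
    for p in out.itertuples():
        pos = cgi_pos.get(p.chrom, np.zeros(0))
        lo, hi = np.searchsorted(pos, [p.start, p.end])
        overlaps.append(hi > lo)
    out = out.assign(cgi=overlaps)
    high_rate_cgi = (out[out.cgi].density_class == "high").mean()
    high_rate_other = (out[~out.cgi].density_class == "high").mean()
    assert high_rate_cgi > high_rate_other + 0.2
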