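"""Gamete divergence, DMP calling, dynamics classification, heatmap matrix."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import methreprog as mr


def _table(site_counts, chrom="chr1"):
    return mr.MethylomeTable.from_records(
        [(chrom, 10 * i, "+", "CG", m, t) for i, (m, t) in enumerate(site_counts)]
    )


def _promoters(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def test_divergence_identical_tables_is_zero():
    t = _table([(5, 10)] * 50)
    gd, bd = mr.sperm_oocyte_divergence(t, t, bin_bp=100)
    assert gd == 0.0 and bd == 0.0


def test_divergence_zero_asymmetry_is_noise_level(anemone):
    _, _, tables = anemone
    gd, bd = mr.sperm_oocyte_divergence(tables["sperm"], tables["oocyte"])
    assert abs(gd) < 0.01
    assert bd < 0.03  # sampling noise only


def test_divergence_increases_along_preset_series(anemone, deutero, fish, mammal):
    """Gamete divergence grows through the deuterostome/chordate series."""
    deltas = []
    for _, _, tables in (anemone, deutero, fish, mammal):
        _, bd = mr.sperm_oocyte_divergence(tables["sperm"], tables["oocyte"])
        deltas.append(bd)
    assert all(a < b for a, b in zip(deltas, deltas[1:]))


def test_call_dmps_identical_tables_yields_none():
    t = _table([(int(i % 2) * 10, 10) for i in range(20)])
    proms = _promoters([("g", "chr1", 0, 200, "+")])
    out = mr.call_dmps(t, t, proms)
    assert (out.status == "ns").all()
    assert out.delta.iloc[0] == 0.0


def test_call_dmps_worked_single_promoter():
    """Pooled 900/1000 vs 100/1000: delta 0.8, vanishing p, hyper in A."""
    a = _table([(90, 100)] * 10)
    b = _table([(10, 100)] * 10)
    proms = _promoters([("g", "chr1", 0, 200, "+")])
    out = mr.call_dmps(a, b, proms)
    row = out.iloc[0]
    assert row.ml_a == pytest.approx(0.9) and row.ml_b == pytest.approx(0.1)
    assert row.delta == pytest.approx(0.8)
    assert row.p < 1e-6
    assert row.status == "hyper_in_a"
    # heatmap row for this DMP
    matrix = mr.dmp_heatmap_matrix({"A": a, "B": b}, out, proms)
    np.testing.assert_allclose(matrix.loc["g"], [0.9, 0.1])


def test_fisher_p_matches_hypergeometric_tail_enumeration():
    """Two-sided Fisher p equals the sum of hypergeometric outcome
    probabilities no larger than the observed one."""
    cases = [(18, 30, 4, 25), (900, 1000, 100, 1000), (3, 40, 9, 35), (0, 12, 7, 15)]
    for ma, ta, mb, tb in cases:
        _, p = sps.fisher_exact([[ma, ta - ma], [mb, tb - mb]])
        n_meth, total = ma + mb, ta + tb
        pmf = sps.hypergeom(total, n_meth, ta).pmf(
            np.arange(max(0, n_meth - tb), min(ta, n_meth) + 1)
        )
        obs = sps.hypergeom(total, n_meth, ta).pmf(ma)
        oracle = pmf[pmf <= obs * (1 + 1e-9)].sum()
        assert p == pytest.approx(oracle, rel=1e-6)


def test_call_dmps_symmetric_in_sample_order(dmp_dataset):
    _, _, sperm, oocyte = dmp_dataset
    proms = _promoters([("g", "chr1", 0, 5000, "+"), ("h", "chr1", 5000, 10_000, "+")])
    ab = mr.call_dmps(sperm, oocyte, proms)
    ba = mr.call_dmps(oocyte, sperm, proms)
    np.testing.assert_allclose(ab.delta, -ba.delta)
    np.testing.assert_allclose(ab.p, ba.p)
    swap = {"hyper_in_a": "hypo_in_a", "hypo_in_a": "hyper_in_a", "ns": "ns"}
    assert ba.status.tolist() == [swap[s] for s in ab.status]


def test_call_dmps_requires_testable_promoters():
    t = _table([(5, 10)] * 5)
    proms = _promoters([("g", "chr9", 0, 100, "+")])
    with pytest.raises(ValueError, match="no promoter testable"):
        mr.call_dmps(t, t, proms)


def test_dmp_truth_recovery(dmp_dataset):
    """>= 95% recall at truth delta 0.85; observed FDR <= 5%."""
    _, truth, sperm, oocyte = dmp_dataset
    out = mr.call_dmps(sperm, oocyte, truth.annotation.promoters)
    called = set(out.loc[out.status != "ns", "gene_id"])
    designed = set(truth.designed_dmps.gene_id)
    recall = len(called & designed) / len(designed)
    fdr = len(called - designed) / max(len(called), 1)
    assert recall >= 0.95
    assert fdr <= 0.05
    # calls carry the designed direction
    hyper = set(out.loc[out.status == "hyper_in_a", "gene_id"])
    designed_hyper = set(
        truth.designed_dmps.loc[
            truth.designed_dmps.direction == "hyper_in_sperm", "gene_id"
        ]
    )
    assert designed_hyper <= hyper


def test_null_dmp_rate_controlled(dmp_dataset):
    spec, truth, _, _ = dmp_dataset
    a = mr.simulate_counts(truth, spec, "sperm", replicate=1)
    b = mr.simulate_counts(truth, spec, "sperm", replicate=2)
    out = mr.call_dmps(a, b, truth.annotation.promoters)
    assert (out.status != "ns").mean() <= 0.05


@pytest.mark.parametrize(
    "stages,expected_class,expected_flag",
    [
        ([("sperm", 0.10), ("oocyte", 0.10), ("blastula", 0.10)], "none", False),
        ([("sperm", 0.27), ("oocyte", 0.24)], "minor", False),
        (
            [("sperm", 0.80), ("oocyte", 0.80), ("icm", 0.24), ("e7.5", 0.70)],
            "dramatic",
            True,
        ),
    ],
)
def test_classify_dynamics_table_rows(stages, expected_class, expected_flag):
    out = mr.classify_dynamics(stages)
    assert out.dynamics_class == expected_class
    assert out.demethylation_flag is expected_flag


def test_classify_dynamics_single_stage_warns():
    with pytest.warns(UserWarning, match="fewer than 2 stages"):
        out = mr.classify_dynamics([("sperm", 0.5)])
    assert out.dynamics_class is None


def test_classify_dynamics_invariant_to_embryo_stage_names():
    a = mr.classify_dynamics([("sperm", 0.8), ("oocyte", 0.7), ("x", 0.2)])
    b = mr.classify_dynamics([("sperm", 0.8), ("oocyte", 0.7), ("morula", 0.2)])
    assert a.dynamics_class == b.dynamics_class
    assert a.demethylation_flag == b.demethylation_flag


@pytest.mark.parametrize(
    "fixture,expected_class,expected_flag",
    [
        ("anemone", "none", False),
        ("deutero", "minor", False),
        ("mammal", "dramatic", True),
    ],
)
def test_preset_trajectories_map_to_printed_labels(
    request, fixture, expected_class, expected_flag
):
    spec, _, tables = request.getfixturevalue(fixture)
    mls = [(s, mr.global_ml(tables[s]).site_mean) for s in spec.stages]
    out = mr.classify_dynamics(mls)
    assert out.dynamics_class == expected_class
    assert out.demethylation_flag is expected_flag


def test_heatmap_matrix_row_order_descending_delta(dmp_dataset):
    _, truth, sperm, oocyte = dmp_dataset
    out = mr.call_dmps(sperm, oocyte, truth.annotation.promoters)
    matrix = mr.dmp_heatmap_matrix(
        {"sperm": sperm, "oocyte": oocyte}, out, truth.annotation.promoters
    )
    deltas = out.set_index("gene_id").loc[matrix.index, "delta"]
    assert (np.diff(deltas) <= 1e-12).all()
    assert matrix.shape[1] == 2
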