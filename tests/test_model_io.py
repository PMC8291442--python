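"""Call-table model, dialect readers/writers and coordinate handling."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import methreprog as mr
from methreprog.io import ParseError


def test_cytosine_report_coordinate_shift(tmp_path):
    path = tmp_path / "r.txt"
    path.write_text("chr1\t10\t+\t3\t7\tCG\nchr1\t20\t+\t0\t0\tCG\n")
    table = mr.read_cytosine_report(path)
    assert table.df.iloc[0].tolist() == ["chr1", 9, "+", "CG", 3, 10]
    # zero-coverage record retained for later filtering
    assert table.df.iloc[1].tolist() == ["chr1", 19, "+", "CG", 0, 0]


def test_cytosine_report_roundtrip_identity(tmp_path, tiny_table):
    p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
    mr.write_cytosine_report(tiny_table, p1)
    again = mr.read_cytosine_report(p1, mr.SampleMeta("tiny"))
    pd.testing.assert_frame_equal(again.df, tiny_table.df)
    mr.write_cytosine_report(again, p2)
    assert p1.read_text() == p2.read_text()


def test_cytosine_report_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("chr1\t10\t+\t3\t7\tCG\nchr1\tXX\t+\t1\t1\tCG\n")
    with pytest.raises(ParseError, match="line 2"):
        mr.read_cytosine_report(path)


def test_cytosine_report_negative_counts_rejected(tmp_path):
    path = tmp_path / "neg.txt"
    path.write_text("chr1\t10\t+\t-3\t7\tCG\n")
    with pytest.raises(ParseError, match="negative"):
        mr.read_cytosine_report(path)


def test_bedgraph_counts_mapping_and_counts_win(tmp_path):
    path = tmp_path / "c.bedGraph"
    path.write_text("chr1\t9\t10\t30\t3\t7\nchr1\t19\t20\t100\t3\t7\n")
    with pytest.warns(UserWarning, match="counts win"):
        table = mr.read_bedgraph_counts(path)
    assert table.df.iloc[0].tolist() == ["chr1", 9, ".", "CG", 3, 10]
    assert table.ml.iloc[1] == pytest.approx(0.3)  # percent column ignored


def test_bedgraph_empty_file(tmp_path):
    path = tmp_path / "empty.bedGraph"
    path.write_text("")
    assert len(mr.read_bedgraph_counts(path)) == 0


def test_bedgraph_roundtrip(tmp_path):
    table = mr.MethylomeTable.from_records(
        [("chr1", 9, ".", "CG", 3, 10), ("chr2", 0, ".", "CG", 5, 5)]
    )
    path = tmp_path / "r.bedGraph"
    mr.write_bedgraph_counts(table, path)
    again = mr.read_bedgraph_counts(path)
    pd.testing.assert_frame_equal(again.df, table.df)


def test_table_invariants_enforced():
    with pytest.raises(ValueError, match="n_meth exceeds"):
        mr.MethylomeTable.from_records([("chr1", 1, "+", "CG", 5, 3)])
    with pytest.raises(ValueError, match="duplicate"):
        mr.MethylomeTable.from_records(
            [("chr1", 1, "+", "CG", 1, 3), ("chr1", 1, "+", "CG", 0, 2)]
        )
    with pytest.raises(ValueError, match="context"):
        mr.MethylomeTable.from_records([("chr1", 1, "+", "CHZ", 1, 3)])


def test_merge_cpg_dyads_pools_symmetric_counts(tiny_table):
    merged = mr.merge_cpg_dyads(tiny_table)
    row = merged.df[(merged.df.chrom == "chr1") & (merged.df.pos == 9)].iloc[0]
    assert (row.n_meth, row.n_total, row.strand) == (5, 20, "+")
    # dyad ML is the coverage-weighted mean of the strand MLs
    assert row.n_meth / row.n_total == pytest.approx((3 + 2) / (10 + 10))
    # lone sites and non-CG records unchanged
    assert len(merged.df[merged.df.pos == 149]) == 1
    assert (merged.df.context == "CHH").sum() == 1


counts = st.tuples(st.integers(0, 50), st.integers(0, 50)).map(
    lambda t: (min(t), max(t))
)


@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.booleans(), counts),
        min_size=0,
        max_size=25,
        unique_by=lambda r: (r[0], r[1]),
    )
)
def test_merge_conserves_counts(records):
    rows = [
        ("chr1", pos * 2 + int(minus), "-" if minus else "+", "CG", m, t)
        for pos, minus, (m, t) in records
    ]
    table = mr.MethylomeTable.from_records(rows)
    merged = mr.merge_cpg_dyads(table)
    assert merged.df.n_meth.sum() == table.df.n_meth.sum()
    assert merged.df.n_total.sum() == table.df.n_total.sum()
    merged.validate()


def test_filter_by_coverage_threshold_and_idempotence(tiny_table):
    f5 = mr.filter_by_coverage(tiny_table, 5)
    assert set(f5.df.n_total) == {10, 10, 30, 30}
    f1 = mr.filter_by_coverage(tiny_table, 1)
    assert len(f1) == len(tiny_table) - 1  # only the zero-coverage site drops
    pd.testing.assert_frame_equal(
        mr.filter_by_coverage(f5, 5).df, f5.df
    )


def _annotation(rows):
    genes = mr.add_tss(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    return mr.AnnotationSet(genes=genes)


@pytest.mark.parametrize(
    "start,end,strand,expected",
    [
        (5000, 7000, "+", (4000, 5500)),  # [tss-1000, tss+500)
        (3000, 5001, "-", (4500, 6000)),  # mirrored around tss = 5000
        (300, 2000, "+", (0, 800)),  # clipped at chromosome start
    ],
)
def test_make_promoters(start, end, strand, expected):
    ann = _annotation([("g", "chr1", start, end, strand)])
    ann = mr.make_promoters(ann, upstream=1000, downstream=500)
    prom = ann.promoters.iloc[0]
    assert (prom.start, prom.end) == expected


def test_make_promoters_requires_strand():
    genes = pd.DataFrame(
        [("g", "chr1", 0, 10, ".", 0)],
        columns=["gene_id", "chrom", "start", "end", "strand", "tss"],
    )
    with pytest.raises(ValueError, match="strand"):
        mr.make_promoters(mr.AnnotationSet(genes=genes))


def test_gene_set_resolution_checked():
    ann = _annotation([("g1", "chr1", 0, 100, "+")])
    ann.gene_sets["HOX"] = pd.DataFrame({"gene_id": ["missing"], "cluster": ["HOXA"]})
    with pytest.raises(ValueError, match="not in the annotation"):
        ann.validate()


def test_bed6_and_gene_sets_roundtrip(tmp_path):
    ann = _annotation([("g1", "chr1", 100, 900, "+"), ("g2", "chr2", 50, 500, "-")])
    bed = tmp_path / "genes.bed"
    mr.io.write_bed6_genes(ann.genes, bed)
    again = mr.read_bed6_genes(bed)
    pd.testing.assert_frame_equal(again, ann.genes)
    sets = {"HOX": pd.DataFrame({"gene_id": ["g1"], "cluster": ["HOXA"]})}
    path = tmp_path / "sets.tsv"
    mr.io.write_gene_sets(sets, path)
    again_sets = mr.read_gene_sets(path)
    pd.testing.assert_frame_equal(again_sets["HOX"], sets["HOX"])


def test_gff3_gene_reading(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t900\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t101\t900\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr2\tsrc\tgene\t51\t500\t.\t-\t.\tID=g2\n"
    )
    genes = mr.read_gff3_genes(gff)
    assert genes.gene_id.tolist() == ["g1", "g2"]
    assert genes.start.tolist() == [100, 50]  # converted to 0-based
    assert genes.tss.tolist() == [100, 499]
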