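"""Annotation/coverage I/O and gene-level quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucdis import (
    CoverageTrack,
    FormatError,
    GeneOccupancyTable,
    ValidationError,
    gene_level_occupancy,
    interval_mean,
    occupancy_change,
    read_coverage_bedgraph,
    read_gene_annotation,
    read_gene_table,
    write_gene_table,
)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def test_gff3_converts_to_zero_based_half_open(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=t1\n"
    )
    df = read_gene_annotation(p, format="gff3")
    assert len(df) == 1  # only feature_type 'gene' retained
    assert (df.loc[0, "start"], df.loc[0, "end"]) == (100, 200)


def test_bed_passes_through(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t100\t200\tgeneA\t0\t-\n")
    df = read_gene_annotation(p, format="bed")
    row = df.iloc[0]
    assert (row.gene_id, row.start, row.end, row.strand) == ("geneA", 100, 200, "-")


def test_empty_annotation_warns_and_returns_empty(tmp_path, caplog):
    p = tmp_path / "empty.gff3"
    p.write_text("##gff-version 3\n")
    with caplog.at_level("WARNING"):
        df = read_gene_annotation(p)
    assert df.empty
    assert any("no gene records" in m for m in caplog.messages)


def test_malformed_line_reports_line_number(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("chr1\tsrc\tgene\t101\n")
    with pytest.raises(FormatError, match=":1:"):
        read_gene_annotation(p)


def test_duplicate_gene_id_rejected(tmp_path):
    p = tmp_path / "dup.bed"
    p.write_text("chr1\t0\t10\tg\t0\t+\nchr1\t20\t30\tg\t0\t+\n")
    with pytest.raises(ValidationError, match="duplicate"):
        read_gene_annotation(p, format="bed")


# ---------------------------------------------------------------------------
# bedGraph rasterization
# ---------------------------------------------------------------------------

def test_uniform_record_fills_bins(tmp_path):
    p = tmp_path / "x.bedgraph"
    p.write_text("chr1\t0\t100\t5\n")
    track = read_coverage_bedgraph(p, {"chr1": 100}, step_bp=10)
    np.testing.assert_array_equal(track.data["chr1"], np.full(10, 5.0))


def test_length_weighted_bin_averaging(tmp_path):
    # [0,15)=2 then [15,20)=4 at step 10: bin0 = 2, bin1 = (2*5 + 4*5)/10 = 3
    p = tmp_path / "x.bedgraph"
    p.write_text("chr1\t0\t15\t2\nchr1\t15\t20\t4\n")
    track = read_coverage_bedgraph(p, {"chr1": 20}, step_bp=10)
    np.testing.assert_allclose(track.data["chr1"], [2.0, 3.0])


def test_empty_bedgraph_gives_zero_track(tmp_path):
    p = tmp_path / "x.bedgraph"
    p.write_text("")
    track = read_coverage_bedgraph(p, {"chr1": 50}, step_bp=10)
    np.testing.assert_array_equal(track.data["chr1"], np.zeros(5))


def test_interval_beyond_chromosome_rejected(tmp_path):
    p = tmp_path / "x.bedgraph"
    p.write_text("chr1\t90\t120\t1\n")
    with pytest.raises(ValidationError, match="outside chromosome"):
        read_coverage_bedgraph(p, {"chr1": 100}, step_bp=10)


def test_overlapping_intervals_rejected(tmp_path):
    p = tmp_path / "x.bedgraph"
    p.write_text("chr1\t0\t20\t1\nchr1\t10\t30\t2\n")
    with pytest.raises(ValidationError, match="overlapping"):
        read_coverage_bedgraph(p, {"chr1": 100}, step_bp=10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_rasterization_conserves_mass(tmp_path_factory, data):
    """sum(bin * step) equals sum(value * interval length) for any bedGraph."""
    n = data.draw(st.integers(1, 8))
    bounds = sorted(data.draw(
        st.lists(st.integers(0, 200), min_size=2 * n, max_size=2 * n, unique=True)
    ))
    values = data.draw(st.lists(
        st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n
    ))
    step = data.draw(st.sampled_from([1, 3, 7, 10]))
    lines, mass = [], 0.0
    for i in range(n):
        a, b = bounds[2 * i], bounds[2 * i + 1]
        lines.append(f"chr1\t{a}\t{b}\t{values[i]!r}\n")
        mass += values[i] * (b - a)
    p = tmp_path_factory.mktemp("bg") / "x.bedgraph"
    p.write_text("".join(lines))
    track = read_coverage_bedgraph(p, {"chr1": 200}, step_bp=step)
    assert track.data["chr1"].sum() * step == pytest.approx(mass, abs=1e-6)


# ---------------------------------------------------------------------------
# interval_mean and quantification
# ---------------------------------------------------------------------------

def test_interval_mean_fractional_bins():
    values = np.array([2.0, 4.0])
    assert interval_mean(values, 10, 5, 15) == pytest.approx(3.0)
    assert interval_mean(values, 10, 0, 20) == pytest.approx(3.0)
    assert interval_mean(values, 10, 12, 14) == pytest.approx(4.0)


def test_interval_mean_out_of_bounds_policies():
    values = np.array([6.0])
    with pytest.raises(ValidationError):
        interval_mean(values, 10, -10, 10)
    # zero policy: missing half contributes 0
    assert interval_mean(values, 10, -10, 10, oob="zero") == pytest.approx(3.0)
    assert np.isnan(interval_mean(values, 10, -10, 10, oob="nan"))


def test_flat_four_vs_one_gives_two(flat_tracks, simple_genes):
    ip, control = flat_tracks
    table, excl = gene_level_occupancy(ip, control, simple_genes, pseudocount=0.0)
    assert excl.empty
    np.testing.assert_allclose(table.values["occupancy"], 2.0)
    assert table.tags["occupancy"] == "log2_ip_over_input"


def test_identical_tracks_give_zero(flat_tracks, simple_genes):
    ip, _ = flat_tracks
    table, _ = gene_level_occupancy(ip, ip, simple_genes, pseudocount=0.0)
    np.testing.assert_allclose(table.values["occupancy"], 0.0)


def test_pseudocount_arithmetic(simple_genes):
    ip = CoverageTrack(10, {"chr1": np.full(100, 3.0)})
    control = CoverageTrack(10, {"chr1": np.full(100, 2.0)})
    table, _ = gene_level_occupancy(ip, control, simple_genes, pseudocount=0.01)
    np.testing.assert_allclose(table.values["occupancy"], np.log2(3.01 / 2.01))


def test_scale_invariance_without_pseudocount(simple_genes):
    rng = np.random.default_rng(0)
    base = rng.uniform(0.5, 4.0, 100)
    ctrl = rng.uniform(0.5, 2.0, 100)
    t1, _ = gene_level_occupancy(
        CoverageTrack(10, {"chr1": base}), CoverageTrack(10, {"chr1": ctrl}),
        simple_genes, pseudocount=0.0,
    )
    t2, _ = gene_level_occupancy(
        CoverageTrack(10, {"chr1": 7.3 * base}), CoverageTrack(10, {"chr1": 7.3 * ctrl}),
        simple_genes, pseudocount=0.0,
    )
    np.testing.assert_allclose(t1.values["occupancy"], t2.values["occupancy"], rtol=1e-10)


def test_zero_control_and_out_of_extent_excluded(simple_genes):
    ip = CoverageTrack(10, {"chr1": np.full(100, 4.0)})
    control = CoverageTrack(
        10, {"chr1": np.concatenate([np.zeros(40), np.ones(60)])}
    )
    genes = pd.concat(
        [simple_genes, pd.DataFrame([{
            "gene_id": "geneC", "chrom": "chr1", "start": 950, "end": 1200, "strand": "+",
        }])],
        ignore_index=True,
    )
    table, excl = gene_level_occupancy(ip, control, genes)
    assert set(excl["gene_id"]) == {"geneA", "geneC"}  # geneA: control 0; geneC: off end
    assert list(table.values.index) == ["geneB"]
    reasons = dict(zip(excl["gene_id"], excl["reason"]))
    assert "zero control" in reasons["geneA"]
    assert "extent" in reasons["geneC"]


def test_occupancy_change_is_difference():
    wt = pd.Series({"a": 1.0, "b": 2.0, "c": 0.5})
    mut = pd.Series({"a": 3.0, "b": 2.0, "c": -0.25})
    change = occupancy_change(mut, wt)
    assert change["a"] == 2.0 and change["b"] == 0.0 and change["c"] == -0.75
    np.testing.assert_array_equal(occupancy_change(wt, wt), 0.0)
    with pytest.raises(ValidationError):
        occupancy_change(pd.Series({"x": 1.0}), wt)


# ---------------------------------------------------------------------------
# gene table round-trip
# ---------------------------------------------------------------------------

def test_gene_table_round_trip_with_nan(tmp_path):
    df = pd.DataFrame(
        {"s1": [0.123456789012345, np.nan, -3.5], "s2": [1e-17, 2.0, 0.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    table = GeneOccupancyTable(df, tags={"s1": "log2_mutant_over_wt", "s2": "linear"})
    path = tmp_path / "t.tsv"
    write_gene_table(table, path)
    back = read_gene_table(path)
    pd.testing.assert_frame_equal(back.values, table.values)
    assert back.tags == table.tags


def test_gene_table_requires_gene_id_column(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("foo\ts1\ng1\t1.0\n")
    with pytest.raises(FormatError, match="gene_id"):
        read_gene_table(p)
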