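"""VCF ingestion, the genotype domain model, and matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tests.conftest import make_record
from varprov.model import (
    GenotypeCall,
    StudyDesign,
    VariantRecord,
    VcfParseError,
    build_matrix,
    default_design,
    key_str,
    parse_key,
    read_vcf,
    records_equal,
    write_vcf,
)
from varprov.simulate import SimConfig, simulate_study

HEADER = """##fileformat=VCFv4.2
##contig=<ID=Chr01,length=1000000>
##contig=<ID=Chr02,length=1000000>
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
"""


def write_text_vcf(tmp_path, body, name="t.vcf"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestReadVcf:
    def test_header_only_yields_no_records_and_samples(self, tmp_path):
        records, samples = read_vcf(write_text_vcf(tmp_path, ""))
        assert records == []
        assert samples == ["s1", "s2", "s3", "s4"]

    def test_gt_category_mapping(self, tmp_path):
        body = "Chr01\t100\t.\tA\tG\t50\t.\tFS=1.5;QD=20\tGT:DP\t0/0:10\t0/1:3\t1/1:7\t./.:.\n"
        records, _ = read_vcf(write_text_vcf(tmp_path, body))
        (r,) = records
        assert list(r.calls) == [
            GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT, GenotypeCall.MISSING,
        ]
        assert list(r.depths) == [10, 3, 7, -1]
        assert (r.fs, r.qd, r.qual) == (1.5, 20.0, 50.0)

    def test_phased_separator_treated_as_unphased(self, tmp_path):
        body = "Chr01\t100\t.\tA\tG\t50\t.\t.\tGT\t0|1\t1|1\t0|0\t.|.\n"
        records, _ = read_vcf(write_text_vcf(tmp_path, body))
        assert list(records[0].calls) == [1, 2, 0, -1]

    def test_multiallelic_site_split_per_alt(self, tmp_path):
        body = "Chr01\t100\t.\tA\tG,T\t50\t.\t.\tGT\t0/1\t2/2\t1/2\t0/0\n"
        records, _ = read_vcf(write_text_vcf(tmp_path, body))
        assert [r.alt for r in records] == ["G", "T"]
        # genotypes referencing the other alternate become MISSING
        assert list(records[0].calls) == [1, -1, -1, 0]
        assert list(records[1].calls) == [-1, 2, -1, 0]

    def test_absent_annotations_stored_as_none_not_zero(self, tmp_path):
        body = "Chr01\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n"
        records, _ = read_vcf(write_text_vcf(tmp_path, body))
        assert records[0].qual is None
        assert records[0].fs is None
        assert records[0].qd is None

    def test_non_diploid_genotype_names_the_sample(self, tmp_path):
        body = "Chr01\t100\t.\tA\tG\t50\t.\t.\tGT\t0/0\t0/1/1\t0/0\t0/0\n"
        with pytest.raises(VcfParseError, match="s2"):
            read_vcf(write_text_vcf(tmp_path, body))

    def test_malformed_record_names_the_line(self, tmp_path):
        body = "Chr01\tnot_a_position\t.\tA\tG\t50\t.\t.\tGT\t0/0\t0/0\t0/0\t0/0\n"
        with pytest.raises(VcfParseError, match="line"):
            read_vcf(write_text_vcf(tmp_path, body))


class TestVariantRecord:
    def test_rejects_equal_alleles(self):
        with pytest.raises(ValueError, match="not a variant"):
            make_record(ref="A", alt="A")

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError, match="position"):
            make_record(pos=0)

    def test_key_string_round_trips(self):
        r = make_record(chrom="Chr07", pos=1234, ref="AT", alt="A")
        assert parse_key(key_str(r.key)) == r.key


class TestWriteVcf:
    def test_empty_records_give_header_only_file(self, tmp_path):
        path = write_vcf([], ["a", "b"], tmp_path / "e.vcf")
        records, samples = read_vcf(path)
        assert records == [] and samples == ["a", "b"]

    def test_missing_call_emitted_as_dot_slash_dot(self, tmp_path):
        r = make_record(calls=[-1, 0])
        path = write_vcf([r], ["a", "b"], tmp_path / "m.vcf")
        assert "./." in path.read_text()

    def test_simulated_study_round_trips(self, tmp_path):
        cfg = SimConfig(seed=7, fp_per_sample=2, panel_positions=60,
                        panel_accessions=5, n_expressed_panel_positions=30,
                        n_cluster_variants=10)
        records, design, _panel, _truth = simulate_study(cfg)
        assert len(records) >= 50
        path = write_vcf(records, design.samples, tmp_path / "rt.vcf")
        back, samples = read_vcf(path)
        assert samples == design.samples
        assert len(back) == len(records)
        assert all(records_equal(a, b) for a, b in zip(records, back))


@st.composite
def record_lists(draw):
    n = draw(st.integers(1, 25))
    positions = draw(
        st.lists(st.tuples(st.sampled_from(["Chr01", "Chr02"]), st.integers(1, 10_000)),
                 min_size=n, max_size=n, unique=True)
    )
    positions.sort()
    records = []
    for chrom, pos in positions:
        ref, alt = draw(st.sampled_from([("A", "G"), ("C", "T"), ("A", "AT"), ("GCA", "G")]))
        calls = draw(st.lists(st.sampled_from([-1, 0, 1, 2]), min_size=3, max_size=3))
        depths = draw(st.lists(st.integers(-1, 100), min_size=3, max_size=3))
        qual = draw(st.one_of(st.none(), st.integers(0, 5000).map(lambda q: q / 10)))
        fs = draw(st.one_of(st.none(), st.integers(0, 3000).map(lambda q: q / 10)))
        qd = draw(st.one_of(st.none(), st.integers(0, 400).map(lambda q: q / 10)))
        records.append(
            VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                          fs=fs, qd=qd,
                          calls=np.array(calls, dtype=np.int8),
                          depths=np.array(depths, dtype=np.int32),
                          filter_flags=set(draw(st.sets(st.sampled_from(["FS", "QD"])))))
        )
    return records


@settings(max_examples=40, derandomize=True, deadline=None)
@given(record_lists())
def test_write_then_read_is_identity(tmp_path_factory, records):
    """read_vcf(write_vcf(x)) == x for any valid domain-model input."""
    path = tmp_path_factory.mktemp("rt") / "x.vcf"
    write_vcf(records, ["sA", "sB", "sC"], path)
    back, samples = read_vcf(path)
    assert samples == ["sA", "sB", "sC"]
    assert len(back) == len(records)
    assert all(records_equal(a, b) for a, b in zip(records, back))


class TestStudyDesign:
    def test_default_layout_is_4_groups_of_3x3(self):
        design = default_design()
        assert len(design.groups) == 4
        for g in design.groups:
            assert len(design.samples_in_group(g)) == 9
        assert len(design.samples) == 36
        assert len(design.families()) == 12

    def test_tsv_round_trip(self, tmp_path):
        design = default_design()
        path = design.to_tsv(tmp_path / "d.tsv")
        assert StudyDesign.from_tsv(path) == design

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            StudyDesign(groups=("a",), sample_map={"s": ("b", "f", "r")})


class TestBuildMatrix:
    def test_dimensions_and_sorted_variant_order(self):
        design = default_design()
        records = [
            make_record(chrom="Chr02", pos=5, calls=[0] * 36),
            make_record(chrom="Chr01", pos=9, calls=[1] * 36),
            make_record(chrom="Chr01", pos=2, calls=[2] * 36),
        ]
        m = build_matrix(records, design)
        assert m.shape == (3, 36)
        assert [v[:2] for v in m.variants] == [("Chr01", 2), ("Chr01", 9), ("Chr02", 5)]

    def test_extra_non_design_sample_dropped(self):
        design = default_design()
        samples = design.samples + ["stray"]
        records = [make_record(calls=[1] * 37)]
        m = build_matrix(records, design, samples=samples)
        assert m.shape == (1, 36)
        assert "stray" not in m.samples

    def test_design_sample_absent_from_vcf_is_an_error(self):
        design = default_design()
        records = [make_record(calls=[0] * 35)]
        with pytest.raises(ValueError, match="absent"):
            build_matrix(records, design, samples=design.samples[:-1])

    def test_matrix_matches_simulated_dimensions(self, small_study):
        records, design, _panel, truth = small_study
        m = build_matrix(records, design)
        assert m.shape == (len(records), 36)
        truth_keys = truth.all_planted_true() | truth.all_fp()
        assert set(m.variants) == truth_keys

    def test_genotype_counts_invariant_under_sample_reordering(self):
        design = default_design()
        rng = np.random.default_rng(3)
        records = [
            make_record(pos=p, calls=rng.integers(-1, 3, size=36))
            for p in range(1, 30)
        ]
        m = build_matrix(records, design)
        perm = rng.permutation(36)
        shuffled_samples = [design.samples[i] for i in perm]
        records2 = [
            make_record(pos=r.pos, calls=r.calls[perm], depths=r.depths[perm])
            for r in records
        ]
        m2 = build_matrix(records2, design, samples=shuffled_samples)
        for code in (-1, 0, 1, 2):
            assert np.sum(m.calls == code) == np.sum(m2.calls == code)
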