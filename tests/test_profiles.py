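import pytest
from hypothesis import given, settings, strategies as st

from ctdna_tmi.profiles import (
    BurdenSummary,
    MutationKey,
    MutationRecord,
    ParseError,
    SampleProfile,
    apply_call_filters,
    compute_burdens,
    read_mutation_table,
    write_mutation_table,
)

PANEL = ("TP53", "EGFR", "ARID1A", "BRCA2", "TGFBR2", "IDH1", "KRAS")


class TestMutationKey:
    def test_parses_printed_style_with_grouping_spaces(self):
        key = MutationKey.parse("chr 1: 26 779 439:TG/T")
        assert key == MutationKey("chr1", 26779439, "TG", "T")

    def test_compact_roundtrip(self):
        key = MutationKey("chr13", 32379885, "C", "CA")
        assert MutationKey.parse(str(key)) == key

    @pytest.mark.parametrize(
        "kwargs",
        [dict(chrom="chr1", pos=0, ref="A", alt="T"),
         dict(chrom="chr1", pos=5, ref="A", alt="A")],
    )
    def test_invalid_keys_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MutationKey(**kwargs)

    def test_unparseable_text_raises(self):
        with pytest.raises(ParseError):
            MutationKey.parse("not a mutation")


def _rec(pos, gene="TP53", effect="HIGH", syn=False, depth=500, vaf=0.08,
         ref="A", alt="T"):
    return ("chr1", pos, ref, alt, gene, effect, syn, depth, vaf)


class TestFilters:
    def test_depth_below_minimum_drops_from_all_sets(self, tmp_path):
        prof = SampleProfile("P1", "BL")
        prof.add(MutationRecord(MutationKey("chr1", 10, "A", "T"), "TP53",
                                "HIGH", False, 99, 0.1))
        res = apply_call_filters(prof, panel=PANEL)
        assert not res.gs_keys and not res.somatic_keys

    def test_high_vaf_counts_germline_side_of_gs(self):
        from tests.conftest import make_profile

        prof = make_profile(records=[_rec(10, vaf=0.5, effect="HIGH")])
        res = apply_call_filters(prof, panel=PANEL)
        key = MutationKey("chr1", 10, "A", "T")
        assert key in res.gs_keys
        assert key not in res.somatic_keys
        assert res.origins[key] == "germline"

    def test_low_effect_excluded_from_somatic_but_counted_in_gs(self):
        from tests.conftest import make_profile

        prof = make_profile(records=[_rec(10, effect="LOW", vaf=0.05)])
        res = apply_call_filters(prof, panel=PANEL)
        assert compute_burdens(res) == BurdenSummary(gs_mb=1, ns_mb=0)

    def test_off_panel_gene_dropped(self):
        from tests.conftest import make_profile

        prof = make_profile(records=[_rec(10, gene="NOT_A_GENE")])
        res = apply_call_filters(prof, panel=PANEL)
        assert not res.gs_keys

    def test_empty_profile_is_valid(self):
        res = apply_call_filters(SampleProfile("P1", "BL"), panel=PANEL)
        assert compute_burdens(res) == BurdenSummary(0, 0)

    def test_hand_counted_burdens(self):
        """10 retained records: 3 germline-like (VAF>0.2), 2 LOW-effect
        somatic, 5 MODERATE/HIGH somatic -> G+S 10, N+S 5."""
        from tests.conftest import make_profile

        records = (
            [_rec(i, vaf=0.45, effect="HIGH") for i in (1, 2, 3)]
            + [_rec(i, vaf=0.05, effect="LOW") for i in (4, 5)]
            + [_rec(i, vaf=0.08, effect="MODERATE") for i in (6, 7)]
            + [_rec(i, vaf=0.08, effect="HIGH") for i in (8, 9, 10)]
        )
        res = apply_call_filters(make_profile(records=records), panel=PANEL)
        assert compute_burdens(res) == BurdenSummary(gs_mb=10, ns_mb=5)

    def test_filter_idempotence(self):
        from tests.conftest import make_profile

        records = [
            _rec(1, vaf=0.45), _rec(2, vaf=0.05, effect="LOW"),
            _rec(3, vaf=0.08), _rec(4, depth=50), _rec(5, gene="NOT_A_GENE"),
        ]
        once = apply_call_filters(make_profile(records=records), panel=PANEL)
        twice = apply_call_filters(once.filtered, panel=PANEL)
        assert twice.gs_keys == once.gs_keys
        assert twice.somatic_keys == once.somatic_keys
        assert twice.nonsyn_high_keys == once.nonsyn_high_keys


record_strategy = st.tuples(
    st.integers(1, 30),
    st.sampled_from(PANEL + ("OFFPANEL1", "OFFPANEL2")),
    st.sampled_from(["MODIFIER", "LOW", "MODERATE", "HIGH"]),
    st.booleans(),
    st.integers(0, 600),
    st.floats(0.0, 1.0),
)


class TestFilterProperties:
    @given(st.lists(record_strategy, max_size=25, unique_by=lambda r: r[0]))
    @settings(max_examples=60, deadline=None)
    def test_burden_ordering_and_monotonicity(self, rows):
        from tests.conftest import make_profile

        records = [("chr1", pos, "A", "T", gene, eff, syn, depth, vaf)
                   for pos, gene, eff, syn, depth, vaf in rows]
        prof = make_profile(records=records)
        full = compute_burdens(apply_call_filters(prof, panel=PANEL))
        assert 0 <= full.ns_mb <= full.gs_mb
        deeper = compute_burdens(
            apply_call_filters(prof, min_depth=300, panel=PANEL)
        )
        assert deeper.gs_mb <= full.gs_mb and deeper.ns_mb <= full.ns_mb
        narrower = compute_burdens(apply_call_filters(prof, panel=PANEL[:2]))
        assert narrower.gs_mb <= full.gs_mb and narrower.ns_mb <= full.ns_mb


class TestTableIO:
    def test_roundtrip(self, tmp_path):
        from tests.conftest import make_profile

        profiles = {
            "P1_BL": make_profile("P1", "BL", [_rec(10), _rec(20, vaf=0.4)]),
            "P1_PD": make_profile("P1", "PD", [_rec(10)]),
            "P2_BL": make_profile("P2", "BL", []),
        }
        path = tmp_path / "m.tsv"
        write_mutation_table(profiles, path)
        back = read_mutation_table(path)
        assert set(back) == set(profiles)
        for sid in profiles:
            assert back[sid].records == profiles[sid].records

    def test_zero_depth_cell_means_absent(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect_class\tsynonymous\tP1_BL\tP2_BL\n"
            "chr1\t10\tA\tT\tTP53\tHIGH\t0\t500:0.100000\t0:0.0\n"
        )
        prof = read_mutation_table(path)
        assert len(prof["P1_BL"]) == 1
        assert len(prof["P2_BL"]) == 0

    def test_grouping_spaces_in_pos_column(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect_class\tsynonymous\tP1_BL\n"
            "chr1\t26 779 439\tTG\tT\tARID1A\tHIGH\t0\t500:0.100000\n"
        )
        prof = read_mutation_table(path)
        assert MutationKey("chr1", 26779439, "TG", "T") in prof["P1_BL"].records

    @pytest.mark.parametrize(
        "row,message",
        [
            ("chr1\t10\tA\tT\tTP53\tHIGH\t0\tbadcell", "malformed cell"),
            ("chr1\t10\tA\tT\tTP53\tWEIRD\t0\t500:0.1", "effect_class"),
        ],
    )
    def test_malformed_rows_raise_named_errors(self, tmp_path, row, message):
        path = tmp_path / "m.tsv"
        header = "chrom\tpos\tref\talt\tgene\teffect_class\tsynonymous\tP1_BL\n"
        path.write_text(header + row + "\n")
        with pytest.raises(ParseError, match=message):
            read_mutation_table(path)

    def test_duplicate_mutation_row_raises(self, tmp_path):
        path = tmp_path / "m.tsv"
        row = "chr1\t10\tA\tT\tTP53\tHIGH\t0\t500:0.1\n"
        path.write_text(
            "chrom\tpos\tref\talt\tgene\teffect_class\tsynonymous\tP1_BL\n"
            + row + row
        )
        with pytest.raises(ParseError, match="duplicate"):
            read_mutation_table(path)


MINIMAL_VCF = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Predicted effect class">
##INFO=<ID=SYN,Number=0,Type=Flag,Description="Synonymous">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1_BL\tP2_BL
chr1\t26779439\t.\tTG\tT\t.\t.\tGENE=ARID1A;EFFECT=HIGH\tDP:AF\t500:0.08\t.:.
chr2\t100\t.\tA\tT\t.\t.\tGENE=TP53;EFFECT=MODERATE;SYN\tDP:AF\t200:0.45\t150:0.05
"""


class TestVCFImport:
    def test_minimal_vcf_maps_to_profiles(self, tmp_path):
        from ctdna_tmi.profiles import read_vcf

        path = tmp_path / "calls.vcf"
        path.write_text(MINIMAL_VCF)
        profiles = read_vcf(path)
        assert set(profiles) == {"P1_BL", "P2_BL"}
        rec = profiles["P1_BL"].records[MutationKey("chr1", 26779439, "TG", "T")]
        assert rec.gene == "ARID1A" and rec.effect_class == "HIGH"
        assert rec.depth == 500 and rec.vaf == pytest.approx(0.08)
        # missing genotype (./.) in P2 produces no record at that site
        assert MutationKey("chr1", 26779439, "TG", "T") not in \
            profiles["P2_BL"].records
        syn = profiles["P2_BL"].records[MutationKey("chr2", 100, "A", "T")]
        assert syn.synonymous and syn.effect_class == "MODERATE"

    def test_vcf_missing_annotation_rejected(self, tmp_path):
        from ctdna_tmi.profiles import read_vcf

        bad = MINIMAL_VCF.replace("GENE=ARID1A;", "")
        path = tmp_path / "bad.vcf"
        path.write_text(bad)
        with pytest.raises(ParseError, match="GENE"):
            read_vcf(path)
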