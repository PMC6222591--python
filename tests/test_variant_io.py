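"""Pileup tokenizing, VCF/TSV/panel round trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.variant_io import (
    PileupParseError,
    PanelParseError,
    SitePanel,
    VariantSet,
    make_variant,
    parse_pileup_line,
    read_pileup,
    read_site_panel,
    read_variants_tsv,
    read_vcf,
    write_site_panel,
    write_variants_tsv,
    write_vcf,
)

from .conftest import pileup_line, q


class TestPileupTokenizer:
    @pytest.mark.parametrize(
        "bases,quals,n_symbols,n_indels",
        [
            (",,AaAA.a", "IIIIIIII", 8, 0),          # plain symbols
            (".^I,$T", "IIJ", 3, 0),                  # read start/end markers
            (".+2TT,", "II", 2, 1),                   # attached insertion
            (".-3AAA,", "II", 2, 1),                  # attached deletion
            ("*.,", "III", 3, 0),                     # deletion placeholder
            ("^].+12ACGTACGTACGT,", "II", 2, 1),      # multi-digit indel length
        ],
    )
    def test_scorable_symbols_align_with_qualities(
        self, bases, quals, n_symbols, n_indels
    ):
        rec = parse_pileup_line(pileup_line("chr1", 100, "G", bases, quals), 1)
        symbols, indels = rec.tokenize()
        assert len(symbols) == n_symbols == len(quals)
        assert len(indels) == n_indels

    def test_read_end_and_start_strip_correct_symbols(self):
        rec = parse_pileup_line(pileup_line("chr1", 101, "C", ".^I,$T", "IIJ"), 1)
        symbols, _ = rec.tokenize()
        assert symbols == [".", ",", "T"]

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\tG\t2\t..\tI",          # quals/bases mismatch
            "chr1\t100\tG\t1\t.\t",            # missing column content
            "chr1\t0\tG\t1\t.\tI",             # position < 1
            "chr1\t100\tG\t1\t%\tI",           # illegal symbol
            "chr1\t100\tG\t1\t.+A\tI",         # indel without length
            "chr1\tx\tG\t1\t.\tI",             # non-integer position
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, line):
        with pytest.raises(PileupParseError, match="line 7|chr1"):
            parse_pileup_line(line, 7)

    def test_read_pileup_streams_in_file_order(self, tmp_path):
        p = tmp_path / "x.pileup"
        p.write_text(
            pileup_line("chr1", 100, "G", ",,AaAA.a", "IIIIIIII") + "\n"
            + pileup_line("chr1", 102, "A", ".+2TT,", "II") + "\n"
        )
        recs = list(read_pileup(p))
        assert [r.pos for r in recs] == [100, 102]
        assert recs[0].depth == 8

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(list(".,*ACGTNacgtn")),
                st.integers(2, 40),
                st.booleans(),  # prepend ^X
                st.booleans(),  # append $
                st.one_of(
                    st.none(),
                    st.tuples(st.sampled_from("+-"), st.text("ACGT", min_size=1,
                                                             max_size=12)),
                ),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_generated_lines_always_balance_symbols_and_quals(self, tokens):
        bases, quals = "", ""
        for sym, qual, start, end, indel in tokens:
            if start:
                bases += "^I"
            bases += sym
            if indel is not None:
                sign, seq = indel
                bases += f"{sign}{len(seq)}{seq}"
            if end:
                bases += "$"
            quals += chr(qual + 33)
        rec = parse_pileup_line(pileup_line("c", 5, "G", bases, quals), 1)
        symbols, _ = rec.tokenize()
        assert len(symbols) == len(quals)


class TestVcf:
    def _write(self, tmp_path, body, fmt="GT:DP:AD"):
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">\n'
            '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="f">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tpool\n"
        )
        p = tmp_path / "t.vcf"
        p.write_text(header + body)
        return p

    def test_snv_record_parsed_with_allele_depth_frequency(self, tmp_path):
        p = self._write(
            tmp_path, "1\t12172055\t.\tC\tT\t.\tPASS\t.\tGT:DP:AD\t1/1:30:1,29\n"
        )
        vs = read_vcf(p)
        rec = vs.get(("1", 12172055, "C", "T"))
        assert rec is not None and not rec.is_indel
        assert rec.total_qdepth == 30 and rec.alt_count == 29
        assert rec.freq == pytest.approx(29 / 30)

    def test_multiallelic_record_split_per_alt(self, tmp_path):
        p = self._write(
            tmp_path, "1\t500\t.\tG\tA,T\t.\tPASS\t.\tGT:DP:AD\t1/2:40:2,30,8\n"
        )
        vs = read_vcf(p)
        assert ("1", 500, "G", "A") in vs and ("1", 500, "G", "T") in vs
        assert vs.get(("1", 500, "G", "A")).alt_count == 30
        assert vs.get(("1", 500, "G", "T")).alt_count == 8

    def test_identity_alt_rejected_and_counted(self, tmp_path):
        p = self._write(
            tmp_path, "1\t600\t.\tA\tA\t.\tPASS\t.\tGT:DP:AD\t1/1:10:0,10\n"
        )
        vs = read_vcf(p)
        assert len(vs) == 0 and vs.n_skipped == 1

    def test_deletion_length_arithmetic(self, tmp_path):
        p = self._write(
            tmp_path,
            "1\t700\t.\tACCTGACCTGACCTGA\tA\t.\tPASS\t.\tGT:DP:AD\t1/1:20:1,19\n",
        )
        rec = vs_rec = next(iter(read_vcf(p)))
        assert rec.is_indel and rec.indel_len == -15

    def test_varscan_freq_fallback_when_no_ad(self, tmp_path):
        p = self._write(
            tmp_path, "1\t800\t.\tG\tA\t.\tPASS\t.\tGT:DP:FREQ\t1/1:20:100%\n"
        )
        rec = next(iter(read_vcf(p)))
        assert rec.total_qdepth == 20 and rec.alt_count == 20
        assert rec.zygosity == "homozygous"

    def test_record_without_depths_skipped_with_count(self, tmp_path):
        p = self._write(tmp_path, "1\t900\t.\tG\tA\t.\tPASS\t.\tGT\t1/1\n")
        vs = read_vcf(p)
        assert len(vs) == 0 and vs.n_skipped == 1

    def test_vcf_round_trip_preserves_keys(self, tmp_path):
        vs = VariantSet(
            [
                make_variant("1", 100, "G", "A", 30, 30),
                make_variant("1", 200, "C", "T", 25, 13),
                make_variant("2", 50, "ACCT", "A", 20, 20),
            ]
        )
        path = tmp_path / "rt.vcf"
        write_vcf(vs, path)
        assert read_vcf(path) == vs


class TestSitePanel:
    def test_duplicates_collapse(self, tmp_path):
        p = tmp_path / "p.tsv"
        p.write_text("1\t47570165\tG\tA\n1\t10\tC\tT\n1\t47570165\tG\tA\n")
        panel = read_site_panel(p, "hapmap")
        assert len(panel) == 2
        assert ("1", 47570165, "G", "A") in panel

    def test_empty_file_gives_empty_panel(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert len(read_site_panel(p, "x")) == 0

    def test_header_row_tolerated_but_bad_positions_raise(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("chrom\tpos\tref\talt\n1\t5\tG\tA\n")
        assert len(read_site_panel(p, "x")) == 1
        p.write_text("1\t5\tG\tA\n1\tBAD\tC\tT\n")
        with pytest.raises(PanelParseError):
            read_site_panel(p, "x")

    def test_panel_round_trip(self, tmp_path):
        panel = SitePanel("p", {("1", 5, "G", "A"), ("2", 9, "C", "T")})
        path = tmp_path / "p.tsv"
        write_site_panel(panel, path)
        assert read_site_panel(path, "p").keys == panel.keys


def test_variants_tsv_round_trip(tmp_path):
    vs = VariantSet(
        [
            make_variant("chr1", 100, "G", "A", 30, 30),
            make_variant("chr1", 200, "C", "T", 40, 21),
            make_variant("chr2", 5, "A", "ATTTTTTTTTTTTTTTT", 12, 12),
        ]
    )
    path = tmp_path / "v.tsv"
    write_variants_tsv(vs, path)
    back = read_variants_tsv(path)
    assert back == vs
    rec = back.get(("chr2", 5, "A", "ATTTTTTTTTTTTTTTT"))
    assert rec.is_indel and rec.indel_len == 16
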