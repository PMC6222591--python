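"""Shared fixtures: constructed pileup lines, gene models, filter fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from bsamap.effects import GeneModel
from bsamap.variant_io import VariantSet, make_variant


def pileup_line(chrom, pos, ref, bases, quals):
    depth = len(quals)
    return f"{chrom}\t{pos}\t{ref}\t{depth}\t{bases}\t{quals}"


def q(phred: int, n: int = 1) -> str:
    return chr(phred + 33) * n


def build_filter_fixture():
    """Twelve pileup lines covering every filtering rule, with the
    designed survivor sets for mapping and candidate (EMS-only) purposes.

    Rules covered: quality-adjusted depth 7 vs 8, base quality 19 vs 20,
    frequency 0.98 vs 0.99, mapping depth cap 100 vs 101, EMS vs non-EMS
    changes, heterozygous vs homozygous calls.
    """
    lines = [
        # 1: depth 7 after quality (two ref bases at Q19 do not count)
        pileup_line("c", 1, "G", "AAAAAAA..", q(40, 7) + q(19, 2)),
        # 2: depth exactly 8 at exactly Q20, hom EMS
        pileup_line("c", 2, "G", "A" * 8, q(20, 8)),
        # 3: freq 0.99 (99/100), hom
        pileup_line("c", 3, "G", "A" * 99 + ".", q(40, 100)),
        # 4: freq 0.98 (98/100), het
        pileup_line("c", 4, "G", "A" * 98 + "..", q(40, 100)),
        # 5: depth 101, hom EMS (mapping cap)
        pileup_line("c", 5, "G", "A" * 101, q(40, 101)),
        # 6: depth exactly 100, hom EMS (kept at the cap)
        pileup_line("c", 6, "G", "A" * 100, q(40, 100)),
        # 7: hom non-EMS transition (A>G)
        pileup_line("c", 7, "A", "G" * 25, q(40, 25)),
        # 8: hom EMS C>T
        pileup_line("c", 8, "C", "T" * 25, q(40, 25)),
        # 9: het ~0.52
        pileup_line("c", 9, "G", "A" * 13 + "," * 12, q(40, 25)),
        # 10: depth 8 het
        pileup_line("c", 10, "C", "T" * 4 + "." * 4, q(40, 8)),
        # 11: depth 7 het
        pileup_line("c", 11, "C", "T" * 3 + "," * 4, q(40, 7)),
        # 12: depth 150 het (mapping cap + zygosity)
        pileup_line("c", 12, "G", "A" * 75 + "." * 75, q(40, 150)),
    ]
    expected_mapping = {2, 3, 4, 6, 7, 8, 9, 10}
    expected_candidate_ems = {2, 3, 5, 6, 8}
    return lines, expected_mapping, expected_candidate_ems


def brute_force_frequency(bases: str, quals: str, ref: str, min_bq: int = 20):
    """Independent character-by-character pileup counter (test oracle).

    Walks the raw base string one character at a time, with its own
    handling of ^/$/indel decorations, and tallies every base against
    its quality.  Returns (total_qdepth, {base: count}) over passing
    non-reference bases, or None when no base passes.
    """
    counts: dict[str, int] = {}
    total = 0
    qi = 0
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while bases[j].isdigit():
                j += 1
            i = j + int(bases[i + 1 : j])
            continue
        qual = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if qual < min_bq or c in "*<>":
            continue
        if c in ".,":
            total += 1
            continue
        b = c.upper()
        total += 1
        if b != "N" and b != ref:
            counts[b] = counts.get(b, 0) + 1
    return total, counts


# ---------------------------------------------------------------------------
# gene-model fixture: two-exon plus-strand gene, CDS = ATG CTT TGG TAC TAA
# ---------------------------------------------------------------------------

GENE_SEQ = "GGGGGGGGGG" + "ATGCTTTG" + "GTAAGTACAG" + "GTACTAA" + "CCCCCCCCCC"
# positions:  1-10 flank   11-18 ex1   19-28 intron   29-35 ex2   36-45 flank


@pytest.fixture
def two_exon_gene():
    genome = {"chr1": GENE_SEQ}
    model = GeneModel(
        gene_id="gene1",
        chrom="chr1",
        strand="+",
        exons=[(11, 18), (29, 35)],
        cds=[(11, 18), (29, 35)],
    )
    return genome, model


def snv(chrom, pos, ref, alt, qdepth=30, alt_count=30):
    return make_variant(chrom, pos, ref, alt, qdepth, alt_count)


def variant_set(*records) -> VariantSet:
    return VariantSet(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
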