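"""Minimal SNV consequence calling against GFF3 gene models.

Classifies each candidate SNP by its effect on every overlapping
transcript: coding changes are computed by substituting the alternate
base into the spliced CDS (reverse-complemented for minus-strand genes)
and translating both codons with the standard genetic code; splice
donor/acceptor sites are the first/last two intronic bases of each
intron.  Severity tiers follow the usual triage: nonsense, start/stop
disruption and splice-site changes are HIGH (likely null alleles),
missense changes are MODERATE, synonymous changes LOW, and non-coding
positions NONE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .variant_io import VariantRecord, fetch

logger = logging.getLogger(__name__)

SEVERITY_BY_CONSEQUENCE = {
    "intergenic": "NONE",
    "intronic": "NONE",
    "synonymous": "LOW",
    "missense": "MODERATE",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
}

_SEVERITY_RANK = {"HIGH": 0, "MODERATE": 1, "LOW": 2, "NONE": 3}

#: intronic bases on each side of an exon boundary treated as splice site
SPLICE_WINDOW = 2


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


@dataclass
class GeneModel:
    """One transcript: ordered exons and CDS segments, 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for segs, name in ((self.exons, "exons"), (self.cds, "CDS")):
            for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.gene_id}: {name} overlap or are unsorted"
                    )

    @property
    def span(self) -> tuple[int, int]:
        segs = self.exons or self.cds
        return segs[0][0], segs[-1][1]


@dataclass
class ConsequenceCall:
    """Effect of one variant on one transcript (or intergenic)."""

    variant_key: tuple
    gene_id: str | None
    consequence: str
    severity: str
    protein_change: str | None = None


def annotate_variant(
    v: VariantRecord, models: list[GeneModel], genome
) -> list[ConsequenceCall]:
    """One ConsequenceCall per overlapping transcript (else intergenic).

    Only SNVs are annotated; indels are handled by marker design, not
    effect-called.  Raises ReferenceMismatchError when the variant's REF
    disagrees with the genome, or when ALT equals the reference base.
    """
    if v.is_indel or len(v.ref) != 1 or len(v.alt) != 1:
        raise ValueError(f"{v.chrom}:{v.pos}: only SNVs are annotated")
    genome_ref = fetch(genome, v.chrom, v.pos, v.pos)
    if genome_ref != v.ref.upper():
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: REF {v.ref} != reference base {genome_ref}"
        )
    if v.alt.upper() == genome_ref:
        raise ReferenceMismatchError(
            f"{v.chrom}:{v.pos}: ALT equals the reference base"
        )
    calls = [
        _annotate_in_model(v, m, genome)
        for m in models
        if m.chrom == v.chrom and m.span[0] <= v.pos <= m.span[1]
    ]
    if not calls:
        calls = [ConsequenceCall(v.key, None, "intergenic", "NONE")]
    return calls


def _call(v: VariantRecord, m: GeneModel, consequence: str, change=None):
    return ConsequenceCall(
        v.key, m.gene_id, consequence, SEVERITY_BY_CONSEQUENCE[consequence], change
    )


def _annotate_in_model(
    v: VariantRecord, m: GeneModel, genome
) -> ConsequenceCall:
    splice = _splice_class(v.pos, m)
    if splice is not None:
        return _call(v, m, splice)
    cds_index = _cds_index(v.pos, m.cds)
    if cds_index is None:
        return _call(v, m, "intronic")

    cds_seq = "".join(fetch(genome, m.chrom, s, e) for s, e in m.cds)
    if m.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
        cds_index = len(cds_seq) - 1 - cds_index
        alt_base = str(Seq(v.alt).reverse_complement())
    else:
        alt_base = v.alt.upper()

    codon_i = cds_index // 3
    offset = cds_index - codon_i * 3
    ref_codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(ref_codon) < 3:
        raise ValueError(
            f"{m.gene_id}: incomplete terminal codon at CDS index {cds_index}"
        )
    alt_codon = ref_codon[:offset] + alt_base + ref_codon[offset + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    change = f"{ref_aa}{codon_i + 1}{alt_aa}"

    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*":
        consequence = "stop_lost"
    elif codon_i == 0 and ref_aa == "M":
        consequence = "start_lost"
    else:
        consequence = "missense"
    return _call(v, m, consequence, change)


def _splice_class(pos: int, m: GeneModel) -> str | None:
    """splice_donor / splice_acceptor when pos is in a 2 bp intron edge."""
    for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
        intron_start, intron_end = e1 + 1, s2 - 1
        if intron_end < intron_start:
            continue
        size = intron_end - intron_start + 1
        left = pos - intron_start  # offset from the 5' (plus-strand) end
        right = intron_end - pos
        if left < 0 or right < 0:
            continue
        window = min(SPLICE_WINDOW, size)
        if left < window:
            return "splice_donor" if m.strand == "+" else "splice_acceptor"
        if right < window:
            return "splice_acceptor" if m.strand == "+" else "splice_donor"
    return None


def _cds_index(pos: int, cds: list[tuple[int, int]]) -> int | None:
    """0-based plus-strand index of pos within the spliced CDS, or None."""
    offset = 0
    for s, e in cds:
        if s <= pos <= e:
            return offset + (pos - s)
        offset += e - s + 1
    return None


def triage_candidates(
    calls: list[ConsequenceCall], interval
) -> pd.DataFrame:
    """Rank candidate calls inside a mapping interval by severity.

    Returns a table (chrom, pos, ref, alt, gene_id, severity, consequence,
    protein_change) sorted HIGH > MODERATE > LOW > NONE, then by position.
    """
    rows = []
    for c in calls:
        chrom, pos, ref, alt = c.variant_key
        if interval is not None and not interval.contains(chrom, pos):
            continue
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene_id": c.gene_id,
                "severity": c.severity,
                "consequence": c.consequence,
                "protein_change": c.protein_change,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene_id",
            "severity", "consequence", "protein_change",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["severity", "pos"],
            key=lambda col: col.map(_SEVERITY_RANK) if col.name == "severity" else col,
        ).reset_index(drop=True)
    return df
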