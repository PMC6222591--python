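"""Quality-adjusted allele frequencies and the pipeline's variant filters.

The variant allele frequency at a position is the number of quality-passing
reads that differ from the reference divided by the quality-adjusted total
read count.  Filters: minimum quality-adjusted depth of 8, a mapping-only
cap dropping positions with depth > 100 (repeat-enriched artifacts), a
homozygosity threshold of 0.99, and an optional restriction to canonical
EMS changes (G>A and C>T transitions, jointly covering both strands of a
G:C -> A:T lesion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import (
    BASE_ORDER,
    HOMOZYGOUS,
    PileupRecord,
    VariantRecord,
    VariantSet,
    make_variant,
)

logger = logging.getLogger(__name__)

PURPOSE_MAPPING = "mapping"
PURPOSE_CANDIDATE = "candidate"

#: canonical EMS transitions on the reference plus strand
_EMS_PAIRS = {("G", "A"), ("C", "T")}


@dataclass
class FilterConfig:
    """Thresholds for variant filtering.

    min_base_quality : Phred score a base must reach to be counted (>= 20).
    min_depth        : minimum quality-adjusted depth (>= 8 reads).
    max_depth_for_mapping : mapping-purpose cap; positions with depth > 100
                       are dropped as repeat-enriched.
    hom_threshold    : allele frequency at or above which a call is
                       homozygous (0.99).
    ems_only         : candidate purpose only keeps canonical EMS SNVs.
    """

    min_base_quality: int = 20
    min_depth: int = 8
    max_depth_for_mapping: int = 100
    hom_threshold: float = 0.99
    ems_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.hom_threshold <= 1):
            raise ValueError("hom_threshold must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.max_depth_for_mapping <= self.min_depth:
            raise ValueError("max_depth_for_mapping must exceed min_depth")


def compute_allele_frequency(
    rec: PileupRecord,
    min_base_quality: int = 20,
    hom_threshold: float = 0.99,
) -> VariantRecord | None:
    """Turn one pileup position into a VariantRecord, or None.

    Counts only bases whose quality is at or above ``min_base_quality``.
    Deletion placeholders ``*`` consume a quality character but carry no
    base call and are excluded from both counts.  The alternate allele is
    the most frequent non-reference base among passing bases (ties broken
    in A<C<G<T order); positions with no passing non-reference base are
    non-variant and return None.
    """
    symbols, _indels = rec.tokenize()
    counts = {b: 0 for b in BASE_ORDER}
    ref_count = 0
    total = 0
    for sym, qchar in zip(symbols, rec.quals):
        if ord(qchar) - 33 < min_base_quality:
            continue
        if sym == "*":
            continue  # no base quality is meaningful for a deletion gap
        if sym in ".,":
            ref_count += 1
            total += 1
        elif sym in "><":
            continue  # reference skips: not base evidence
        else:
            base = sym.upper()
            total += 1
            if base != "N" and base != rec.ref_base:
                counts[base] = counts.get(base, 0) + 1
            elif base == rec.ref_base:
                ref_count += 1
    if total == 0:
        return None
    alt = max(BASE_ORDER, key=lambda b: (counts.get(b, 0), -BASE_ORDER.index(b)))
    alt_count = counts.get(alt, 0)
    if alt_count == 0:
        return None  # non-variant position
    return make_variant(
        rec.chrom, rec.pos, rec.ref_base, alt, total, alt_count,
        hom_threshold=hom_threshold,
    )


def is_canonical_ems(ref: str, alt: str) -> bool:
    """True for G>A and C>T transitions; indels and transversions are False."""
    if len(ref) != 1 or len(alt) != 1:
        return False
    return (ref.upper(), alt.upper()) in _EMS_PAIRS


def apply_filters(
    vs: VariantSet, cfg: FilterConfig, purpose: str
) -> tuple[VariantSet, dict[str, int]]:
    """Apply the depth / homozygosity / EMS filters for one purpose.

    ``purpose='mapping'`` keeps min_depth <= total_qdepth <= max_depth;
    heterozygous calls are retained (flagged by their zygosity field).
    ``purpose='candidate'`` keeps total_qdepth >= min_depth, homozygous
    calls only and, when ``cfg.ems_only``, canonical EMS SNVs only.

    Returns the surviving VariantSet and a per-rule drop tally; tallies
    sum to ``len(vs) - len(result)``.
    """
    if purpose not in (PURPOSE_MAPPING, PURPOSE_CANDIDATE):
        raise ValueError(f"unknown purpose {purpose!r}")
    out = VariantSet()
    tallies = {"low_depth": 0, "high_depth": 0, "not_homozygous": 0, "non_ems": 0}
    for rec in vs:
        if rec.total_qdepth < cfg.min_depth:
            tallies["low_depth"] += 1
            continue
        if purpose == PURPOSE_MAPPING and rec.total_qdepth > cfg.max_depth_for_mapping:
            tallies["high_depth"] += 1
            continue
        if purpose == PURPOSE_CANDIDATE:
            if rec.zygosity != HOMOZYGOUS:
                tallies["not_homozygous"] += 1
                continue
            if cfg.ems_only and not is_canonical_ems(rec.ref, rec.alt):
                tallies["non_ems"] += 1
                continue
        out.add(rec)
    logger.info(
        "apply_filters(%s): %d -> %d (%s)", purpose, len(vs), len(out), tallies
    )
    return out, tallies
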