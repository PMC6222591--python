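"""Background-panel construction and subtraction.

A background panel is a set of sites expected to be polymorphic for
reasons unrelated to the mutagenesis: natural variation catalogued in a
HapMap-style resource, the mutagenized inbred's private SNPs (built by
intersecting several independent datasets from the same background), the
unmutagenized parent, or homozygous calls from a wild-type sibling pool.
Subtracting these panels from the mutant pool leaves lesions unique to
the mutant.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .variant_io import SitePanel, VariantSet

logger = logging.getLogger(__name__)

KEY_ALLELE = "allele"
KEY_POSITION = "position"


def intersect_common_variants(
    sets: Sequence[VariantSet], label: str = "common"
) -> SitePanel:
    """Panel of (chrom, pos, ref, alt) keys present in every input set.

    Intersecting independent datasets from the same genetic background
    retains that background's private SNPs while discarding each
    dataset's own mutagenesis-induced changes.  Requires at least two
    sets; records with a different alt allele at the same position are
    not common.
    """
    if len(sets) < 2:
        raise ValueError("intersection requires at least two variant sets")
    keys = set(sets[0].keys())
    for vs in sets[1:]:
        keys &= vs.keys()
    logger.info("panel %s: %d keys common to %d sets", label, len(keys), len(sets))
    return SitePanel(label=label, keys=keys)


def subtract_panels(
    target: VariantSet,
    panels: Sequence[SitePanel],
    key_mode: str = KEY_ALLELE,
) -> tuple[VariantSet, dict[str, int]]:
    """Remove target records whose key appears in any panel.

    ``key_mode='allele'`` matches on (chrom, pos, ref, alt) so an EMS
    lesion at a position that is polymorphic for a *different* allele in
    a panel survives; ``key_mode='position'`` matches on (chrom, pos) for
    conservative filtering.  Returns the remaining set and per-panel
    removal tallies (a record present in several panels is tallied
    against the first).
    """
    if key_mode not in (KEY_ALLELE, KEY_POSITION):
        raise ValueError(f"unknown key_mode {key_mode!r}")
    panel_keys = [
        (p.label, p.keys if key_mode == KEY_ALLELE else p.position_keys())
        for p in panels
    ]
    out = VariantSet()
    tallies = {p.label: 0 for p in panels}
    for rec in target:
        key = rec.key if key_mode == KEY_ALLELE else rec.position_key
        for label, keys in panel_keys:
            if key in keys:
                tallies[label] += 1
                break
        else:
            out.add(rec)
    logger.info(
        "subtract_panels: %d -> %d (%s, key_mode=%s)",
        len(target), len(out), tallies, key_mode,
    )
    return out, tallies
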