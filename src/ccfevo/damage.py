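"""Missense versus gene-damaging classification of somatic alterations.

Alterations are grouped by their consequence on the encoded protein:
missense mutations leave a full-length protein (point_missense), whereas
nonsense mutations (early stop), splice-site mutations (aberrant
splicing, intron retention or in-frame loss of larger regions),
frameshifts running into early stops, larger in-frame indels and
structural events presumably destroy the product (gene_damaging).
Consequence calling itself (VEP-style annotation) is an input; this
module only applies the deterministic grouping rule used to stratify,
for example, TP53 alterations by their impact on chemosensitivity.
"""

from __future__ import annotations

import pandas as pd

POINT_MISSENSE = "point_missense"
GENE_DAMAGING = "gene_damaging"
UNCLASSIFIED = "unclassified"

_DAMAGING_EFFECTS = {"nonsense", "splice", "frameshift", "inframe_large", "structural"}
_EFFECT_VOCABULARY = _DAMAGING_EFFECTS | {"missense"}


def classify_damage(effect: str, inframe_large_damaging: bool = True) -> str:
    """Map a consequence class onto point_missense / gene_damaging.

    Effects outside the declared vocabulary (e.g. synonymous) return an
    explicit ``unclassified`` status rather than joining either group.
    ``inframe_large_damaging`` controls whether in-frame indels of three
    or more codons count as damaging (default) or stay unclassified.
    """
    if effect == "missense":
        return POINT_MISSENSE
    if effect == "inframe_large" and not inframe_large_damaging:
        return UNCLASSIFIED
    if effect in _DAMAGING_EFFECTS:
        return GENE_DAMAGING
    return UNCLASSIFIED


def damage_table(alterations: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-gene, per-patient damage calls from an annotated table.

    ``alterations`` needs columns ``patient, gene, effect``; the output
    adds a ``damage_call`` column.
    """
    out = alterations.copy()
    out["damage_call"] = out["effect"].map(lambda e: classify_damage(e, **kwargs))
    return out
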