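"""Structure-stage prioritisation and pocket annotation rules.

The structure stage adds three binary scores to the sequence cumulative
score: a change in the local hydrogen-bond pattern (1), a change in steric
clashes (1), and a positional (accessibility-orbit) shift of the mutated
residue (1).  Within each gene x dataset x region group, the variants
attaining the top two combined score *values* are carried forward to
docking; every variant tying either value is kept, so a group may
contribute more than two variants.

The druggability comparison rules (mean pocket drug score and pocket count
of the mutant versus its wild type) are informational annotations only and
never feed selection.
"""

from __future__ import annotations

import math
from typing import Callable, Hashable, Sequence

from .records import (
    AsaShift,
    PocketAnnotation,
    SequenceScoreVector,
    StructureChangeOutcomes,
    StructureScoreVector,
    VariantRecord,
)


def score_structure_outcomes(
    outcomes: StructureChangeOutcomes, seq: SequenceScoreVector
) -> StructureScoreVector:
    """Score the structure-change flags and combine with the sequence score."""
    hbond = 1 if outcomes.hbond_changed else 0
    clash = 1 if outcomes.clash_changed else 0
    asa = 0 if outcomes.asa_shift is AsaShift.NONE else 1
    structure = hbond + clash + asa
    return StructureScoreVector(
        hbond_score=hbond,
        clash_score=clash,
        asa_score=asa,
        cumulative_structure=structure,
        combined_total=seq.cumulative + structure,
    )


def default_grouping(variant: VariantRecord) -> tuple[str, str, str]:
    return (variant.gene, variant.dataset.value, variant.region.value)


def select_top_two(
    scored: Sequence[tuple[VariantRecord, int]],
    grouping: Callable[[VariantRecord], Hashable] = default_grouping,
) -> list[tuple[VariantRecord, int]]:
    """Keep, per group, every variant attaining one of the top two score values.

    "Top two" refers to distinct combined-total values, not to two variants:
    a group scoring {9, 9, 8, 8, 8, 7} keeps all five variants at 9 or 8.
    Groups with a single distinct value keep everything.
    """
    groups: dict[Hashable, list[int]] = {}
    for variant, total in scored:
        groups.setdefault(grouping(variant), []).append(total)
    cutoffs = {}
    for key, totals in groups.items():
        values = sorted(set(totals), reverse=True)
        cutoffs[key] = values[1] if len(values) >= 2 else values[0]
    return [
        (variant, total)
        for variant, total in scored
        if total >= cutoffs[grouping(variant)]
    ]


def classify_drug_score(
    mean_mut: float, mean_wt: float, tol: float = 1e-9
) -> str:
    """Compare mean pocket drug scores: Favourable / Unfavourable / Neutral."""
    if not (math.isfinite(mean_mut) and math.isfinite(mean_wt)):
        raise ValueError("drug scores must be finite")
    if abs(mean_mut - mean_wt) <= tol:
        return "Neutral"
    return "Favourable" if mean_mut > mean_wt else "Unfavourable"


def classify_pocket_count(n_mut: int, n_wt: int) -> str:
    """Compare ligand-binding pocket counts: Increase / Decrease / Neutral."""
    if n_mut < 0 or n_wt < 0:
        raise ValueError("pocket counts must be non-negative")
    if n_mut == n_wt:
        return "Neutral"
    return "Increase" if n_mut > n_wt else "Decrease"


def annotate_pockets(
    mean_drug_score_wt: float,
    mean_drug_score_mut: float,
    n_pockets_wt: int,
    n_pockets_mut: int,
) -> PocketAnnotation:
    return PocketAnnotation(
        mean_drug_score_wt=mean_drug_score_wt,
        mean_drug_score_mut=mean_drug_score_mut,
        n_pockets_wt=n_pockets_wt,
        n_pockets_mut=n_pockets_mut,
        drug_score_label=classify_drug_score(mean_drug_score_mut, mean_drug_score_wt),
        pocket_label=classify_pocket_count(n_pockets_mut, n_pockets_wt),
    )
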