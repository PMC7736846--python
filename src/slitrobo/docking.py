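"""Weighted scoring and grading of mutant-vs-wild-type docked complexes.

Seven post-docking parameters are compared between each mutant:wild-type
complex and the wild-type:wild-type reference: three energy terms (docking
free energy dG, binding-affinity change ddG_bind, solvation gain d^iG),
three interaction counts (hydrogen bonds, van der Waals contacts, salt
bridges) and the superposition RMSD of the mutant complex onto the
reference.  Each comparison maps to a weight: no change 0, a
strengthening-type change (more negative energy, gained interactions,
RMSD below the category mean) 1, and a weakening-type change 2.  The total
score TS (0-14) of a mutant complex is graded against the arithmetic mean
TS of its docking category: TS > mean is "more disrupting", TS < mean
"less disrupting"; the wild-type reference sits at 0 by construction.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

from .records import (
    CategorySummary,
    CountClass,
    DockComparison,
    EnergyClass,
    Grade,
    RmsdClass,
    ScoredComplex,
    VariantRecord,
    COUNT_PARAMETERS,
    ENERGY_PARAMETERS,
)

#: Default neutral tolerances per raw parameter: energies are real-valued
#: server outputs (exact ties are meaningful only to machine precision),
#: interaction counts are integers (any difference counts), RMSD carries
#: sub-milliangstrom numerical noise from superposition.
DEFAULT_TOLERANCES = {
    "free_energy": 1e-9,
    "binding_affinity": 1e-9,
    "solvation": 1e-9,
    "hbond": 0.0,
    "vdw": 0.0,
    "saltbridge": 0.0,
    "rmsd": 1e-3,
}


def classify_delta(
    param: str, wt_value: float, mut_value: float, tol: float | None = None
) -> EnergyClass | CountClass:
    """Classify a raw (wild type, mutant) parameter pair.

    Energy terms: a more negative mutant value strengthens the complex;
    a less negative one weakens it.  Interaction counts: more interactions
    in the mutant complex is ``increased``, fewer is ``decreased``.
    """
    if param in ENERGY_PARAMETERS:
        classes = (EnergyClass.NEUTRAL, EnergyClass.STRENGTHENING, EnergyClass.WEAKENING)
    elif param in COUNT_PARAMETERS:
        classes = (CountClass.NEUTRAL, CountClass.INCREASED, CountClass.DECREASED)
    else:
        raise ValueError(f"unknown docking parameter {param!r}")
    if not (math.isfinite(wt_value) and math.isfinite(mut_value)):
        raise ValueError(f"non-finite values for {param}: wt={wt_value}, mut={mut_value}")
    if tol is None:
        tol = DEFAULT_TOLERANCES[param]
    delta = mut_value - wt_value
    if abs(delta) <= tol:
        return classes[0]
    if param in ENERGY_PARAMETERS:
        # lower (more negative) energy strengthens the interaction
        return classes[1] if delta < 0 else classes[2]
    # counts: a gain of interactions scores 1, a loss scores 2
    return classes[1] if delta > 0 else classes[2]


def rmsd_class(rmsd: float, mean_rmsd: float, tol: float | None = None) -> RmsdClass:
    """Classify a complex RMSD against the category mean RMSD."""
    if rmsd < 0 or mean_rmsd < 0:
        raise ValueError("RMSD values must be non-negative")
    if tol is None:
        tol = DEFAULT_TOLERANCES["rmsd"]
    if abs(rmsd - mean_rmsd) <= tol:
        return RmsdClass.EQUAL_MEAN
    return RmsdClass.BELOW_MEAN if rmsd < mean_rmsd else RmsdClass.ABOVE_MEAN


def score_docked_complex(
    variant: VariantRecord,
    comparison: DockComparison,
    category: str,
    mutated_partner: str = "",
    wild_type_partner: str = "",
) -> ScoredComplex:
    """Apply the weight map to a seven-parameter comparison."""
    scores = comparison.component_scores()
    return ScoredComplex(
        variant=variant,
        mutated_partner=mutated_partner or variant.gene,
        wild_type_partner=wild_type_partner,
        category=category,
        comparison=comparison,
        component_scores=scores,
        total_score=sum(scores),
    )


def summarize_category(
    complexes: Sequence[ScoredComplex], category: str
) -> CategorySummary:
    """Mean total score (and mean RMSD when raw values exist) of one category.

    Only mutant complexes enter the means; wild-type reference rows
    (grade ``wild_type_reference``) are excluded.
    """
    members = [
        c for c in complexes
        if c.category == category and c.grade is not Grade.WILD_TYPE_REFERENCE
    ]
    if not members:
        raise ValueError(f"no mutant complexes in category {category!r}")
    totals = [c.total_score for c in members]
    rmsds = [c.comparison.rmsd for c in members if c.comparison.rmsd is not None]
    n_more = sum(1 for c in members if c.grade is Grade.MORE_DISRUPTING)
    n_less = sum(1 for c in members if c.grade is Grade.LESS_DISRUPTING)
    if n_more + n_less not in (0, len(members)):
        raise ValueError("category is only partially graded")
    if n_more + n_less == 0:
        # ungraded cohort: the summary is used to drive grading, so the
        # partition fields provisionally count everything as less disrupting
        n_less = len(members)
    return CategorySummary(
        category=category,
        n_complexes=len(members),
        mean_total_score=sum(totals) / len(totals),
        mean_rmsd=(sum(rmsds) / len(rmsds)) if len(rmsds) == len(members) else None,
        n_more=n_more,
        n_less=n_less,
        n_tied=sum(1 for c in members if c.tie_flag),
    )


def grade_complex(complex_: ScoredComplex, summary: CategorySummary) -> Grade:
    """Grade one complex against its category mean total score.

    A total exactly equal to the mean is graded less disrupting with
    ``tie_flag`` set (the scheme defines only the strict inequalities;
    ties are resolved conservatively toward the wild-type reference).
    """
    if complex_.category != summary.category:
        raise ValueError(
            f"complex category {complex_.category!r} does not match summary "
            f"{summary.category!r}")
    if complex_.total_score > summary.mean_total_score:
        complex_.grade = Grade.MORE_DISRUPTING
        complex_.tie_flag = False
    elif complex_.total_score < summary.mean_total_score:
        complex_.grade = Grade.LESS_DISRUPTING
        complex_.tie_flag = False
    else:
        complex_.grade = Grade.LESS_DISRUPTING
        complex_.tie_flag = True
    return complex_.grade


def grade_all(complexes: Sequence[ScoredComplex]) -> dict[str, CategorySummary]:
    """Grade every complex within its category; returns graded summaries.

    The category mean is computed over the ungraded totals first, each
    member is graded against it, and the summary is then rebuilt so its
    grade partition reflects the outcome.
    """
    by_category: dict[str, list[ScoredComplex]] = defaultdict(list)
    for c in complexes:
        if c.grade is not Grade.WILD_TYPE_REFERENCE:
            by_category[c.category].append(c)
    summaries: dict[str, CategorySummary] = {}
    for category, members in by_category.items():
        mean = sum(c.total_score for c in members) / len(members)
        pre = CategorySummary(
            category=category, n_complexes=len(members), mean_total_score=mean,
            n_more=0, n_less=len(members))
        for c in members:
            grade_complex(c, pre)
        summaries[category] = summarize_category(members, category)
    return summaries


#: Printed-name aliases: the same ROBO4 variant appears as p.W367C in the
#: prioritisation table and p.W397C in the docking table.
VARIANT_ALIASES: dict[tuple[str, str], str] = {("ROBO4", "W397C"): "W367C"}


def canonical_variant_name(gene: str, change: str) -> str:
    return VARIANT_ALIASES.get((gene, change), change)


def count_high_disruptors(
    graded: Iterable[ScoredComplex],
    mutated_gene: str,
    wild_type_partner_gene: str | None = None,
) -> int:
    """Count distinct mutant variants of a gene graded more disrupting.

    Counts across all categories (domain-level and whole-protein) in which
    the stated gene carries the mutation and the other partner is the wild
    type of ``wild_type_partner_gene`` (any partner when ``None``).
    Printed-name aliases of the same variant are merged before counting.
    """
    hits: set[str] = set()
    for c in graded:
        if c.grade is not Grade.MORE_DISRUPTING:
            continue
        if c.variant.gene != mutated_gene:
            continue
        if wild_type_partner_gene is not None:
            partner_gene = c.wild_type_partner.split(".")[0]
            if partner_gene != wild_type_partner_gene:
                continue
        hits.add(canonical_variant_name(c.variant.gene, c.variant.protein_change))
    return len(hits)


def disruptor_count_matrix(
    graded: Sequence[ScoredComplex],
) -> dict[tuple[str, str], int]:
    """Disruptor counts for every (mutated gene, wild-type partner gene) pair."""
    pairs = {
        (c.variant.gene, c.wild_type_partner.split(".")[0])
        for c in graded
        if c.grade is not Grade.WILD_TYPE_REFERENCE
    }
    return {
        (gene, partner): count_high_disruptors(graded, gene, partner)
        for gene, partner in sorted(pairs)
    }
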