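"""Sequence-stage variant prioritisation.

Six sequence predictors each contribute a weighted score: the damaging-side
outcome of PROVEAN, SIFT, SNPs&GO, iMutant and FATHMM scores 1, PolyPhen2
distinguishes "possibly damaging" (1) from "probably damaging" (2), and all
benign-side outcomes score 0.  The per-variant cumulative score therefore
lies in [0, 7].  Variants whose cumulative score strictly exceeds the median
of the cumulative-score distribution of the pooled cohort advance to the
structure stage.
"""

from __future__ import annotations

from typing import Iterable, Literal, Sequence

import numpy as np

from .records import (
    Fathmm,
    Imutant,
    Polyphen2,
    Provean,
    SequenceScoreVector,
    SequenceToolOutcomes,
    Sift,
    SnpsGo,
    VariantRecord,
)

TOOL_SCORES = {
    "provean": {Provean.NEUTRAL: 0, Provean.DELETERIOUS: 1},
    "sift": {Sift.TOLERATED: 0, Sift.DAMAGING: 1},
    "polyphen2": {
        Polyphen2.BENIGN: 0,
        Polyphen2.POSSIBLY_DAMAGING: 1,
        Polyphen2.PROBABLY_DAMAGING: 2,
    },
    "snps_go": {SnpsGo.NEUTRAL: 0, SnpsGo.DISEASE: 1},
    "imutant": {Imutant.INCREASE_STABILITY: 0, Imutant.DECREASE_STABILITY: 1},
    "fathmm": {Fathmm.PASSENGER: 0, Fathmm.CANCER_ASSOCIATED: 1},
}

Pooling = Literal["all", "per_gene", "per_dataset"]


def score_sequence_outcomes(outcomes: SequenceToolOutcomes) -> SequenceScoreVector:
    """Apply the weighted scoring scheme to one variant's predictor outcomes.

    A missing outcome scores 0 (the benign-side value) and the tool name is
    recorded in ``missing_tools``; no imputation is attempted.
    """
    scores: dict[str, int] = {}
    missing: list[str] = []
    for tool, table in TOOL_SCORES.items():
        outcome = getattr(outcomes, tool)
        if outcome is None:
            scores[tool] = 0
            missing.append(tool)
        else:
            scores[tool] = table[outcome]
    return SequenceScoreVector(
        cumulative=sum(scores.values()), missing_tools=tuple(missing), **scores
    )


def median_threshold(cumulative_scores: Sequence[int]) -> float:
    """Median of the cumulative scores (midpoint convention for even n)."""
    if len(cumulative_scores) == 0:
        raise ValueError("cannot take the median of an empty score set")
    return float(np.median(np.asarray(cumulative_scores, dtype=float)))


def select_by_median(
    scored: Sequence[tuple[VariantRecord, SequenceScoreVector]],
    pooling: Pooling = "all",
) -> tuple[list[tuple[VariantRecord, SequenceScoreVector]], dict[str, float]]:
    """Select variants whose cumulative score strictly exceeds the pool median.

    Parameters
    ----------
    scored:
        Variants with their sequence score vectors.
    pooling:
        ``"all"`` pools every variant of every gene and dataset (the default
        cohort definition); ``"per_gene"`` / ``"per_dataset"`` compute one
        median per group and select within the group.

    Returns
    -------
    (selected, thresholds)
        The selected subset in input order and the median threshold used for
        each pool (keyed ``"all"`` or by the group label).

    Notes
    -----
    The comparison is strict: a variant whose score ties the median is
    excluded, so a pool in which every score is identical selects nothing.
    """
    if not scored:
        raise ValueError("select_by_median requires a non-empty input")

    def pool_key(v: VariantRecord) -> str:
        if pooling == "all":
            return "all"
        if pooling == "per_gene":
            return v.gene
        if pooling == "per_dataset":
            return v.dataset.value
        raise ValueError(f"unknown pooling {pooling!r}")

    pools: dict[str, list[int]] = {}
    for variant, vec in scored:
        pools.setdefault(pool_key(variant), []).append(vec.cumulative)
    thresholds = {key: median_threshold(vals) for key, vals in pools.items()}
    selected = [
        (variant, vec)
        for variant, vec in scored
        if vec.cumulative > thresholds[pool_key(variant)]
    ]
    return selected, thresholds
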