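"""Conditionality-aware METRICS scoring.

The percentage score divides the weight a study *achieved* by the maximum
weight it *could* achieve given its pipeline:

    percentage = 100 * sum(w_i, i fulfilled) / sum(w_i, i applicable)

An item contributes its full weight when fulfilled and 0 otherwise; there is
no partial credit. Renormalizing by the achievable weight means an ideal
study scores exactly 100% whatever its pipeline, and inapplicable items can
neither help nor hurt. The percentage maps onto five verbal quality grades
at 20-point boundaries (top bin closed): very low, low, moderate, good,
excellent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import ConsistencyError, DomainError, SchemaError
from .instrument import ApplicabilityProfile, Instrument, resolve_applicability

__all__ = [
    "Status",
    "QualityCategory",
    "Assessment",
    "ScoreResult",
    "compute_score",
    "categorize_score",
    "batch_score",
]

logger = logging.getLogger(__name__)

Status = Literal["fulfilled", "not_fulfilled", "not_applicable"]
QualityCategory = Literal["very low", "low", "moderate", "good", "excellent"]

_STATUSES = ("fulfilled", "not_fulfilled", "not_applicable")


@dataclass(frozen=True)
class Assessment:
    """One study's appraisal: its pipeline profile and per-item statuses.

    ``statuses`` must cover exactly item ids 1-30; an item must be marked
    ``not_applicable`` exactly when the profile makes it inapplicable
    (cross-checked at score time).
    """

    study_id: str
    profile: ApplicabilityProfile
    statuses: Mapping[int, Status]


@dataclass(frozen=True)
class ScoreResult:
    """Score breakdown for one study.

    ``percentage`` = 100 * achieved_weight / achievable_weight, computed in
    full precision (display rounds to 2 decimals). ``per_item_contribution``
    maps each applicable item to the weight it contributed (its weight if
    fulfilled, else 0); inapplicable items are absent.
    """

    study_id: str
    percentage: float
    achieved_weight: float
    achievable_weight: float
    quality_category: QualityCategory
    per_item_contribution: Mapping[int, float]


def categorize_score(percentage: float) -> QualityCategory:
    """Map a 0-100 percentage onto the five quality grades.

    Bins are left-closed/right-open at 20, 40, 60, 80, except the top bin
    which includes 100: [0,20) very low, [20,40) low, [40,60) moderate,
    [60,80) good, [80,100] excellent.
    """
    if not 0.0 <= percentage <= 100.0:
        raise DomainError(f"percentage must be in [0, 100], got {percentage}")
    if percentage < 20.0:
        return "very low"
    if percentage < 40.0:
        return "low"
    if percentage < 60.0:
        return "moderate"
    if percentage < 80.0:
        return "good"
    return "excellent"


def compute_score(instrument: Instrument, assessment: Assessment) -> ScoreResult:
    """Score one assessment against an instrument.

    Validates that statuses cover all 30 items with known status labels and
    that the not-applicable markings agree exactly with the applicability
    resolved from the profile, then accumulates achieved and achievable
    weights and bins the (unrounded) percentage.

    Raises
    ------
    SchemaError
        Unknown item id, missing item, or unknown status label.
    ConsistencyError
        An applicable item marked not_applicable, or vice versa (the
        message names the item).
    """
    statuses = dict(assessment.statuses)
    expected = set(instrument.item_ids)
    got = set(statuses)
    if got != expected:
        extra, missing = sorted(got - expected), sorted(expected - got)
        raise SchemaError(
            f"study {assessment.study_id!r}: statuses must cover item ids "
            f"1..30; missing {missing}, unknown {extra}"
        )
    for item_id, status in statuses.items():
        if status not in _STATUSES:
            raise SchemaError(
                f"study {assessment.study_id!r}: item {item_id} has unknown "
                f"status {status!r}"
            )

    applicable = resolve_applicability(instrument, assessment.profile)
    achieved = 0.0
    achievable = 0.0
    contributions: dict[int, float] = {}
    for item in instrument.items:
        status = statuses[item.item_id]
        if item.item_id in applicable:
            if status == "not_applicable":
                raise ConsistencyError(
                    f"study {assessment.study_id!r}: item {item.item_id} is "
                    "applicable under the profile but marked not_applicable"
                )
            achievable += item.weight
            fulfilled = status == "fulfilled"
            if fulfilled:
                achieved += item.weight
            contributions[item.item_id] = item.weight if fulfilled else 0.0
        elif status != "not_applicable":
            raise ConsistencyError(
                f"study {assessment.study_id!r}: item {item.item_id} is not "
                f"applicable under the profile but marked {status!r}"
            )

    # divide before scaling: achieved/achievable is exactly 1.0 for a
    # perfect study, so the percentage is exactly 100
    percentage = 100.0 * (achieved / achievable)
    return ScoreResult(
        study_id=assessment.study_id,
        percentage=percentage,
        achieved_weight=achieved,
        achievable_weight=achievable,
        quality_category=categorize_score(percentage),
        per_item_contribution=contributions,
    )


def batch_score(
    instrument: Instrument,
    assessments: Iterable[Assessment],
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Score a collection of studies into one table, in input order.

    Columns: study_id, percentage, quality_category, achieved_weight,
    achievable_weight. By default any invalid assessment aborts the batch
    with its study_id; with ``skip_invalid=True`` bad studies are dropped
    and logged, and the valid rows are returned.
    """
    rows = []
    skipped: list[str] = []
    for assessment in assessments:
        try:
            result = compute_score(instrument, assessment)
        except Exception as exc:
            if not skip_invalid:
                raise
            skipped.append(assessment.study_id)
            logger.error(
                "skipping study %r: %s", assessment.study_id, exc
            )
            continue
        rows.append(
            {
                "study_id": result.study_id,
                "percentage": result.percentage,
                "quality_category": result.quality_category,
                "achieved_weight": result.achieved_weight,
                "achievable_weight": result.achievable_weight,
            }
        )
    if skipped:
        logger.error("skipped %d invalid studies: %s", len(skipped), skipped)
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "percentage",
            "quality_category",
            "achieved_weight",
            "achievable_weight",
        ],
    )
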