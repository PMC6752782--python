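"""Item vocabularies for the two risk-of-bias instruments.

The Cochrane risk-of-bias (CROB) tool, as applied in systematic reviews,
rates seven core items (sequence generation, allocation concealment,
participant/personnel blinding, outcome-assessment blinding, incomplete
outcome data, selective reporting, other bias) on a three-level scale
(low / unclear / high risk of bias).  Reviews report the two blinding
items in several variant formats (participants only, personnel only,
combined, combined with outcome assessment, subjective/objective outcome
splits), giving 12 reported item variants in total.

The PEDro scale rates 11 items as yes/no; the total score counts the 10
items after the first (inclusion criteria and source, which assesses
external validity and is not scored).
"""

from __future__ import annotations

import enum


class CrobRating(enum.Enum):
    """Three-level CROB judgement plus an explicit not-assessed state.

    NOT_ASSESSED means the review did not evaluate the item for the
    trial (e.g. the review reported blinding only in a combined format).
    """

    LOW = "low"
    UNCLEAR = "unclear"
    HIGH = "high"
    NOT_ASSESSED = "not_assessed"


class CoreItem(enum.Enum):
    """The seven core CROB items used for the summary score."""

    SEQUENCE_GENERATION = "sequence_generation"
    ALLOCATION_CONCEALMENT = "allocation_concealment"
    PERFORMANCE = "performance"  # blinding of participants and personnel
    DETECTION = "detection"  # blinding of outcome assessment
    ATTRITION = "attrition"  # incomplete outcome data
    REPORTING = "reporting"  # selective reporting
    OTHER = "other"  # other sources of bias


# The 12 reported CROB item variants -> core items each one covers.
# Non-blinding variants map to exactly one core item; the combined
# participants+personnel+outcome variant fills both the performance and
# detection items with the same judgement.
CROB_VARIANTS: dict[str, frozenset[CoreItem]] = {
    "sequence_generation": frozenset({CoreItem.SEQUENCE_GENERATION}),
    "allocation_concealment": frozenset({CoreItem.ALLOCATION_CONCEALMENT}),
    "participants_personnel": frozenset({CoreItem.PERFORMANCE}),
    "participants": frozenset({CoreItem.PERFORMANCE}),
    "personnel": frozenset({CoreItem.PERFORMANCE}),
    "outcome_assessment": frozenset({CoreItem.DETECTION}),
    "outcome_subjective": frozenset({CoreItem.DETECTION}),
    "outcome_objective": frozenset({CoreItem.DETECTION}),
    "participants_personnel_outcome": frozenset(
        {CoreItem.PERFORMANCE, CoreItem.DETECTION}
    ),
    "incomplete_outcome": frozenset({CoreItem.ATTRITION}),
    "selective_reporting": frozenset({CoreItem.REPORTING}),
    "other_bias": frozenset({CoreItem.OTHER}),
}

#: Human-readable labels for reports.
CROB_VARIANT_LABELS: dict[str, str] = {
    "sequence_generation": "Random sequence generation",
    "allocation_concealment": "Allocation concealment",
    "participants_personnel": "Blinding of participants and personnel",
    "participants": "Blinding of participants",
    "personnel": "Blinding of personnel",
    "outcome_assessment": "Blinding of outcome assessment",
    "outcome_subjective": "Blinding of outcome assessment (subjective outcomes)",
    "outcome_objective": "Blinding of outcome assessment (objective outcomes)",
    "participants_personnel_outcome": (
        "Blinding of participants, personnel and outcome assessment"
    ),
    "incomplete_outcome": "Incomplete outcome data",
    "selective_reporting": "Selective reporting",
    "other_bias": "Other sources of bias",
}

# The 11 PEDro items in scale order.  The first (eligibility) is rated
# but never counted in the total score.
PEDRO_ITEMS: tuple[str, ...] = (
    "eligibility",
    "random_allocation",
    "concealed_allocation",
    "baseline_comparability",
    "subject_blinding",
    "therapist_blinding",
    "assessor_blinding",
    "follow_up",
    "intention_to_treat",
    "between_group",
    "point_estimates",
)

#: Items contributing to the 0-10 total PEDro score.
PEDRO_SCORED_ITEMS: tuple[str, ...] = PEDRO_ITEMS[1:]

PEDRO_ITEM_LABELS: dict[str, str] = {
    "eligibility": "Inclusion criteria and source",
    "random_allocation": "Random allocation",
    "concealed_allocation": "Concealed allocation",
    "baseline_comparability": "Baseline comparability",
    "subject_blinding": "Subject blinding",
    "therapist_blinding": "Therapist blinding",
    "assessor_blinding": "Assessor blinding",
    "follow_up": "Completeness of follow up",
    "intention_to_treat": "Intention-to-treat analysis",
    "between_group": "Between-group statistical comparisons",
    "point_estimates": "Point measures and variability",
}


def variant_core_items(variant: str) -> frozenset[CoreItem]:
    """Core items covered by a reported CROB variant name."""
    try:
        return CROB_VARIANTS[variant]
    except KeyError:
        raise KeyError(
            f"unknown CROB item variant {variant!r}; "
            f"known variants: {sorted(CROB_VARIANTS)}"
        ) from None
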