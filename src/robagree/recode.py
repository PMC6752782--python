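"""Dichotomization schemes and instrument summary scores.

The CROB three-level judgements are dichotomized three ways before
being compared with the binary PEDro items:

* ``MAIN``  -- low -> 1, unclear or high -> 0 (unclear treated as a
  negative rating);
* ``SENS1`` -- low or unclear -> 1, high -> 0 (unclear treated as a
  positive rating);
* ``SENS2`` -- low -> 1, high -> 0, trials rated unclear are omitted
  from the comparison (pairwise deletion).

Ratings of NOT_ASSESSED are excluded under every scheme.

The CROB summary score for a trial is the percentage of the *evaluated*
core items rated low risk of bias (optionally low-or-unclear); the total
PEDro score is the number of yes ratings among the 10 scored items.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .items import (
    CROB_VARIANTS,
    PEDRO_ITEMS,
    PEDRO_SCORED_ITEMS,
    CoreItem,
    CrobRating,
)


class RecodeScheme(enum.Enum):
    MAIN = "main"
    SENS1 = "sens1"
    SENS2 = "sens2"


#: Marker (``None``) used where a rating is excluded from a scheme.
EXCLUDED = None

_SCHEME_MAP: dict[RecodeScheme, dict[CrobRating, int | None]] = {
    RecodeScheme.MAIN: {
        CrobRating.LOW: 1,
        CrobRating.UNCLEAR: 0,
        CrobRating.HIGH: 0,
        CrobRating.NOT_ASSESSED: EXCLUDED,
    },
    RecodeScheme.SENS1: {
        CrobRating.LOW: 1,
        CrobRating.UNCLEAR: 1,
        CrobRating.HIGH: 0,
        CrobRating.NOT_ASSESSED: EXCLUDED,
    },
    RecodeScheme.SENS2: {
        CrobRating.LOW: 1,
        CrobRating.UNCLEAR: EXCLUDED,
        CrobRating.HIGH: 0,
        CrobRating.NOT_ASSESSED: EXCLUDED,
    },
}


def recode_crob(rating: CrobRating, scheme: RecodeScheme) -> int | None:
    """Dichotomize one CROB rating; ``None`` means excluded."""
    return _SCHEME_MAP[scheme][rating]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TransformedCounts:
    """Counts of trials coded ``1`` for one item under one scheme."""

    n_coded_1: int
    denominator: int
    #: display percentage rounded half-up; ``None`` if denominator == 0
    percent: int | None

    @property
    def undefined(self) -> bool:
        return self.percent is None


def transform_counts(
    low: int, unclear: int, high: int, scheme: RecodeScheme
) -> TransformedCounts:
    """Recode marginal (low, unclear, high) counts under a scheme.

    Returns the number of trials coded 1, the number retained by the
    scheme (the denominator), and the integer display percentage.
    """
    if min(low, unclear, high) < 0:
        raise ValueError("counts must be non-negative")
    if scheme is RecodeScheme.MAIN:
        n1, denom = low, low + unclear + high
    elif scheme is RecodeScheme.SENS1:
        n1, denom = low + unclear, low + unclear + high
    else:  # SENS2: unclear omitted
        n1, denom = low, low + high
    pct = round_half_up(100.0 * n1 / denom) if denom > 0 else None
    return TransformedCounts(n1, denom, pct)


# Rating severity used when a review reported several variants of the
# same core item for one trial: keep the worst (most biased) judgement.
_SEVERITY = {CrobRating.LOW: 0, CrobRating.UNCLEAR: 1, CrobRating.HIGH: 2}


def core_item_ratings(crob: dict[str, CrobRating]) -> dict[CoreItem, CrobRating]:
    """Collapse reported variant ratings onto the seven core items.

    Each variant fills the core item(s) it covers; when two variants
    disagree on the same core item the worst rating wins
    (HIGH > UNCLEAR > LOW).  NOT_ASSESSED ratings contribute nothing.
    """
    out: dict[CoreItem, CrobRating] = {}
    for variant, rating in crob.items():
        if rating is CrobRating.NOT_ASSESSED:
            continue
        for item in CROB_VARIANTS[variant]:
            prev = out.get(item)
            if prev is None or _SEVERITY[rating] > _SEVERITY[prev]:
                out[item] = rating
    return out


def crob_summary_score(record, include_unclear: bool = False) -> float | None:
    """Percentage of evaluated core items rated low (or low/unclear).

    ``record`` is any object with a ``crob`` mapping of variant name to
    :class:`CrobRating`.  Returns ``None`` when no core item was
    evaluated (the trial is then excluded from summary-score analyses).
    """
    ratings = core_item_ratings(record.crob)
    if not ratings:
        return None
    good = {CrobRating.LOW, CrobRating.UNCLEAR} if include_unclear else {CrobRating.LOW}
    num = sum(1 for r in ratings.values() if r in good)
    return 100.0 * num / len(ratings)


def pedro_total(record) -> int:
    """Total PEDro score: yes-count over the 10 scored items (0-10)."""
    missing = [i for i in PEDRO_ITEMS if i not in record.pedro]
    if missing:
        raise ValueError(f"PEDro ratings missing for items: {missing}")
    return sum(int(record.pedro[i]) for i in PEDRO_SCORED_ITEMS)
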