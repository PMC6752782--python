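"""Reading, validating and writing trial-rating tables.

Input is a delimited table with one row per (trial, review): a trial
identifier, a review (cluster) identifier, up to 12 CROB item-variant
columns rated low/unclear/high, and the 11 yes/no PEDro item columns.
A :class:`Dialect` maps column names to the canonical item vocabulary,
so exports with arbitrary headers can be ingested with a small config.

Trials appearing in more than one review are resolved by
:func:`deduplicate` into a main analysis set (one randomly retained
rating per trial) and a set of rating pairs used for the between-review
reliability analysis.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import AgreementResult, IccResult
from .items import CROB_VARIANTS, PEDRO_ITEMS, CrobRating


class RatingsSchemaError(ValueError):
    """A mandatory column is missing or a row is malformed."""


class RatingVocabularyError(ValueError):
    """A rating token is outside the configured vocabulary."""


DEFAULT_CROB_VOCAB: dict[str, CrobRating] = {
    "low": CrobRating.LOW,
    "unclear": CrobRating.UNCLEAR,
    "high": CrobRating.HIGH,
    "not assessed": CrobRating.NOT_ASSESSED,
    "not_assessed": CrobRating.NOT_ASSESSED,
    "na": CrobRating.NOT_ASSESSED,
    "": CrobRating.NOT_ASSESSED,
}

DEFAULT_PEDRO_VOCAB: dict[str, int] = {
    "yes": 1,
    "no": 0,
    "y": 1,
    "n": 0,
    "1": 1,
    "0": 0,
}


@dataclass(frozen=True)
class Dialect:
    """Column-naming and vocabulary configuration for rating tables.

    By default CROB variant columns are named ``crob_<variant>`` and
    PEDro columns ``pedro_<item>`` using the canonical keys from
    :mod:`robagree.items`.  CROB columns absent from the file default
    to NOT_ASSESSED; all 11 PEDro columns are mandatory.
    """

    trial_col: str = "trial_id"
    review_col: str = "review_id"
    crob_columns: Mapping[str, str] = field(
        default_factory=lambda: {v: f"crob_{v}" for v in CROB_VARIANTS}
    )
    pedro_columns: Mapping[str, str] = field(
        default_factory=lambda: {i: f"pedro_{i}" for i in PEDRO_ITEMS}
    )
    crob_vocab: Mapping[str, CrobRating] = field(
        default_factory=lambda: dict(DEFAULT_CROB_VOCAB)
    )
    pedro_vocab: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PEDRO_VOCAB)
    )
    delimiter: str = ","
    #: optional column with a precomputed total PEDro score; if present
    #: it is cross-checked against recomputation (mismatch = warning).
    pedro_total_col: str = "pedro_total"

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Dialect":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise RatingsSchemaError(f"unknown dialect keys: {sorted(unknown)}")
        return replace(cls(), **dict(cfg))


@dataclass
class TrialRecord:
    """One trial's paired ratings within one review (the cluster)."""

    trial_id: str
    review_id: str
    crob: dict[str, CrobRating]
    pedro: dict[str, int]
    occurrence_index: int = 1

    def __post_init__(self):
        missing = [i for i in PEDRO_ITEMS if i not in self.pedro]
        if missing:
            raise RatingsSchemaError(
                f"trial {self.trial_id!r}: PEDro items missing: {missing}"
            )
        unknown = set(self.crob) - set(CROB_VARIANTS)
        if unknown:
            raise RatingsSchemaError(
                f"trial {self.trial_id!r}: unknown CROB variants: {sorted(unknown)}"
            )


def _norm(token) -> str:
    return str(token).strip().lower()


def read_trial_ratings(
    source, dialect: Dialect | Mapping | None = None
) -> list[TrialRecord]:
    """Parse and validate a delimited rating table into TrialRecords.

    ``source`` is a path or text stream.  Rating tokens are matched
    case-insensitively against the dialect vocabularies; unknown tokens
    and missing mandatory columns raise errors that name the offending
    token/column and the 1-based data row.
    """
    if dialect is None:
        dialect = Dialect()
    elif not isinstance(dialect, Dialect):
        dialect = Dialect.from_mapping(dialect)
    df = pd.read_csv(
        source, sep=dialect.delimiter, dtype=str, keep_default_na=False
    )
    for col in (dialect.trial_col, dialect.review_col):
        if col not in df.columns:
            raise RatingsSchemaError(f"mandatory column {col!r} missing")
    missing_pedro = [
        c for c in dialect.pedro_columns.values() if c not in df.columns
    ]
    if missing_pedro:
        raise RatingsSchemaError(f"mandatory PEDro columns missing: {missing_pedro}")
    crob_present = {
        v: c for v, c in dialect.crob_columns.items() if c in df.columns
    }

    records: list[TrialRecord] = []
    occurrence: dict[str, int] = defaultdict(int)
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        trial_id = str(row[dialect.trial_col]).strip()
        review_id = str(row[dialect.review_col]).strip()
        if not trial_id or not review_id:
            raise RatingsSchemaError(f"row {pos}: empty trial or review id")
        crob: dict[str, CrobRating] = {}
        for variant, col in crob_present.items():
            token = _norm(row[col])
            if token not in dialect.crob_vocab:
                raise RatingVocabularyError(
                    f"row {pos}, column {col!r}: unknown CROB rating "
                    f"token {row[col]!r}"
                )
            crob[variant] = dialect.crob_vocab[token]
        for variant in dialect.crob_columns:
            crob.setdefault(variant, CrobRating.NOT_ASSESSED)
        pedro: dict[str, int] = {}
        for item, col in dialect.pedro_columns.items():
            token = _norm(row[col])
            if token not in dialect.pedro_vocab:
                raise RatingVocabularyError(
                    f"row {pos}, column {col!r}: unknown PEDro rating "
                    f"token {row[col]!r}"
                )
            pedro[item] = dialect.pedro_vocab[token]
        occurrence[trial_id] += 1
        rec = TrialRecord(
            trial_id=trial_id,
            review_id=review_id,
            crob=crob,
            pedro=pedro,
            occurrence_index=occurrence[trial_id],
        )
        if dialect.pedro_total_col in df.columns:
            stated = _norm(row[dialect.pedro_total_col])
            if stated not in ("", "na"):
                from .recode import pedro_total

                if int(float(stated)) != pedro_total(rec):
                    warnings.warn(
                        f"row {pos}: stated total PEDro score {stated} "
                        f"differs from recomputed {pedro_total(rec)}",
                        stacklevel=2,
                    )
        records.append(rec)

    seen = set()
    for rec in records:
        key = (rec.trial_id, rec.review_id)
        if key in seen:
            raise RatingsSchemaError(
                f"duplicate (trial_id, review_id) pair {key!r}"
            )
        seen.add(key)
    return records


def records_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten records to the default wide CSV layout."""
    rows = []
    for rec in records:
        row: dict = {
            "trial_id": rec.trial_id,
            "review_id": rec.review_id,
            "occurrence_index": rec.occurrence_index,
        }
        for variant in CROB_VARIANTS:
            rating = rec.crob.get(variant, CrobRating.NOT_ASSESSED)
            row[f"crob_{variant}"] = (
                "" if rating is CrobRating.NOT_ASSESSED else rating.value
            )
        for item in PEDRO_ITEMS:
            row[f"pedro_{item}"] = "yes" if rec.pedro[item] else "no"
        rows.append(row)
    return pd.DataFrame(rows)


def write_trial_ratings(records: Sequence[TrialRecord], destination) -> None:
    """Write records in the default dialect (read/write round-trips)."""
    records_to_frame(records).to_csv(destination, index=False)


# ---------------------------------------------------------------------------
# duplicate-trial resolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DedupResult:
    main_set: list[TrialRecord]
    reliability_pairs: list[tuple[TrialRecord, TrialRecord]]
    dropped: list[TrialRecord]


def deduplicate(records: Sequence[TrialRecord], seed: int) -> DedupResult:
    """Partition records into a main analysis set and reliability pairs.

    Trials rated in a single review pass through.  For a trial rated in
    k >= 2 reviews, one rating is retained uniformly at random
    (seeded); of the remaining ratings, the first in a canonical sort
    of review ids becomes the second member of a between-review
    reliability pair; third and later ratings are dropped.  The result
    is deterministic given the seed and invariant to input order.
    """
    rng = np.random.default_rng(seed)
    by_trial: dict[str, list[TrialRecord]] = defaultdict(list)
    for rec in records:
        by_trial[rec.trial_id].append(rec)

    main: list[TrialRecord] = []
    pairs: list[tuple[TrialRecord, TrialRecord]] = []
    dropped: list[TrialRecord] = []
    for trial_id in sorted(by_trial):
        group = sorted(by_trial[trial_id], key=lambda r: str(r.review_id))
        if len(group) == 1:
            main.append(group[0])
            continue
        keep = group[int(rng.integers(len(group)))]
        rest = [r for r in group if r is not keep]
        main.append(keep)
        pairs.append((keep, rest[0]))
        dropped.extend(rest[1:])
    return DedupResult(main, pairs, dropped)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def _format_value(key: str, value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if key in ("percent_agreement",):
        return f"{value:.1f}"
    if key in ("kappa", "icc", "ci_low", "ci_high"):
        return f"{value:.3f}"
    return value


def agreement_results_to_frame(
    results: Mapping[str, AgreementResult | IccResult]
) -> pd.DataFrame:
    """Tabulate named agreement/ICC results with report formatting.

    Percentages are printed to 1 decimal and kappa/ICC values to 3
    decimals; not-calculable cells are left blank.
    """
    rows = []
    for name, res in results.items():
        d = res.to_dict()
        rows.append(
            {"analysis": name, **{k: _format_value(k, v) for k, v in d.items()}}
        )
    return pd.DataFrame(rows)


def write_report(
    results: Mapping[str, "pd.DataFrame | Mapping"], destination
) -> None:
    """Write result tables as CSV files plus one combined JSON report.

    ``results`` maps a table name to either a DataFrame (written as
    ``<name>.csv``) or a plain mapping of scalars (JSON only).
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    combined: dict = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(dest / f"{name}.csv", index=False)
            combined[name] = json.loads(obj.to_json(orient="records"))
        else:
            combined[name] = obj
    with open(dest / "report.json", "w") as fh:
        json.dump(combined, fh, indent=2, sort_keys=True)
        fh.write("\n")
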