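"""Synthetic rating datasets with a closed-form agreement oracle.

The generator emulates the structure of risk-of-bias ratings extracted
from systematic reviews: trials nested in reviews, a latent per-domain
methodological status, a reporting-clarity channel that produces
"unclear" CROB judgements, two imperfect instruments observing the same
latent status, review-level variation in both prevalence and in which
item variants a review reports, and duplicate ratings of the same trial
by a second review.

Generative model, per trial and latent domain ``d``:

* latent status  S ~ Bernoulli(Phi(Phi^-1(p_d) + u)), where ``u`` is a
  review-level effect drawn once per review from N(0, review_effect_sd)
  (probit scale keeps probabilities bounded);
* reporting clarity  C ~ Bernoulli(clarity_d);
* CROB judgement: if the report is clear, low/high tracking S with
  misclassification probability ``crob_error``; if unclear, the rating
  is UNCLEAR with probability 1 - unclear_to_rating, otherwise the
  rater still commits to low/high tracking S with the same error;
* PEDro judgement: yes tracks S with probability ``pedro_error`` of
  misclassification, but only when the report is clear -- an unclear
  report is scored no, because the scale requires explicit reporting.

Combined CROB blinding variants observe the conjunction of their
component latent statuses and clarities.  Because every step is a
finite mixture, the joint distribution of (PEDro binary x CROB
three-level) per domain -- and hence the population kappa under each
recoding scheme -- has a closed form, computed exactly by
:func:`analytic_joint_distribution` (Gauss-Hermite integration over the
review effect).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .agreement import cohen_kappa
from .io import TrialRecord
from .items import CrobRating
from .recode import RecodeScheme

#: Latent domains tracked by the generator.  The two blinding items are
#: split into participant/personnel/assessor statuses so that the
#: combined reporting variants can be derived as conjunctions.
LATENT_DOMAINS: tuple[str, ...] = (
    "sequence_generation",
    "allocation_concealment",
    "participant_blinding",
    "personnel_blinding",
    "assessor_blinding",
    "incomplete_outcome",
    "selective_reporting",
    "other_bias",
)

#: CROB variant -> latent components (conjunction).
VARIANT_LATENTS: dict[str, tuple[str, ...]] = {
    "sequence_generation": ("sequence_generation",),
    "allocation_concealment": ("allocation_concealment",),
    "participants": ("participant_blinding",),
    "personnel": ("personnel_blinding",),
    "participants_personnel": ("participant_blinding", "personnel_blinding"),
    "outcome_assessment": ("assessor_blinding",),
    "outcome_subjective": ("assessor_blinding",),
    "outcome_objective": ("assessor_blinding",),
    "participants_personnel_outcome": (
        "participant_blinding",
        "personnel_blinding",
        "assessor_blinding",
    ),
    "incomplete_outcome": ("incomplete_outcome",),
    "selective_reporting": ("selective_reporting",),
    "other_bias": ("other_bias",),
}

#: PEDro item -> latent domain it observes.
PEDRO_LATENTS: dict[str, str] = {
    "random_allocation": "sequence_generation",
    "concealed_allocation": "allocation_concealment",
    "subject_blinding": "participant_blinding",
    "therapist_blinding": "personnel_blinding",
    "assessor_blinding": "assessor_blinding",
    "follow_up": "incomplete_outcome",
}

_DEFAULT_PREVALENCE = {
    "sequence_generation": 0.55,
    "allocation_concealment": 0.35,
    "participant_blinding": 0.06,
    "personnel_blinding": 0.03,
    "assessor_blinding": 0.40,
    "incomplete_outcome": 0.55,
    "selective_reporting": 0.50,
    "other_bias": 0.60,
}

_DEFAULT_CLARITY = {
    "sequence_generation": 0.58,
    "allocation_concealment": 0.42,
    "participant_blinding": 0.86,
    "personnel_blinding": 0.87,
    "assessor_blinding": 0.70,
    "incomplete_outcome": 0.76,
    "selective_reporting": 0.61,
    "other_bias": 0.69,
}

#: Review-level probability that an item variant family is assessed at
#: all (blinding items are governed by the style draws instead).
_DEFAULT_ASSESSED = {
    "sequence_generation": 1.0,
    "allocation_concealment": 1.0,
    "incomplete_outcome": 1.0,
    "selective_reporting": 0.91,
    "other_bias": 0.60,
}

#: Marginal prevalence of a yes for PEDro items with no CROB partner.
_DEFAULT_PEDRO_EXTRA = {
    "eligibility": 0.81,
    "baseline_comparability": 0.80,
    "intention_to_treat": 0.32,
    "between_group": 0.95,
    "point_estimates": 0.91,
}

_RATING_CODES = (CrobRating.LOW, CrobRating.UNCLEAR, CrobRating.HIGH)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic rating study.

    Defaults emulate the observed shape of published review data:
    ~108 reviews of 7-22 trials each, participant/therapist blinding
    rarely achieved, assessor blinding achieved in roughly a third of
    trials, and heavy "unclear" use for allocation concealment.
    """

    n_reviews: int = 108
    trials_per_review: tuple[int, int] = (7, 22)
    domain_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE)
    )
    clarity_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLARITY)
    )
    crob_error: float = 0.05
    pedro_error: float = 0.05
    unclear_to_rating: float = 0.10
    review_effect_sd: float = 0.30
    duplicate_fraction: float = 0.054
    duplicate_error: float = 0.10
    #: review-level probability each blinding reporting style is used:
    #: separate participant/personnel columns, combined, triple-combined
    #: (covering outcome assessment too), or no performance item.
    performance_style_probs: tuple[float, float, float, float] = (
        0.35,
        0.40,
        0.15,
        0.10,
    )
    #: when the style is not triple-combined: plain outcome-assessment
    #: column, subjective-outcomes column, objective-outcomes column,
    #: or no detection item.
    detection_style_probs: tuple[float, float, float, float] = (
        0.85,
        0.06,
        0.08,
        0.01,
    )
    item_assessed_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ASSESSED)
    )
    pedro_extra_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PEDRO_EXTRA)
    )
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.trials_per_review
        if not (1 <= lo <= hi):
            raise ValueError("trials_per_review must satisfy 1 <= lo <= hi")
        if self.n_reviews < 2:
            raise ValueError("n_reviews must be >= 2")
        probs = [
            self.crob_error,
            self.pedro_error,
            self.unclear_to_rating,
            self.duplicate_fraction,
            self.duplicate_error,
            *self.domain_prevalence.values(),
            *self.clarity_prob.values(),
            *self.item_assessed_prob.values(),
            *self.pedro_extra_prevalence.values(),
            *self.performance_style_probs,
            *self.detection_style_probs,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.review_effect_sd < 0:
            raise ValueError("review_effect_sd must be >= 0")
        for styles in (self.performance_style_probs, self.detection_style_probs):
            if abs(sum(styles) - 1.0) > 1e-9:
                raise ValueError("style probabilities must sum to 1")
        missing = set(LATENT_DOMAINS) - set(self.domain_prevalence)
        if missing or set(LATENT_DOMAINS) - set(self.clarity_prob):
            raise ValueError("prevalence/clarity must cover every latent domain")


@dataclass
class GroundTruth:
    """Oracle side-channel: latent statuses and analytic joints."""

    #: trial_id -> {latent domain -> bool status}
    latent_status: dict[str, dict[str, bool]]
    #: latent domain -> 2x3 joint P(pedro in {yes,no} x crob in {L,U,H})
    joints: dict[str, np.ndarray]
    #: latent domain -> {RecodeScheme -> population kappa}
    expected_kappa: dict[str, dict[RecodeScheme, float]]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _rate_crob(
    status: np.ndarray, clear: np.ndarray, cfg: SyntheticConfig, rng
) -> np.ndarray:
    """Vector of rating codes (0=low, 1=unclear, 2=high)."""
    m = status.shape[0]
    err = rng.random(m)
    tracked_low = np.where(status, err >= cfg.crob_error, err < cfg.crob_error)
    rating = np.where(tracked_low, 0, 2)
    commit = rng.random(m) < cfg.unclear_to_rating
    rating = np.where(~clear & ~commit, 1, rating)
    return rating


def _rate_pedro(
    status: np.ndarray, clear: np.ndarray, cfg: SyntheticConfig, rng
) -> np.ndarray:
    err = rng.random(status.shape[0])
    tracked_yes = np.where(status, err >= cfg.pedro_error, err < cfg.pedro_error)
    return (clear & tracked_yes).astype(int)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Draw a full rating dataset (no duplicates) plus its ground truth."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    lo, hi = cfg.trials_per_review
    prev = np.array([cfg.domain_prevalence[d] for d in LATENT_DOMAINS])
    clar = np.array([cfg.clarity_prob[d] for d in LATENT_DOMAINS])
    base_probit = ndtri(np.clip(prev, 1e-12, 1 - 1e-12))

    records: list[TrialRecord] = []
    latent_status: dict[str, dict[str, bool]] = {}
    perf_styles = ("separate", "combined", "triple", "none")
    det_styles = ("plain", "subjective", "objective", "none")

    trial_counter = 0
    for j in range(cfg.n_reviews):
        review_id = f"R{j + 1:04d}"
        m = int(rng.integers(lo, hi + 1))
        u = rng.normal(0.0, cfg.review_effect_sd) if cfg.review_effect_sd else 0.0
        p_review = ndtr(base_probit + u)

        perf = perf_styles[rng.choice(4, p=cfg.performance_style_probs)]
        det = (
            "covered"
            if perf == "triple"
            else det_styles[rng.choice(4, p=cfg.detection_style_probs)]
        )
        assessed = {
            item: rng.random() < p for item, p in cfg.item_assessed_prob.items()
        }

        status = rng.random((m, len(LATENT_DOMAINS))) < p_review
        clear = rng.random((m, len(LATENT_DOMAINS))) < clar
        s_of = {d: status[:, i] for i, d in enumerate(LATENT_DOMAINS)}
        c_of = {d: clear[:, i] for i, d in enumerate(LATENT_DOMAINS)}

        variants: list[str] = [
            v for v in ("sequence_generation", "allocation_concealment",
                        "incomplete_outcome", "selective_reporting", "other_bias")
            if assessed.get(v, True)
        ]
        if perf == "separate":
            variants += ["participants", "personnel"]
        elif perf == "combined":
            variants.append("participants_personnel")
        elif perf == "triple":
            variants.append("participants_personnel_outcome")
        if det == "plain":
            variants.append("outcome_assessment")
        elif det == "subjective":
            variants.append("outcome_subjective")
        elif det == "objective":
            variants.append("outcome_objective")

        crob_codes: dict[str, np.ndarray] = {}
        for v in variants:
            parts = VARIANT_LATENTS[v]
            s = np.logical_and.reduce([s_of[d] for d in parts])
            c = np.logical_and.reduce([c_of[d] for d in parts])
            crob_codes[v] = _rate_crob(s, c, cfg, rng)

        pedro_cols: dict[str, np.ndarray] = {}
        for item, d in PEDRO_LATENTS.items():
            pedro_cols[item] = _rate_pedro(s_of[d], c_of[d], cfg, rng)
        for item, p in cfg.pedro_extra_prevalence.items():
            pedro_cols[item] = (rng.random(m) < p).astype(int)

        for t in range(m):
            trial_counter += 1
            trial_id = f"T{trial_counter:05d}"
            crob = {v: _RATING_CODES[crob_codes[v][t]] for v in variants}
            pedro = {item: int(col[t]) for item, col in pedro_cols.items()}
            records.append(
                TrialRecord(
                    trial_id=trial_id,
                    review_id=review_id,
                    crob=crob,
                    pedro=pedro,
                    occurrence_index=1,
                )
            )
            latent_status[trial_id] = {
                d: bool(s_of[d][t]) for d in LATENT_DOMAINS
            }

    joints: dict[str, np.ndarray] = {}
    kappas: dict[str, dict[RecodeScheme, float]] = {}
    for d in LATENT_DOMAINS:
        oracle = analytic_joint_distribution(cfg, d)
        joints[d] = oracle.joint
        kappas[d] = oracle.expected_kappa
    return records, GroundTruth(latent_status, joints, kappas)


def inject_duplicates(
    records: Sequence[TrialRecord], config: SyntheticConfig
) -> list[TrialRecord]:
    """Append second-review ratings for a fraction of trials.

    A ``duplicate_fraction`` share of trials is re-rated by a randomly
    chosen different review: each assessed CROB item independently
    moves to one of the other two categories with probability
    ``duplicate_error``; PEDro ratings are trial-level database scores
    and are carried over unchanged.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    records = list(records)
    n_dup = int(math.floor(cfg.duplicate_fraction * len(records)))
    if n_dup < 1:
        if cfg.duplicate_fraction > 0:
            warnings.warn(
                "duplicate_fraction too small for this dataset; "
                "no duplicates injected",
                stacklevel=2,
            )
        return records
    review_ids = sorted({r.review_id for r in records})
    chosen = rng.choice(len(records), size=n_dup, replace=False)
    out = records.copy()
    for i in sorted(chosen):
        orig = records[i]
        others = [rid for rid in review_ids if rid != orig.review_id]
        new_review = others[int(rng.integers(len(others)))]
        crob: dict[str, CrobRating] = {}
        for v, rating in orig.crob.items():
            if rating is CrobRating.NOT_ASSESSED:
                crob[v] = rating
                continue
            if rng.random() < cfg.duplicate_error:
                alternatives = [r for r in _RATING_CODES if r is not rating]
                crob[v] = alternatives[int(rng.integers(2))]
            else:
                crob[v] = rating
        out.append(
            TrialRecord(
                trial_id=orig.trial_id,
                review_id=new_review,
                crob=crob,
                pedro=dict(orig.pedro),
                occurrence_index=2,
            )
        )
    return out


def generate_study(
    config: SyntheticConfig,
) -> tuple[list[TrialRecord], GroundTruth]:
    """Full study draw: dataset plus injected cross-review duplicates."""
    records, truth = generate_dataset(config)
    return inject_duplicates(records, config), truth


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticJoint:
    """Exact joint (PEDro x CROB) for one latent domain."""

    domain: str
    #: 2x3 array, rows PEDro (yes, no), cols CROB (low, unclear, high)
    joint: np.ndarray
    expected_kappa: dict[RecodeScheme, float]


def _joint_at_prevalence(p: float, cfg: SyntheticConfig, clarity: float) -> np.ndarray:
    e, ep, q = cfg.crob_error, cfg.pedro_error, cfg.unclear_to_rating
    joint = np.zeros((2, 3))
    for s, ps in ((1, p), (0, 1.0 - p)):
        low_track = (1.0 - e) if s else e
        pedro_yes_track = (1.0 - ep) if s else ep
        for c, pc in ((1, clarity), (0, 1.0 - clarity)):
            if pc == 0.0:
                continue
            if c:
                crob = np.array([low_track, 0.0, 1.0 - low_track])
                py = pedro_yes_track
            else:
                crob = np.array(
                    [q * low_track, 1.0 - q, q * (1.0 - low_track)]
                )
                py = 0.0
            joint += ps * pc * np.outer([py, 1.0 - py], crob)
    return joint


def expected_kappa_from_joint(
    joint: np.ndarray, scheme: RecodeScheme
) -> float:
    """Population kappa of the recoded 2x2 distribution.

    Cohen's kappa is scale-invariant, so the count formula applies
    directly to cell probabilities.  SENS2 conditions on the CROB
    rating not being unclear (pairwise deletion in the population).
    """
    joint = np.asarray(joint, dtype=float)
    if scheme is RecodeScheme.MAIN:
        two = np.stack([joint[:, 0], joint[:, 1] + joint[:, 2]], axis=1)
    elif scheme is RecodeScheme.SENS1:
        two = np.stack([joint[:, 0] + joint[:, 1], joint[:, 2]], axis=1)
    else:
        two = joint[:, [0, 2]]
        mass = two.sum()
        if mass <= 0:
            return float("nan")
        two = two / mass
    return cohen_kappa(two)


def analytic_joint_distribution(
    config: SyntheticConfig, domain: str, n_quad: int = 41
) -> AnalyticJoint:
    """Exact joint distribution and population kappa for one domain.

    Marginalizes the generative model by finite enumeration over
    (latent status, clarity, rating outcome), integrating the
    review-level probit effect with ``n_quad``-point Gauss-Hermite
    quadrature.  ``domain`` is a latent domain name; single-latent CROB
    variants of that domain share this joint.
    """
    if domain not in LATENT_DOMAINS:
        raise KeyError(f"unknown latent domain {domain!r}")
    cfg = config
    p0 = cfg.domain_prevalence[domain]
    clarity = cfg.clarity_prob[domain]
    if cfg.review_effect_sd == 0:
        joint = _joint_at_prevalence(p0, cfg, clarity)
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        weights = weights / math.sqrt(2.0 * math.pi)
        base = ndtri(min(max(p0, 1e-12), 1 - 1e-12))
        joint = np.zeros((2, 3))
        for x, w in zip(nodes, weights):
            p = float(ndtr(base + cfg.review_effect_sd * x))
            joint += w * _joint_at_prevalence(p, cfg, clarity)
        joint /= joint.sum()
    kappas = {
        scheme: expected_kappa_from_joint(joint, scheme)
        for scheme in RecodeScheme
    }
    return AnalyticJoint(domain, joint, kappas)
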