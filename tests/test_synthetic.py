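import dataclasses
import math

import numpy as np
import pytest

from robagree import (
    CrobRating,
    RecodeScheme,
    SyntheticConfig,
    analytic_joint_distribution,
    generate_dataset,
    inject_duplicates,
)
from robagree.agreement import kappa_variance
from robagree.io import records_to_frame
from robagree.pipeline import _cluster_tables_2x2, _pair_data, PairSpec
from robagree.synthetic import LATENT_DOMAINS


def noiseless_config(**overrides):
    base = dict(
        n_reviews=10,
        crob_error=0.0,
        pedro_error=0.0,
        clarity_prob={d: 1.0 for d in LATENT_DOMAINS},
        seed=2,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            SyntheticConfig(crob_error=1.5)

    def test_bad_trial_range_rejected(self):
        with pytest.raises(ValueError, match="trials_per_review"):
            SyntheticConfig(trials_per_review=(10, 5))

    def test_style_probs_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticConfig(performance_style_probs=(0.5, 0.5, 0.5, 0.0))


class TestGenerateDataset:
    def test_same_config_and_seed_identical_datasets(self):
        cfg = SyntheticConfig(n_reviews=8, seed=77)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(cfg)
        assert records_to_frame(a).equals(records_to_frame(b))

    def test_review_sizes_within_configured_range(self):
        cfg = SyntheticConfig(n_reviews=30, trials_per_review=(7, 22), seed=1)
        records, _ = generate_dataset(cfg)
        sizes = records_to_frame(records).groupby("review_id").size()
        assert sizes.between(7, 22).all()

    def test_noiseless_limit_gives_perfect_item_agreement(self):
        records, _ = generate_dataset(noiseless_config())
        pedro, crob01, _ = _pair_data(
            records,
            PairSpec("concealed_allocation", ("allocation_concealment",)),
        )
        assert pedro.size > 0
        assert np.array_equal(pedro, crob01)

    def test_unclear_fraction_matches_clarity_channel(self):
        # clarity 0.5 and no commit-to-rating channel: the unclear
        # share of CROB ratings is Binomial(n, 0.5).
        cfg = SyntheticConfig(
            n_reviews=60,
            trials_per_review=(30, 40),
            clarity_prob={d: 0.5 for d in LATENT_DOMAINS},
            unclear_to_rating=0.0,
            review_effect_sd=0.0,
            seed=5,
        )
        records, _ = generate_dataset(cfg)
        ratings = [
            rec.crob["allocation_concealment"]
            for rec in records
            if "allocation_concealment" in rec.crob
        ]
        n = len(ratings)
        assert n > 1500
        frac = sum(r is CrobRating.UNCLEAR for r in ratings) / n
        se = math.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_marginal_shapes_match_intended_calibration(self):
        """Defaults emulate physiotherapy trials: participant/therapist
        blinding rare, assessor blinding about a third, allocation
        concealment dominated by unclear ratings."""
        cfg = SyntheticConfig(n_reviews=80, seed=42)
        records, _ = generate_dataset(cfg)
        n = len(records)
        subject = sum(r.pedro["subject_blinding"] for r in records) / n
        therapist = sum(r.pedro["therapist_blinding"] for r in records) / n
        assessor = sum(r.pedro["assessor_blinding"] for r in records) / n
        conceal = [r.crob["allocation_concealment"] for r in records]
        unclear_frac = sum(r is CrobRating.UNCLEAR for r in conceal) / len(conceal)
        assert subject < 0.15
        assert therapist < 0.10
        assert 0.20 < assessor < 0.45
        assert unclear_frac > 0.40


class TestAnalyticJoint:
    def test_joint_sums_to_one(self):
        oracle = analytic_joint_distribution(SyntheticConfig(), "other_bias")
        assert oracle.joint.sum() == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_main_kappa_is_one(self):
        oracle = analytic_joint_distribution(
            noiseless_config(), "allocation_concealment"
        )
        assert oracle.expected_kappa[RecodeScheme.MAIN] == pytest.approx(1.0)

    def test_uninformative_pedro_gives_zero_kappa(self):
        # with clear reporting everywhere and pedro_error = 0.5 the
        # PEDro rating is an independent coin flip
        cfg = noiseless_config(pedro_error=0.5, crob_error=0.05)
        oracle = analytic_joint_distribution(cfg, "sequence_generation")
        for scheme in RecodeScheme:
            assert oracle.expected_kappa[scheme] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_domain_rejected(self):
        with pytest.raises(KeyError):
            analytic_joint_distribution(SyntheticConfig(), "bogus")

    def test_monte_carlo_agrees_with_analytic_kappa(self):
        """Empirical kappa at ~50k trials falls within 3 SEs of the
        closed-form value (iid regime: no review effect)."""
        cfg = SyntheticConfig(
            n_reviews=100,
            trials_per_review=(480, 520),
            review_effect_sd=0.0,
            seed=13,
        )
        records, _ = generate_dataset(cfg)
        oracle = analytic_joint_distribution(cfg, "allocation_concealment")
        pedro, crob01, review = _pair_data(
            records,
            PairSpec("concealed_allocation", ("allocation_concealment",)),
        )
        table = _cluster_tables_2x2(pedro, crob01, review).sum(axis=0)
        from robagree import cohen_kappa

        emp = cohen_kappa(table)
        se = math.sqrt(kappa_variance(table))
        assert abs(emp - oracle.expected_kappa[RecodeScheme.MAIN]) < 3 * se

    def test_kappa_strictly_decreases_with_crob_error(self):
        cfg = SyntheticConfig()
        kappas = [
            analytic_joint_distribution(
                dataclasses.replace(cfg, crob_error=e), "allocation_concealment"
            ).expected_kappa[RecodeScheme.MAIN]
            for e in (0.0, 0.05, 0.1, 0.2, 0.35)
        ]
        assert all(a > b for a, b in zip(kappas, kappas[1:]))

    def test_review_effect_integration_matches_zero_sd_limit(self):
        cfg0 = SyntheticConfig(review_effect_sd=0.0)
        cfg_small = SyntheticConfig(review_effect_sd=1e-8)
        a = analytic_joint_distribution(cfg0, "selective_reporting").joint
        b = analytic_joint_distribution(cfg_small, "selective_reporting").joint
        assert np.allclose(a, b, atol=1e-9)


class TestInjectDuplicates:
    def test_zero_fraction_is_identity(self):
        cfg = SyntheticConfig(n_reviews=8, duplicate_fraction=0.0, seed=3)
        records, _ = generate_dataset(cfg)
        assert inject_duplicates(records, cfg) == records

    def test_duplicate_count_arithmetic(self):
        cfg = SyntheticConfig(
            n_reviews=100,
            trials_per_review=(15, 15),
            duplicate_fraction=0.05,
            seed=9,
        )
        records, _ = generate_dataset(cfg)
        assert len(records) == 1500
        augmented = inject_duplicates(records, cfg)
        assert len(augmented) == 1575

    def test_duplicates_get_second_occurrence_and_other_review(self):
        cfg = SyntheticConfig(n_reviews=10, duplicate_fraction=0.2, seed=4)
        records, _ = generate_dataset(cfg)
        augmented = inject_duplicates(records, cfg)
        originals = {r.trial_id: r for r in records}
        dups = [r for r in augmented if r.occurrence_index == 2]
        assert dups
        for dup in dups:
            assert dup.review_id != originals[dup.trial_id].review_id
            assert dup.pedro == originals[dup.trial_id].pedro

    def test_tiny_fraction_warns_and_adds_nothing(self):
        cfg = SyntheticConfig(
            n_reviews=2,
            trials_per_review=(2, 2),
            duplicate_fraction=0.01,
            seed=6,
        )
        records, _ = generate_dataset(cfg)
        with pytest.warns(UserWarning, match="no duplicates"):
            augmented = inject_duplicates(records, cfg)
        assert augmented == records
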