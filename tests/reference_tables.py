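"""Published summary tables from a large convergent-validity study of
the two instruments (1442 physiotherapy trials drawn from 108 Cochrane
reviews), frozen here as consistency oracles for the recoding
arithmetic and the contingency-table reconstruction utility.

Only printed marginal counts and point estimates are stored; nothing
here feeds the implementation.
"""

# Per-variant counts of trials rated low / unclear / high.
CROB_MARGINALS: dict[str, tuple[int, int, int]] = {
    "sequence_generation": (738, 603, 100),
    "allocation_concealment": (517, 799, 122),
    "participants_personnel": (82, 81, 438),
    "participants": (75, 78, 385),
    "personnel": (51, 52, 312),
    "outcome_assessment": (318, 375, 388),
    "outcome_subjective": (20, 8, 54),
    "outcome_objective": (57, 33, 18),
    "participants_personnel_outcome": (72, 94, 52),
    "incomplete_outcome": (743, 339, 350),
    "selective_reporting": (628, 517, 169),
    "other_bias": (490, 273, 109),
}

# Transformed counts coded "1" and integer display percentages under
# the main scheme and the two sensitivity schemes:
# variant -> (main_n1, main_pct, sens1_n1, sens1_pct, sens2_n1, sens2_pct)
TRANSFORMED_COUNTS: dict[str, tuple[int, int, int, int, int, int]] = {
    "sequence_generation": (738, 51, 1341, 93, 738, 88),
    "allocation_concealment": (517, 36, 1316, 92, 517, 81),
    "participants_personnel": (82, 14, 163, 27, 82, 16),
    "participants": (75, 14, 153, 28, 75, 16),
    "personnel": (51, 12, 103, 25, 51, 14),
    "outcome_assessment": (318, 29, 693, 64, 318, 45),
    "outcome_subjective": (20, 24, 28, 34, 20, 27),
    "outcome_objective": (57, 53, 90, 83, 57, 76),
    "participants_personnel_outcome": (72, 33, 166, 76, 72, 58),
    "incomplete_outcome": (743, 52, 1082, 76, 743, 68),
    "selective_reporting": (628, 48, 1145, 87, 628, 79),
    "other_bias": (490, 56, 763, 88, 490, 82),
}

# Yes-counts for the 11 PEDro items over all 1442 trials.
PEDRO_YES_COUNTS: dict[str, int] = {
    "eligibility": 1170,
    "random_allocation": 1399,
    "concealed_allocation": 473,
    "baseline_comparability": 1153,
    "subject_blinding": 70,
    "therapist_blinding": 26,
    "assessor_blinding": 529,
    "follow_up": 877,
    "intention_to_treat": 465,
    "between_group": 1372,
    "point_estimates": 1311,
}

PEDRO_N_TRIALS = 1442

# Main-scheme item-pair results: pedro item, crob variant,
# n, percent exact agreement, kappa.
MAIN_PAIR_RESULTS: list[tuple[str, str, int, float, float]] = [
    ("random_allocation", "sequence_generation", 1441, 53.8, 0.054),
    ("concealed_allocation", "allocation_concealment", 1438, 81.2, 0.582),
    ("subject_blinding", "participants", 538, 90.7, 0.479),
    ("therapist_blinding", "personnel", 415, 89.2, 0.251),
    ("assessor_blinding", "outcome_assessment", 1081, 78.8, 0.519),
    ("follow_up", "incomplete_outcome", 1432, 63.0, 0.254),
]
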