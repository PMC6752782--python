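import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import cohens_kappa as sm_cohens_kappa

from robagree import (
    InconsistentTableError,
    UndefinedReplicatesError,
    cluster_bootstrap_ci,
    cluster_bootstrap_table_ci,
    cohen_kappa,
    icc_oneway,
    interpret_label,
    kappa_normal_ci,
    percent_exact_agreement,
    reconstruct_two_by_two,
)
from robagree.agreement import icc_oneway_f_ci, kappa_variance


def brute_force_kappa(table):
    """Independent oracle: explicit double loops over categories."""
    table = np.asarray(table, dtype=float)
    k = table.shape[0]
    n = table.sum()
    po = 0.0
    for i in range(k):
        po += table[i, i] / n
    pe = 0.0
    for i in range(k):
        row_i = sum(table[i, j] for j in range(k))
        col_i = sum(table[j, i] for j in range(k))
        pe += (row_i / n) * (col_i / n)
    if abs(1.0 - pe) < 1e-12:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def brute_force_icc(x, y):
    """Independent one-way ANOVA oracle with explicit sums."""
    n = len(x)
    k = 2
    values = [xi for xi in x] + [yi for yi in y]
    grand = sum(values) / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for i in range(n):
        m_i = (x[i] + y[i]) / 2.0
        ss_between += k * (m_i - grand) ** 2
        ss_within += (x[i] - m_i) ** 2 + (y[i] - m_i) ** 2
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1))
    if msb + msw == 0:
        return float("nan")
    return (msb - msw) / (msb + (k - 1) * msw)


class TestPercentAgreement:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[5, 0], [0, 5]], 100.0),
            ([[0, 5], [5, 0]], 0.0),
            ([[360, 113], [157, 808]], 100.0 * (360 + 808) / 1438),
        ],
    )
    def test_examples(self, table, expected):
        assert percent_exact_agreement(table) == pytest.approx(expected)

    def test_empty_table_undefined(self):
        assert math.isnan(percent_exact_agreement([[0, 0], [0, 0]]))


class TestCohenKappa:
    def test_perfect_diagonal(self):
        assert cohen_kappa([[5, 0], [0, 5]]) == pytest.approx(1.0)

    def test_independence_table(self):
        # P_o = P_e = 0.18, so kappa is exactly zero
        assert cohen_kappa([[9, 1], [81, 9]]) == pytest.approx(0.0, abs=1e-12)

    def test_reconstructed_concealment_table(self):
        table = [[360, 113], [157, 808]]
        assert cohen_kappa(table) == pytest.approx(
            brute_force_kappa(table), abs=1e-14
        )

    def test_degenerate_single_category_not_calculable(self):
        assert math.isnan(cohen_kappa([[7, 0], [0, 0]]))

    def test_kappa_never_exceeds_one_and_one_iff_diagonal(self, rng):
        for _ in range(200):
            t = rng.integers(0, 30, size=(3, 3))
            if t.sum() == 0:
                continue
            k = cohen_kappa(t)
            if math.isnan(k):
                continue
            assert k <= 1.0 + 1e-12
            off_diag = t.sum() - np.trace(t)
            if k == pytest.approx(1.0):
                assert off_diag == 0

    def test_matches_statsmodels_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 40, size=(3, 3)) + np.eye(3, dtype=int)
            ours = cohen_kappa(t)
            theirs = sm_cohens_kappa(t, return_results=False)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_variance_matches_statsmodels(self, rng):
        for _ in range(25):
            t = rng.integers(1, 40, size=(2, 2))
            res = sm_cohens_kappa(t)
            assert kappa_variance(t) == pytest.approx(
                res.var_kappa, rel=1e-10
            )

    def test_normal_ci_matches_statsmodels(self):
        t = [[360, 113], [157, 808]]
        res = sm_cohens_kappa(t)
        lo, hi = kappa_normal_ci(t)
        assert lo == pytest.approx(res.kappa_low, abs=1e-9)
        assert hi == pytest.approx(res.kappa_upp, abs=1e-9)


class TestIccOneWay:
    def test_identical_scores_give_one(self):
        x = [0.0, 10.0, 20.0, 50.0]
        assert icc_oneway(x, x) == pytest.approx(1.0)

    def test_crossed_pairs_give_minus_one(self):
        # MSB = 0 so ICC = -MSW / MSW
        assert icc_oneway([0.0, 10.0], [10.0, 0.0]) == pytest.approx(-1.0)

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.normal(size=n) * 10
            y = x + rng.normal(size=n) * rng.uniform(0.1, 5)
            assert icc_oneway(x, y) == pytest.approx(
                brute_force_icc(list(x), list(y)), rel=1e-12
            )

    def test_zero_variance_undefined(self):
        assert math.isnan(icc_oneway([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]))

    def test_decreases_with_error_variance(self, rng):
        subjects = rng.normal(size=200) * 10
        iccs = []
        for sd in (0.5, 2.0, 5.0, 10.0):
            noise = np.random.default_rng(99).normal(size=200) * sd
            iccs.append(icc_oneway(subjects, subjects + noise))
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_f_ci_brackets_point_estimate(self, rng):
        x = rng.normal(size=50) * 10
        y = x + rng.normal(size=50)
        icc = icc_oneway(x, y)
        lo, hi = icc_oneway_f_ci(x, y)
        assert lo < icc < hi


class TestInterpretLabel:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (-0.04, "poor"),
            (0.0, "slight"),
            (0.054, "slight"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.328, "fair"),
            (0.40, "fair"),
            (0.479, "moderate"),
            (0.582, "moderate"),
            (0.60, "moderate"),
            (0.686, "substantial"),
            (0.80, "substantial"),
            (0.818, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_kappa_bands(self, value, expected):
        assert interpret_label(value, "kappa") == expected

    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.285, "poor"),
            (-0.150, "poor"),
            (0.40, "fair to good"),
            (0.711, "fair to good"),
            (0.75, "fair to good"),
            (0.76, "excellent"),
        ],
    )
    def test_icc_bands(self, value, expected):
        assert interpret_label(value, "icc") == expected

    def test_nan_is_not_calculable(self):
        assert interpret_label(float("nan"), "kappa") == "not calculable"

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            interpret_label(0.5, "rho")


class TestReconstructTwoByTwo:
    def test_perfect_agreement(self):
        table = reconstruct_two_by_two(10, 100.0, 5, 5)
        assert table.tolist() == [[5, 0], [0, 5]]

    def test_concealment_row(self):
        table = reconstruct_two_by_two(1438, 81.2, 473, 517)
        assert table.tolist() == [[360, 113], [157, 808]]

    def test_infeasible_input_rejected(self):
        with pytest.raises(InconsistentTableError):
            reconstruct_two_by_two(10, 0.0, 9, 9)

    @given(
        a=st.integers(0, 200),
        b=st.integers(0, 200),
        c=st.integers(0, 200),
        d=st.integers(0, 200),
    )
    def test_round_trip_from_exact_summaries(self, a, b, c, d):
        n = a + b + c + d
        if n == 0:
            return
        pct = 100.0 * (a + d) / n
        table = reconstruct_two_by_two(n, pct, a + b, a + c)
        assert table.tolist() == [[a, b], [c, d]]


class TestClusterBootstrap:
    @staticmethod
    def _df(rng, n_clusters=10, per=8):
        return pd.DataFrame(
            {
                "review": np.repeat([f"r{i}" for i in range(n_clusters)], per),
                "value": rng.normal(size=n_clusters * per),
            }
        )

    def test_constant_statistic_gives_degenerate_interval(self, rng):
        ci = cluster_bootstrap_ci(
            self._df(rng), lambda d: 3.25, "review", n_boot=100, seed=0
        )
        assert (ci.low, ci.high) == (3.25, 3.25)

    def test_same_seed_identical_interval(self, rng):
        df = self._df(rng)
        stat = lambda d: float(d["value"].mean())
        a = cluster_bootstrap_ci(df, stat, "review", n_boot=200, seed=9)
        b = cluster_bootstrap_ci(df, stat, "review", n_boot=200, seed=9)
        assert (a.low, a.high) == (b.low, b.high)

    def test_endpoints_bracket_median_replicate(self, rng):
        df = self._df(rng)
        stat = lambda d: float(d["value"].mean())
        ci = cluster_bootstrap_ci(df, stat, "review", n_boot=500, seed=2)
        assert ci.low <= stat(df) + 1.0  # sanity scale check
        assert ci.low <= ci.high

    def test_single_cluster_rejected(self, rng):
        df = self._df(rng, n_clusters=1)
        with pytest.raises(ValueError, match="2 clusters"):
            cluster_bootstrap_ci(df, lambda d: 0.0, "review", n_boot=10)

    def test_mostly_undefined_statistic_errors(self, rng):
        df = self._df(rng)
        with pytest.raises(UndefinedReplicatesError):
            cluster_bootstrap_ci(
                df, lambda d: float("nan"), "review", n_boot=50, seed=1
            )

    def test_table_bootstrap_deterministic_and_ordered(self, rng):
        tables = rng.integers(0, 10, size=(12, 2, 2))
        a = cluster_bootstrap_table_ci(tables, "kappa", n_boot=400, seed=5)
        b = cluster_bootstrap_table_ci(tables, "kappa", n_boot=400, seed=5)
        assert (a.low, a.high) == (b.low, b.high)
        assert a.low <= a.high

    def test_table_and_row_bootstrap_agree_in_location(self, rng):
        """The vectorized table route and the generic row route target
        the same resampling distribution."""
        n_clusters, per = 30, 20
        review = np.repeat(np.arange(n_clusters), per)
        x = rng.integers(0, 2, size=n_clusters * per)
        y = np.where(rng.random(n_clusters * per) < 0.7, x, 1 - x)
        df = pd.DataFrame({"review": review, "x": x, "y": y})

        def stat(d):
            t = np.zeros((2, 2))
            np.add.at(t, (1 - d["x"].to_numpy(), 1 - d["y"].to_numpy()), 1)
            return cohen_kappa(t)

        generic = cluster_bootstrap_ci(df, stat, "review", n_boot=800, seed=3)
        tables = np.zeros((n_clusters, 2, 2), dtype=int)
        np.add.at(tables, (review, 1 - x, 1 - y), 1)
        fast = cluster_bootstrap_table_ci(tables, "kappa", n_boot=800, seed=3)
        assert fast.low == pytest.approx(generic.low, abs=0.05)
        assert fast.high == pytest.approx(generic.high, abs=0.05)
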