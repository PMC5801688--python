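import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phimarker.association import (
    RESISTANCE,
    SENSITIVITY,
    AssociationData,
    ContingencyTable,
    bh_fdr,
    build_contingency,
    chi2_pvalue,
    chi2_statistic,
    compute_threshold,
    phi_coefficient,
    phi_significance_cutoff,
    score_association,
)
from phimarker.exceptions import UndefinedStatisticError


# -- contingency tables with all marginals positive ------------------------
valid_tables = st.tuples(
    st.integers(0, 200), st.integers(0, 200),
    st.integers(0, 200), st.integers(0, 200),
).filter(
    lambda t: min(t[0] + t[1], t[1] + t[3], t[3] + t[2], t[2] + t[0]) > 0
).map(lambda t: ContingencyTable(*t))


class TestThreshold:
    def test_symmetric_midpoint_sensitivity(self):
        d = AssociationData([-2, -2, 0, 0], [1, 1, 0, 0])
        t = compute_threshold(d)
        assert (t.med_mt, t.med_wt, t.threshold) == (-2, 0, -1)
        assert t.direction == SENSITIVITY

    def test_even_count_median_midpoint_resistance(self):
        d = AssociationData([1, 3, 0, 0], [1, 1, 0, 0])
        t = compute_threshold(d)
        assert (t.med_mt, t.med_wt, t.threshold) == (2, 0, 1)
        assert t.direction == RESISTANCE

    def test_degenerate_tie_falls_to_resistance(self):
        d = AssociationData([0, 0, 0, 0], [1, 0, 1, 0])
        t = compute_threshold(d)
        assert t.threshold == 0
        assert t.direction == RESISTANCE
        assert t.degenerate

    def test_group_required_on_both_sides(self):
        with pytest.raises(ValueError):
            AssociationData([1.0, 2.0], [1, 1])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5))
    def test_shift_invariance(self, seed, c):
        """Adding a constant to all responses shifts the medians and the
        threshold by that constant and leaves table/phi/chi2/p unchanged."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        y = rng.normal(0, 1, n)
        flags = np.zeros(n, dtype=int)
        flags[: int(rng.integers(1, n - 1))] = 1
        rng.shuffle(flags)
        a = score_association(AssociationData(y, flags))
        b = score_association(AssociationData(y + c, flags))
        assert b.threshold.threshold == pytest.approx(a.threshold.threshold + c)
        assert b.table == a.table
        assert b.phi == pytest.approx(a.phi)
        assert b.chi2 == pytest.approx(a.chi2)
        assert b.p == pytest.approx(a.p)


class TestContingency:
    def test_perfect_separation(self):
        d = AssociationData([-2, -2, 0, 0], [1, 1, 0, 0])
        t = compute_threshold(d)
        table = build_contingency(d, t)
        assert (table.tp, table.fp, table.fn, table.tn) == (2, 0, 0, 2)

    def test_degenerate_all_observed_positive_under_ge_rule(self):
        # every response sits exactly at the threshold; the resistance
        # branch counts >= as positive, so all four cells are positives
        d = AssociationData([0, 0, 0, 0], [1, 0, 1, 0])
        table = build_contingency(d, compute_threshold(d))
        assert (table.tp, table.fn, table.fp, table.tn) == (2, 2, 0, 0)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_counts_partition_n_and_pp_is_mutant_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.normal(0, 1, n)
        flags = np.zeros(n, dtype=int)
        flags[: int(rng.integers(1, n - 1))] = 1
        rng.shuffle(flags)
        d = AssociationData(y, flags)
        table = build_contingency(d, compute_threshold(d))
        assert table.n == n
        assert table.pp == d.n_mutated

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_phi_nonnegative_when_medians_differ(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = rng.normal(0, 1, n)
        flags = np.zeros(n, dtype=int)
        flags[: int(rng.integers(1, n - 1))] = 1
        rng.shuffle(flags)
        d = AssociationData(y, flags)
        t = compute_threshold(d)
        if t.degenerate:
            return
        assert phi_coefficient(build_contingency(d, t)) >= 0.0


class TestPhi:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (ContingencyTable(10, 0, 0, 10), 1.0),
            (ContingencyTable(5, 5, 5, 5), 0.0),
            (ContingencyTable(8, 2, 2, 8), 0.6),  # (64-4)/sqrt(10^4)
        ],
    )
    def test_examples(self, table, expected):
        assert phi_coefficient(table) == pytest.approx(expected)

    def test_zero_marginal_raises(self):
        with pytest.raises(UndefinedStatisticError):
            phi_coefficient(ContingencyTable(2, 2, 0, 0))

    @settings(deadline=None, derandomize=True)
    @given(valid_tables)
    def test_bounded_and_label_swap_antisymmetry(self, t):
        phi = phi_coefficient(t)
        assert -1.0 <= phi <= 1.0
        swapped = ContingencyTable(tp=t.fn, fn=t.tp, fp=t.tn, tn=t.fp)
        assert phi_coefficient(swapped) == pytest.approx(-phi)


class TestChi2:
    def test_observed_equals_expected_gives_zero(self):
        assert chi2_statistic(ContingencyTable(5, 5, 5, 5)) == pytest.approx(0.0)

    def test_oe_sum_example(self):
        # n * phi^2 = 20 * 0.36, cross-checked by the O/E sum route
        assert chi2_statistic(ContingencyTable(8, 2, 2, 8)) == pytest.approx(7.2)

    @settings(deadline=None, derandomize=True)
    @given(valid_tables)
    def test_identity_chi2_equals_n_phi_squared(self, t):
        chi2 = chi2_statistic(t)
        identity = t.n * phi_coefficient(t) ** 2
        assert chi2 == pytest.approx(identity, rel=1e-10, abs=1e-12)

    def test_zero_expected_count_raises(self):
        with pytest.raises(UndefinedStatisticError):
            chi2_statistic(ContingencyTable(0, 5, 0, 5))


class TestChi2Pvalue:
    def test_zero_statistic_full_tail(self):
        assert chi2_pvalue(0.0) == 1.0

    def test_textbook_critical_value(self):
        assert chi2_pvalue(3.841) == pytest.approx(0.05, abs=2e-4)

    def test_strong_marker_example(self):
        # n = 284 cells, phi = 0.65: a p-value of ~6.4e-28, far below
        # where 1 - cdf would underflow
        p = chi2_pvalue(284 * 0.65**2)
        assert p == pytest.approx(6.4e-28, rel=0.01)

    def test_extreme_statistics_stay_representable(self):
        assert 0.0 < chi2_pvalue(1400.0) < 1e-300

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-0.1)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 500), st.floats(1e-6, 100))
    def test_strictly_decreasing_in_chi2(self, x, eps):
        assert chi2_pvalue(x + eps) < chi2_pvalue(x)


def bh_oracle(pvalues, q):
    """Independent step-up formulation: p_i is significant iff some
    observed p-value t satisfies p_i <= t and t <= (#{p <= t}) * q / m."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    sig = np.zeros(m, dtype=bool)
    for i in range(m):
        for t in p:
            if p[i] <= t and t <= np.sum(p <= t) * q / m:
                sig[i] = True
                break
    return sig


class TestBHFDR:
    def test_worked_step_up(self):
        mask, crit = bh_fdr([0.001, 0.01, 0.02, 0.5], q=0.2)
        assert mask.tolist() == [True, True, True, False]
        assert crit == 0.02  # 0.02 <= 3 * 0.2 / 4

    def test_all_ones_nothing_significant(self):
        mask, crit = bh_fdr([1.0] * 5, q=0.2)
        assert not mask.any()
        assert math.isnan(crit)

    def test_single_test_reduces_to_plain_level(self):
        mask, crit = bh_fdr([0.04], q=0.2)
        assert mask.tolist() == [True]
        assert crit == 0.04

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.2)

    def test_matches_exhaustive_oracle_on_grid(self):
        grid = [0.001, 0.02, 0.04, 0.2, 1.0]
        q = 0.2
        for length in range(1, 6):
            for combo in itertools.product(grid, repeat=length):
                mask, _ = bh_fdr(combo, q)
                np.testing.assert_array_equal(mask, bh_oracle(combo, q))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            mask, _ = bh_fdr(p, 0.2)
            ref = multipletests(p, alpha=0.2, method="fdr_bh")[0]
            np.testing.assert_array_equal(mask, ref)


class TestPhiCutoff:
    def test_published_critical_value_reproduces_cutoffs(self):
        assert round(phi_significance_cutoff(300, 0.00940155), 2) == 0.15
        assert round(phi_significance_cutoff(450, 0.00940155), 2) == 0.12

    def test_quadrupling_n_halves_cutoff(self):
        c1 = phi_significance_cutoff(100, 0.01)
        c2 = phi_significance_cutoff(400, 0.01)
        assert c2 == pytest.approx(c1 / 2)

    def test_cutoff_is_sharp(self):
        # any table with this n and phi >= cutoff is significant
        n, crit_p = 300, 0.00940155
        cutoff = phi_significance_cutoff(n, crit_p)
        assert chi2_pvalue(n * cutoff**2) == pytest.approx(crit_p, rel=1e-9)
        assert chi2_pvalue(n * (cutoff * 1.01) ** 2) < crit_p


def test_phi_and_log_p_rank_identically_at_fixed_n():
    """For associations sharing n, phi and -log p are perfectly rank
    correlated (the chi2 = n phi^2 duality)."""
    rng = np.random.default_rng(21)
    n = 80
    phis, logps = [], []
    for _ in range(60):
        y = rng.normal(0, 1, n)
        flags = np.zeros(n, dtype=int)
        flags[: int(rng.integers(5, n - 5))] = 1
        rng.shuffle(flags)
        r = score_association(AssociationData(y, flags))
        phis.append(r.phi)
        logps.append(-math.log(r.p))
    rho = stats.spearmanr(phis, logps).statistic
    assert rho == pytest.approx(1.0)
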