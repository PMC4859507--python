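"""Rank statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fiberquant as fq
from fiberquant import stats as fstats
from fiberquant.design import generate_cohort
from fiberquant.exceptions import InsufficientPairsError
from fiberquant.section import MYHC_CHANNELS


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation under test)
# ---------------------------------------------------------------------------

def average_ranks(values):
    """Average ranks computed by explicit sorting and tie grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_h(groups):
    """Tie-corrected Kruskal-Wallis H from the textbook formula."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = average_ranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += sum(r) ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for v in pooled:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction else 0.0


def brute_force_exact_p(groups):
    """Exhaustive permutation null of H over all group reassignments."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = brute_force_h(groups)
    count = total = 0
    for perm in set(itertools.permutations(pooled)):
        regrouped, start = [], 0
        for s in sizes:
            regrouped.append(perm[start:start + s])
            start += s
        total += 1
        if brute_force_h(regrouped) >= h_obs - 1e-12:
            count += 1
    return count / total


def brute_force_spearman(a, b):
    """Pearson correlation of average ranks, by the definition."""
    ra, rb = average_ranks(list(a)), average_ranks(list(b))
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    da = math.sqrt(sum((x - ma) ** 2 for x in ra))
    db = math.sqrt(sum((y - mb) ** 2 for y in rb))
    return num / (da * db)


def brute_force_t(diffs):
    n = len(diffs)
    mean = sum(diffs) / n
    sd = math.sqrt(sum((d - mean) ** 2 for d in diffs) / (n - 1))
    return mean / (sd / math.sqrt(n))


# ---------------------------------------------------------------------------
# sorted_profile / ecdf
# ---------------------------------------------------------------------------

def frac_table(values_2b, values_2x=None):
    n = len(values_2b)
    table = pd.DataFrame({"fiber_id": np.arange(1, n + 1)})
    rest = (
        np.asarray(values_2x)
        if values_2x is not None
        else np.linspace(0.1, 0.9, n)
    )
    table["frac_myhc_2b"] = values_2b
    table["frac_myhc_2x"] = rest
    remaining = 1 - table["frac_myhc_2b"] - table["frac_myhc_2x"]
    table["frac_myhc_2a"] = remaining / 2
    table["frac_myhc_1"] = remaining / 2
    return table


class TestSortedProfile:
    def test_orders_by_2b_descending(self):
        table = frac_table([0.1, 0.9, 0.5])
        out = fstats.sorted_profile(table)
        assert out["fiber_id"].tolist() == [2, 3, 1]

    def test_tie_break_on_2x_ascending(self):
        table = frac_table([0.5, 0.5, 0.5], values_2x=[0.3, 0.1, 0.2])
        out = fstats.sorted_profile(table)
        assert out["fiber_id"].tolist() == [2, 3, 1]

    def test_output_is_permutation_of_input(self):
        rng = np.random.default_rng(0)
        table = frac_table(rng.uniform(0, 0.5, 30))
        out = fstats.sorted_profile(table)
        assert sorted(out["fiber_id"]) == sorted(table["fiber_id"])


class TestEcdf:
    def test_interior_point(self):
        f = fstats.ecdf([1.0, 2.0, 3.0])
        assert f(2.0) == pytest.approx(2 / 3)

    def test_single_value_step(self):
        f = fstats.ecdf([5.0])
        assert f(4.999) == 0.0
        assert f(5.0) == 1.0

    def test_duplicates(self):
        f = fstats.ecdf([1.0, 1.0, 2.0])
        assert f(1.0) == pytest.approx(2 / 3)

    def test_reaches_one_at_max(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=50)
        f = fstats.ecdf(v)
        assert f(v.max()) == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fstats.ecdf([])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_identical_groups_h_zero_p_one(self):
        res = fstats.kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_h_matches_brute_force_rank_formula(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        res = fstats.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(brute_force_h(groups), abs=1e-12)

    @pytest.mark.parametrize(
        "groups",
        [
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            [[1.0, 1.0, 2.0], [2.0, 3.0]],
            [[3.1, 0.2], [0.5, 0.5], [2.2, 2.2]],
            [[7.0], [1.0, 2.0, 9.0], [4.0, 4.0]],
        ],
    )
    def test_exact_p_matches_exhaustive_enumeration(self, groups):
        """Exact permutation p agrees with a from-scratch enumeration on
        every input of pooled size <= 8."""
        res = fstats.kruskal_wallis(groups, p_method="exact")
        assert res.p_value == pytest.approx(brute_force_exact_p(groups), abs=1e-12)
        # H agrees with the hand formula on the same inputs
        assert res.statistic == pytest.approx(brute_force_h(groups), abs=1e-12)

    def test_monte_carlo_p_near_exact(self):
        groups = [[1.0, 2.0, 3.0, 9.0], [4.0, 5.0, 6.0, 7.0]]
        exact = fstats.kruskal_wallis(groups, p_method="exact").p_value
        mc = fstats.kruskal_wallis(
            groups, p_method="permutation", n_permutations=20000, rng=0
        ).p_value
        assert abs(mc - exact) <= 0.01

    def test_shifted_cohorts_detected(self):
        """Large fiber samples with a 2b-down shift reject the null."""
        rng = np.random.default_rng(0)
        from fiberquant.synth import SCRAM_PROFILE, SHPAB_PROFILE, sample_fiber_compositions

        _, ca = sample_fiber_compositions(SCRAM_PROFILE, 3000, rng)
        _, cb = sample_fiber_compositions(SHPAB_PROFILE, 3000, rng)
        fa = ca / ca.sum(1, keepdims=True)
        fb = cb / cb.sum(1, keepdims=True)
        res = fstats.kruskal_wallis([fa[:, 0], fb[:, 0]])
        assert res.p_value < 0.05
        assert res.effect_direction == "group_2_lower"

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fstats.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            fstats.kruskal_wallis([[1.0], []])
        with pytest.raises(ValueError):
            fstats.kruskal_wallis([[1.0], [2.0]])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearmanMatrix:
    def test_exact_inversion_gives_minus_one(self):
        n = 10
        v = np.linspace(0.1, 0.9, n)
        table = frac_table(v, values_2x=v[::-1])
        cm = fstats.spearman_matrix(table)
        assert cm.value("myhc_2b", "myhc_2x") == pytest.approx(-1.0)
        assert cm.rho.values.diagonal().tolist() == [1.0] * 4
        np.testing.assert_allclose(cm.rho.values, cm.rho.values.T)

    def test_three_fibers_hand_computed(self):
        a, b = [0.5, 0.2, 0.4], [0.1, 0.3, 0.2]
        table = frac_table(a, values_2x=b)
        cm = fstats.spearman_matrix(table)
        assert cm.value("myhc_2b", "myhc_2x") == pytest.approx(
            brute_force_spearman(a, b), abs=1e-12
        )

    def test_independent_channels_near_zero(self):
        rng = np.random.default_rng(4)
        n = 4000
        table = pd.DataFrame({"fiber_id": np.arange(n)})
        for ch in MYHC_CHANNELS:
            table[f"frac_{ch}"] = rng.uniform(size=n)  # independent by construction
        cm = fstats.spearman_matrix(table)
        assert abs(cm.value("myhc_2b", "myhc_2a")) < 0.05

    def test_constant_channel_reported_missing_not_zero(self):
        table = frac_table([0.1, 0.2, 0.3, 0.4])
        table["frac_myhc_1"] = 0.05
        cm = fstats.spearman_matrix(table)
        assert math.isnan(cm.value("myhc_2b", "myhc_1"))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        power=st.floats(min_value=0.2, max_value=3.0),
    )
    def test_invariance_under_monotone_transforms(self, seed, power):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.01, 1.0, size=15)
        b = rng.uniform(0.01, 1.0, size=15)
        base = brute_force_spearman(list(a), list(b))
        transformed = brute_force_spearman(list(a**power), list(np.log(b)))
        assert transformed == pytest.approx(base, abs=1e-12)
        table = frac_table(a * 0.5, values_2x=b * 0.3)
        cm = fstats.spearman_matrix(table)
        assert cm.value("myhc_2b", "myhc_2x") == pytest.approx(base, abs=1e-9)


class TestPairedCorrelationTest:
    def _matrices(self, rhos_by_sample):
        out = {}
        for sid, r in rhos_by_sample.items():
            m = np.eye(4)
            m[0, 1] = m[1, 0] = r
            out[sid] = fstats.CorrelationMatrix(
                rho=pd.DataFrame(m, index=MYHC_CHANNELS, columns=MYHC_CHANNELS),
                n_fibers=100,
            )
        return out

    def test_identical_matrices_give_t0_p1(self):
        design = generate_cohort(3)
        mats = self._matrices({s: -0.5 for s in design.samples["sample"]})
        res, per_mouse = fstats.paired_correlation_test(
            mats, design, ("myhc_2b", "myhc_2x")
        )
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert len(per_mouse) == 3

    def test_weakened_anticorrelation_positive_mean_delta(self):
        design = generate_cohort(3)
        rhos = {}
        for i, (a, b) in enumerate(design.pairs):
            rhos[a] = -0.6 - 0.02 * i
            rhos[b] = -0.25 + 0.03 * i
        res, per_mouse = fstats.paired_correlation_test(
            mats := self._matrices(rhos), design, ("myhc_2b", "myhc_2x")
        )
        assert per_mouse["delta"].mean() > 0

    def test_single_pair_errors(self):
        design = generate_cohort(1)
        mats = self._matrices({s: -0.5 for s in design.samples["sample"]})
        with pytest.raises(InsufficientPairsError):
            fstats.paired_correlation_test(mats, design, ("myhc_2b", "myhc_2x"))


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestTTests:
    def test_equal_pairs_t_zero(self):
        res = fstats.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_constant_nonzero_difference_reported_exactly(self):
        res = fstats.paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert math.isinf(res.statistic)
        assert "exact-difference" in res.note

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1.0, 1.0, size=20)
        b = rng.normal(0.0, 1.0, size=20)
        res = fstats.paired_t(a, b)
        assert res.statistic == pytest.approx(brute_force_t(list(a - b)), abs=1e-9)

    def test_unpaired_matches_scipy_convention(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        res = fstats.unpaired_t(a, b)
        from scipy import stats as sps

        ref = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.p_value == pytest.approx(float(ref.pvalue))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fstats.paired_t([1.0, 2.0], [1.0])
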