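"""Fiber-type transition and co-expression statistics.

Two-group MFI distribution comparisons use the Kruskal-Wallis rank test
(equivalent to a Wilcoxon rank-sum up to the chi-square approximation for
k = 2); co-expression between MyHC isotypes uses Spearman rank
correlations per sample, with paired t-tests across mice for
condition-level changes. Tie handling is average ranks throughout, and an
undefined correlation (constant channel) propagates as missing rather
than 0 — reporting 0 would fabricate evidence of no association.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CohortDesign
from .exceptions import InsufficientPairsError
from .section import MYHC_CHANNELS

__all__ = [
    "StatTestResult",
    "CorrelationMatrix",
    "sorted_profile",
    "ecdf",
    "kruskal_wallis",
    "spearman_matrix",
    "paired_correlation_test",
    "paired_t",
    "unpaired_t",
]


@dataclass
class StatTestResult:
    """A single hypothesis-test outcome."""

    test: str
    statistic: float
    p_value: float
    n: Mapping[str, int] | int
    effect_direction: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n if isinstance(self.n, int) else dict(self.n),
            "effect_direction": self.effect_direction,
            "note": self.note,
        }


@dataclass
class CorrelationMatrix:
    """Spearman rho between MyHC channels for one sample."""

    rho: pd.DataFrame  # square, symmetric, diagonal 1, NaN where undefined
    n_fibers: int

    def value(self, a: str, b: str) -> float:
        return float(self.rho.loc[a, b])


# ---------------------------------------------------------------------------
# Profiles and distributions
# ---------------------------------------------------------------------------

def sorted_profile(
    table: pd.DataFrame,
    primary: str = f"frac_{MYHC_CHANNELS[0]}",
    secondary: str = f"frac_{MYHC_CHANNELS[1]}",
    channels: Iterable[str] = MYHC_CHANNELS,
) -> pd.DataFrame:
    """Order fibers by MyHC-2b descending, MyHC-2x ascending as tie-break.

    Emits all four isotype fraction series in that fiber order (the layout
    of the per-myofiber MFI distribution plots) plus a ``rank`` column.
    """
    cols = [f"frac_{ch}" for ch in channels]
    missing = [c for c in (primary, secondary, *cols) if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    ordered = table.sort_values(
        [primary, secondary], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out = ordered[["fiber_id", *dict.fromkeys([*cols, primary, secondary])]].copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


@dataclass
class Ecdf:
    """Right-continuous empirical CDF with F(max) = 1."""

    x: np.ndarray  # sorted unique support
    f: np.ndarray  # cumulative heights at x
    n: int

    def __call__(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        idx = np.searchsorted(self.x, q, side="right")
        vals = np.concatenate([[0.0], self.f])[idx]
        return vals if vals.ndim else float(vals)


def ecdf(values: Sequence[float]) -> Ecdf:
    """Empirical CDF of a sample (errors on empty input)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf needs at least one value")
    res = sps.ecdf(arr)
    return Ecdf(x=res.cdf.quantiles, f=res.cdf.probabilities, n=arr.size)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _h_statistic(ranks: np.ndarray, group_sizes: Sequence[int]) -> float:
    """Tie-corrected H from pooled average ranks, split into groups."""
    n = ranks.size
    h = 0.0
    start = 0
    for size in group_sizes:
        r = ranks[start:start + size]
        h += r.sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    correction = 1.0 - tie_term / (n**3 - n)
    if correction == 0.0:
        return 0.0
    return h / correction


def _exact_kw_p(ranks: np.ndarray, sizes: list[int], h_obs: float) -> float:
    """Exhaustive permutation p-value P(H >= h_obs) over group assignments."""
    n = ranks.size
    idx = set(range(n))
    count = 0
    total = 0

    def recurse(remaining: frozenset, sizes_left: list[int], chosen: list[np.ndarray]):
        nonlocal count, total
        if not sizes_left:
            perm = np.concatenate(chosen)
            h = _h_statistic(ranks[perm], sizes)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        size = sizes_left[0]
        if len(sizes_left) == 1:
            recurse(frozenset(), [], chosen + [np.fromiter(remaining, int)])
            return
        for combo in itertools.combinations(sorted(remaining), size):
            recurse(remaining - set(combo), sizes_left[1:], chosen + [np.array(combo)])

    recurse(frozenset(idx), sizes, [])
    return count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    p_method: str = "asymptotic",
    n_permutations: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> StatTestResult:
    """Kruskal-Wallis H test across two or more value sets.

    ``p_method``: ``"asymptotic"`` (chi-square with k-1 df, tie-corrected
    H), ``"exact"`` (exhaustive permutation null; feasible only for small
    pooled n) or ``"permutation"`` (Monte-Carlo permutation null).
    All values identical across groups gives H = 0, p = 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis needs a total n of at least 3")
    sizes = [a.size for a in arrays]
    n_map = {f"group_{i+1}": s for i, s in enumerate(sizes)}

    if np.all(pooled == pooled[0]):
        return StatTestResult(
            test="kruskal_wallis", statistic=0.0, p_value=1.0, n=n_map,
            note="all values identical; p = 1 by convention",
        )

    ranks = sps.rankdata(pooled)  # average ranks
    h_obs = _h_statistic(ranks, sizes)
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(h_obs, df=len(arrays) - 1))
    elif p_method == "exact":
        p = _exact_kw_p(ranks, sizes, h_obs)
    elif p_method == "permutation":
        rng = np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(ranks)
            if _h_statistic(perm, sizes) >= h_obs - 1e-12:
                count += 1
        # add-one correction keeps the Monte-Carlo p valid
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    means = [a.mean() for a in arrays[:2]]
    direction = None
    if len(arrays) == 2:
        direction = "group_2_higher" if means[1] > means[0] else "group_2_lower"
    return StatTestResult(
        test=f"kruskal_wallis[{p_method}]", statistic=float(h_obs), p_value=p,
        n=n_map, effect_direction=direction,
    )


# ---------------------------------------------------------------------------
# Spearman co-expression
# ---------------------------------------------------------------------------

def spearman_matrix(
    table: pd.DataFrame, channels: Iterable[str] = MYHC_CHANNELS
) -> CorrelationMatrix:
    """Spearman rho for every unordered pair of MyHC fraction columns.

    Fibers flagged ``zero_sum`` (no composition) are excluded. A constant
    channel yields NaN for its pairs.
    """
    channels = list(channels)
    cols = [f"frac_{ch}" for ch in channels]
    data = table
    if "zero_sum" in table.columns:
        data = table[~table["zero_sum"]]
    data = data[cols].dropna()
    if len(data) < 3:
        raise ValueError("spearman_matrix needs at least 3 fibers with fractions")
    rho = np.eye(len(channels))
    for i, j in itertools.combinations(range(len(channels)), 2):
        a, b = data[cols[i]].to_numpy(), data[cols[j]].to_numpy()
        if np.all(a == a[0]) or np.all(b == b[0]):
            r = np.nan  # undefined, not zero
        else:
            r = sps.spearmanr(a, b).statistic
        rho[i, j] = rho[j, i] = r
    frame = pd.DataFrame(rho, index=channels, columns=channels)
    return CorrelationMatrix(rho=frame, n_fibers=len(data))


def paired_correlation_test(
    matrices: Mapping[str, CorrelationMatrix],
    design: CohortDesign,
    pair: tuple[str, str],
) -> tuple[StatTestResult, pd.DataFrame]:
    """Paired t-test on per-mouse rho differences (shPab - Scram).

    ``matrices`` maps sample id -> CorrelationMatrix. Returns the test
    result plus the per-mouse rho table behind it.
    """
    a, b = pair
    rows = []
    for scram_sample, shpab_sample in design.pairs:
        if scram_sample not in matrices or shpab_sample not in matrices:
            continue
        r_scram = matrices[scram_sample].value(a, b)
        r_shpab = matrices[shpab_sample].value(a, b)
        if math.isnan(r_scram) or math.isnan(r_shpab):
            continue  # undefined rho: the pair is unusable, not zero
        rows.append(
            {
                "mouse": design.mouse_of(scram_sample),
                "rho_scram": r_scram,
                "rho_shpab": r_shpab,
                "delta": r_shpab - r_scram,
            }
        )
    per_mouse = pd.DataFrame(rows)
    if len(per_mouse) < 2:
        raise InsufficientPairsError(
            f"paired correlation test for {pair} needs >= 2 usable mouse pairs, "
            f"got {len(per_mouse)}"
        )
    result = paired_t(per_mouse["rho_shpab"], per_mouse["rho_scram"])
    result.test = f"paired_t_rho[{a}-{b}]"
    return result, per_mouse


# ---------------------------------------------------------------------------
# t-tests with degenerate-input conventions
# ---------------------------------------------------------------------------

def _t_from_differences(diffs: np.ndarray, test_name: str) -> StatTestResult:
    mean = float(diffs.mean())
    direction = "b_lower" if mean > 0 else ("b_higher" if mean < 0 else None)
    if np.all(diffs == diffs[0]):
        if diffs[0] == 0.0:
            return StatTestResult(
                test=test_name, statistic=0.0, p_value=1.0, n=diffs.size,
                note="all differences zero; p = 1 by convention",
            )
        return StatTestResult(
            test=test_name,
            statistic=math.copysign(math.inf, mean),
            p_value=0.0,
            n=diffs.size,
            effect_direction=direction,
            note=f"degenerate: constant nonzero difference {diffs[0]:g} (exact-difference report)",
        )
    res = sps.ttest_1samp(diffs, 0.0)
    return StatTestResult(
        test=test_name, statistic=float(res.statistic), p_value=float(res.pvalue),
        n=diffs.size, effect_direction=direction,
    )


def paired_t(values_a: Sequence[float], values_b: Sequence[float]) -> StatTestResult:
    """Two-sided paired t-test on a - b (element i of each is one pair)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired_t requires equal-length samples")
    if a.size < 2:
        raise ValueError("paired_t needs at least two pairs")
    return _t_from_differences(a - b, "paired_t")


def unpaired_t(values_a: Sequence[float], values_b: Sequence[float]) -> StatTestResult:
    """Two-sided two-sample t-test (equal-variance, the Prism default)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired_t needs at least two values per group")
    if np.all(a == a[0]) and np.all(b == b[0]):
        if a[0] == b[0]:
            return StatTestResult(
                test="unpaired_t", statistic=0.0, p_value=1.0,
                n={"a": a.size, "b": b.size},
                note="all values identical; p = 1 by convention",
            )
        return StatTestResult(
            test="unpaired_t",
            statistic=math.copysign(math.inf, a.mean() - b.mean()),
            p_value=0.0,
            n={"a": a.size, "b": b.size},
            note="degenerate: zero variance in both groups (exact-difference report)",
        )
    res = sps.ttest_ind(a, b)
    direction = "b_lower" if a.mean() > b.mean() else "b_higher"
    return StatTestResult(
        test="unpaired_t", statistic=float(res.statistic), p_value=float(res.pvalue),
        n={"a": a.size, "b": b.size}, effect_direction=direction,
    )
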