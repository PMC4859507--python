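"""Relative expression, fold change and PAS-utilization analytics.

All quantities assume exact doubling per PCR cycle (100% amplification
efficiency), so expression ratios are powers of two of Ct differences:

* relative expression: ``2^-(meanCt(gene) - mean over refs of meanCt)``,
  supporting a single housekeeping reference (Hprt) or the mean of
  several (Gapdh + Hprt);
* fold change: per-mouse shPab/Scram expression ratio, summarized by the
  cohort mean and a paired t-test on log2 folds;
* distal PAS utilization: ``2^-(meanCt_distal - meanCt_proximal)``; the
  proximal primer set amplifies all transcripts regardless of 3'-UTR
  length, so the ratio is the distal/total fraction. Under Ct noise the
  estimate may exceed 1 and is reported as-is — clipping would bias
  paired deltas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import CohortDesign, SCRAM, SHPAB
from .exceptions import ConfigurationError, InsufficientPairsError
from .stats import StatTestResult, _t_from_differences

__all__ = [
    "validate_qpcr_table",
    "relative_expression",
    "ExpressionTable",
    "fold_change",
    "FoldChangeResult",
    "pas_utilization",
    "pas_utilization_table",
    "pas_change",
    "PasChangeResult",
]

REQUIRED_COLUMNS = ("sample", "mouse", "condition", "gene", "primer_set", "replicate", "ct")


def validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a replicate-level Ct table.

    Requires columns sample/mouse/condition/gene/primer_set/replicate/ct,
    Ct values in (0, 45), and a proximal entry wherever a distal entry
    exists for the same (sample, gene). Returns the table unchanged.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"Ct table lacks columns {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    bad = table.index[ct.isna() | (ct <= 0) | (ct >= 45)]
    if len(bad):
        raise ConfigurationError(
            f"Ct values out of range (0, 45) or non-numeric at rows {list(bad[:10])}"
        )
    has = table.groupby(["sample", "gene"])["primer_set"].agg(set)
    orphans = [
        key for key, sets in has.items() if "distal" in sets and "proximal" not in sets
    ]
    if orphans:
        raise ConfigurationError(
            f"distal primer set without matching proximal set for {orphans}"
        )
    return table


def _mean_ct(table: pd.DataFrame, sample: str, gene: str, primer_set: str) -> float:
    sel = table[
        (table["sample"] == sample)
        & (table["gene"] == gene)
        & (table["primer_set"] == primer_set)
    ]
    if sel.empty:
        raise KeyError(
            f"no Ct rows for sample={sample!r} gene={gene!r} primer_set={primer_set!r}"
        )
    return float(sel["ct"].mean())


@dataclass
class ExpressionTable:
    """Per-sample relative expression for one gene, plus excluded samples."""

    gene: str
    reference_genes: tuple[str, ...]
    per_sample: pd.DataFrame  # sample, mouse, condition, delta_ct, expression
    errors: list[dict] = field(default_factory=list)


def relative_expression(
    table: pd.DataFrame,
    gene: str,
    reference_genes: Sequence[str] | str,
    primer_set: str = "gene_level",
    reference_primer_set: str = "gene_level",
) -> ExpressionTable:
    """Housekeeping-normalized relative expression per sample.

    ``delta_ct = meanCt(gene) - mean over reference genes of meanCt``;
    ``expression = 2^-delta_ct``. Samples missing the gene or any
    reference are excluded with a per-sample error record.
    """
    if isinstance(reference_genes, str):
        reference_genes = (reference_genes,)
    reference_genes = tuple(reference_genes)
    rows, errors = [], []
    for sample, group in table.groupby("sample", sort=True):
        meta = group.iloc[0]
        try:
            gene_ct = _mean_ct(table, sample, gene, primer_set)
            ref_ct = float(
                np.mean(
                    [_mean_ct(table, sample, r, reference_primer_set) for r in reference_genes]
                )
            )
        except KeyError as err:
            errors.append({"sample": sample, "error": str(err)})
            continue
        delta = gene_ct - ref_ct
        rows.append(
            {
                "sample": sample,
                "mouse": meta["mouse"],
                "condition": meta["condition"],
                "delta_ct": delta,
                "expression": 2.0 ** (-delta),
            }
        )
    return ExpressionTable(
        gene=gene,
        reference_genes=reference_genes,
        per_sample=pd.DataFrame(rows),
        errors=errors,
    )


@dataclass
class FoldChangeResult:
    """Per-mouse fold changes and their cohort summary.

    The headline ``mean_fold`` is the geometric mean across mice: folds
    are multiplicative, the paired test runs on log2 folds, and the
    geometric mean is median-unbiased on the log scale (the arithmetic
    mean carries a Jensen bias under Ct noise and is reported alongside).
    """

    gene: str
    per_pair: pd.DataFrame  # mouse, expression in both conditions, fold, log2_fold
    mean_fold: float  # geometric mean
    arithmetic_mean_fold: float
    test: StatTestResult
    excluded_samples: list[str] = field(default_factory=list)


def fold_change(
    expressions: ExpressionTable,
    design: CohortDesign,
    reference_condition: str = SCRAM,
) -> FoldChangeResult:
    """Knockdown/control expression ratio per contralateral pair.

    Fold = expression(shPab) / expression(Scram) within each mouse; the
    summary is the cohort mean fold plus a paired t-test on log2 folds
    against 0. Samples without a partner are excluded and reported.
    """
    expr = dict(zip(expressions.per_sample["sample"], expressions.per_sample["expression"]))
    rows, excluded = [], []
    for ref_sample, alt_sample in design.pairs:
        if reference_condition != SCRAM:
            ref_sample, alt_sample = alt_sample, ref_sample
        if ref_sample not in expr or alt_sample not in expr:
            excluded.extend(s for s in (ref_sample, alt_sample) if s not in expr)
            continue
        fold = expr[alt_sample] / expr[ref_sample]
        rows.append(
            {
                "mouse": design.mouse_of(ref_sample),
                "expression_reference": expr[ref_sample],
                "expression_alt": expr[alt_sample],
                "fold": fold,
                "log2_fold": np.log2(fold),
            }
        )
    paired = [s for s, _ in design.pairs] + [s for _, s in design.pairs]
    excluded.extend(
        s for s in expressions.per_sample["sample"] if s not in paired
    )
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        raise InsufficientPairsError(f"no complete pairs for gene {expressions.gene}")
    if len(per_pair) >= 2:
        test = _t_from_differences(per_pair["log2_fold"].to_numpy(), "paired_t_log2_fold")
    else:
        test = StatTestResult(
            test="paired_t_log2_fold", statistic=float("nan"), p_value=float("nan"),
            n=1, note="single pair; no test",
        )
    return FoldChangeResult(
        gene=expressions.gene,
        per_pair=per_pair,
        mean_fold=float(2.0 ** per_pair["log2_fold"].mean()),
        arithmetic_mean_fold=float(per_pair["fold"].mean()),
        test=test,
        excluded_samples=excluded,
    )


def pas_utilization(table: pd.DataFrame, gene: str, sample: str) -> float:
    """Distal/total transcript fraction for one gene in one sample.

    ``2^-(meanCt_distal - meanCt_proximal)``; requires both primer sets.
    """
    try:
        ct_distal = _mean_ct(table, sample, gene, "distal")
        ct_proximal = _mean_ct(table, sample, gene, "proximal")
    except KeyError as err:
        raise ConfigurationError(str(err)) from err
    return 2.0 ** (-(ct_distal - ct_proximal))


def pas_utilization_table(table: pd.DataFrame, gene: str) -> pd.DataFrame:
    """Per-sample distal PAS utilization for one gene."""
    rows = []
    for sample, group in table.groupby("sample", sort=True):
        sets = set(group.loc[group["gene"] == gene, "primer_set"])
        if not {"distal", "proximal"} <= sets:
            continue
        meta = group.iloc[0]
        rows.append(
            {
                "sample": sample,
                "mouse": meta["mouse"],
                "condition": meta["condition"],
                "utilization": pas_utilization(table, gene, sample),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PasChangeResult:
    """Per-mouse utilization deltas (shPab - Scram) and their paired test."""

    gene: str
    per_pair: pd.DataFrame
    mean_delta: float
    test: StatTestResult


def pas_change(
    utilizations: pd.DataFrame, design: CohortDesign, gene: str = ""
) -> PasChangeResult:
    """Paired change in distal PAS utilization between conditions."""
    util = dict(zip(utilizations["sample"], utilizations["utilization"]))
    rows = []
    for scram_sample, shpab_sample in design.pairs:
        if scram_sample not in util or shpab_sample not in util:
            continue
        rows.append(
            {
                "mouse": design.mouse_of(scram_sample),
                "utilization_scram": util[scram_sample],
                "utilization_shpab": util[shpab_sample],
                "delta": util[shpab_sample] - util[scram_sample],
            }
        )
    per_pair = pd.DataFrame(rows)
    if len(per_pair) < 2:
        raise InsufficientPairsError(
            f"pas_change needs >= 2 complete pairs, got {len(per_pair)}"
        )
    test = _t_from_differences(per_pair["delta"].to_numpy(), "paired_t_pas_delta")
    return PasChangeResult(
        gene=gene,
        per_pair=per_pair,
        mean_delta=float(per_pair["delta"].mean()),
        test=test,
    )
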