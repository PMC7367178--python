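"""Differential-expression filtering and integration with binding/SE classes.

A gene is differentially expressed when it clears three gates at once:
expression (FPKM above 1 in at least one condition), effect size (fold
change above 2 in either direction, computed with a pseudocount), and
significance (externally supplied q below 0.01).  All comparisons are
strict.  Expression shifts between gene groups are compared with the
two-sample Wilcoxon rank-sum test and cumulative-fraction curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionRecord

DEFAULT_MIN_FPKM = 1.0
DEFAULT_MIN_FOLD = 2.0
DEFAULT_MAX_Q = 0.01
DEFAULT_PSEUDOCOUNT_FPKM = 0.1


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    fpkm_wt: float
    fpkm_ko: float
    log2_fold: float
    q_value: float
    klass: str  # up | down | not_de


def call_de(
    records: Sequence[ExpressionRecord],
    min_fpkm: float = DEFAULT_MIN_FPKM,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_q: float = DEFAULT_MAX_Q,
    pseudocount: float = DEFAULT_PSEUDOCOUNT_FPKM,
    fpkm_gate: str = "max",
) -> list[DEGene]:
    """Classify each gene as up / down / not_de in condition B vs A.

    The FPKM gate is applied to the ``max`` of the two conditions by
    default (alternatives: ``either`` is a synonym, ``both`` requires both
    conditions to pass).  Fold change uses a pseudocount on both FPKMs;
    all three gates use strict inequalities.
    """
    if fpkm_gate not in ("max", "either", "both"):
        raise ValueError(f"unknown fpkm_gate {fpkm_gate!r}")
    out = []
    for r in records:
        fold = (r.fpkm_b + pseudocount) / (r.fpkm_a + pseudocount)
        lfc = math.log2(fold)
        if fpkm_gate == "both":
            expressed = r.fpkm_a > min_fpkm and r.fpkm_b > min_fpkm
        else:
            expressed = max(r.fpkm_a, r.fpkm_b) > min_fpkm
        is_de = (
            expressed
            and (fold > min_fold or fold < 1.0 / min_fold)
            and r.q_value < max_q
        )
        if not is_de:
            klass = "not_de"
        else:
            klass = "up" if fold > 1.0 else "down"
        out.append(DEGene(r.gene_id, r.fpkm_a, r.fpkm_b, lfc, r.q_value, klass))
    return out


def stratify_by_binding(
    de_genes: Sequence[DEGene],
    gene_binding_class: Mapping[str, Sequence[str]],
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], list[str]]]:
    """Cross-tabulate expression class against binding class.

    ``gene_binding_class`` maps gene id -> classes of the differential
    peaks assigned to it (subset of {up, down, unchanged}).  A gene hit by
    both up- and down-classified peaks lands in a separate "mixed"
    stratum; genes with no assigned peak are "unbound".

    Returns (counts, per-cell gene lists) keyed by
    (expression class, binding stratum).
    """
    counts: dict[tuple[str, str], int] = {}
    members: dict[tuple[str, str], list[str]] = {}
    for g in de_genes:
        classes = set(gene_binding_class.get(g.gene_id, ()))
        has_up = "up" in classes
        has_down = "down" in classes
        if has_up and has_down:
            stratum = "mixed"
        elif has_up:
            stratum = "bound_up"
        elif has_down:
            stratum = "bound_down"
        elif classes:
            stratum = "bound_unchanged"
        else:
            stratum = "unbound"
        key = (g.klass, stratum)
        counts[key] = counts.get(key, 0) + 1
        members.setdefault(key, []).append(g.gene_id)
    return counts, members


@dataclass(frozen=True)
class ShiftTestResult:
    statistic: float
    p_value: float
    method: str  # exact | asymptotic
    ecdf_a: tuple[np.ndarray, np.ndarray]
    ecdf_b: tuple[np.ndarray, np.ndarray]


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xs = np.sort(values)
    ys = np.arange(1, len(xs) + 1) / len(xs)
    return xs, ys


def expression_shift_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> ShiftTestResult:
    """Two-sample rank-sum comparison of two log-fold-change groups.

    Uses exact enumeration when both groups have at most 20 observations
    and the pooled sample is tie-free, otherwise the normal approximation
    with tie and continuity correction.  Also returns the two empirical
    cumulative-fraction curves for plotting.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 20 and len(b) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ShiftTestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method=method,
        ecdf_a=_ecdf(a),
        ecdf_b=_ecdf(b),
    )
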