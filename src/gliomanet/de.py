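"""Grade-wise differential expression against the normal reference.

Per grade, every gene is tested with an unequal-variance (Welch) t-test
of tumor vs reference log2 values; p-values are FDR-adjusted across the
grade's full gene list and each gene gets a discrete expression state:
OVER (q below threshold, positive mean log-ratio), UNDER (q below
threshold, negative mean log-ratio) or UNCHANGED. The module also
partitions DE genes into exclusive grade subsets (the Venn cells),
computes one-sided Fisher category enrichment, and the Pearson
correlation of DE counts with WHO grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConsistencyError, ExpressionMatrix, TUMOR_GRADES

UNDER = "UNDER"
UNCHANGED = "UNCHANGED"
OVER = "OVER"
STATES = (UNDER, UNCHANGED, OVER)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided t-test of two log2-value groups (Welch by default).

    Degenerate conventions: zero variance in both groups with equal means
    gives (0, 1); zero variance in both groups with unequal means gives
    (+/-inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def adjust_fdr(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR-adjusted p-values (q-values).

    ``bh`` is the Benjamini-Hochberg step-up adjustment; ``storey``
    additionally rescales by a pi0 estimate (lambda = 0.5).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam))
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


# ---------------------------------------------------------------------------
# State calling
# ---------------------------------------------------------------------------


@dataclass
class StateTable:
    """Per-gene test results and discrete expression state for one grade."""

    grade: str
    table: pd.DataFrame  # columns: t, p, q, mean_log_ratio, state, flagged

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def de_genes(self, direction: str | None = None) -> set[str]:
        states = self.table["state"]
        if direction is None:
            return set(states.index[states != UNCHANGED])
        return set(states.index[states == direction])


def call_states(
    expr: ExpressionMatrix,
    grade: str,
    q_threshold: float = 1e-4,
    reference_grade: str = "NORMAL",
    equal_var: bool = False,
    fdr_method: str = "bh",
) -> StateTable:
    """Test every gene for one tumor grade against the normal reference.

    The t-test runs on raw log2 values (tumors vs references); the mean
    log-ratio is the difference of the group means, and its sign decides
    OVER vs UNDER for genes passing the q cut. Genes constant across all
    samples are flagged and left UNCHANGED with missing p.
    """
    tumors = expr.grade_samples(grade)
    refs = expr.grade_samples(reference_grade)
    if len(tumors) < 2 or len(refs) < 2:
        raise ConsistencyError(
            f"grade {grade!r} needs >=2 tumor and >=2 reference samples"
        )
    a = expr.values[tumors].to_numpy()
    b = expr.values[refs].to_numpy()
    mean_lr = a.mean(axis=1) - b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    constant = (va == 0) & (vb == 0) & (mean_lr == 0)
    degenerate = (va == 0) & (vb == 0) & (mean_lr != 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    t[constant] = 0.0
    p[constant] = 1.0
    t[degenerate] = np.copysign(np.inf, mean_lr[degenerate])
    p[degenerate] = 0.0

    q = np.full_like(p, np.nan)
    testable = ~constant
    q[testable] = adjust_fdr(p[testable], method=fdr_method)

    state = np.full(len(p), UNCHANGED, dtype=object)
    called = testable & (q < q_threshold)
    state[called & (mean_lr > 0)] = OVER
    state[called & (mean_lr < 0)] = UNDER

    p[constant] = np.nan
    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "mean_log_ratio": mean_lr,
            "state": state,
            "flagged": constant | degenerate,
        },
        index=expr.values.index,
    )
    return StateTable(grade=grade, table=table)


# ---------------------------------------------------------------------------
# Exclusive grade subsets (Venn cells)
# ---------------------------------------------------------------------------


@dataclass
class SubsetPartition:
    """Genes sharing one DE direction in exactly one grade subset."""

    direction: str
    cells: dict[frozenset[str], set[str]]

    def cell(self, *grades: str) -> set[str]:
        return self.cells.get(frozenset(grades), set())

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.cells.values():
            out |= genes
        return out


def exclusive_subsets(
    tables: Mapping[str, StateTable], direction: str
) -> SubsetPartition:
    """Assign each gene to exactly the subset of grades where its state
    equals ``direction`` (non-members are dropped)."""
    if direction not in (UNDER, OVER):
        raise ValueError("direction must be UNDER or OVER")
    grades = list(tables)
    universes = {g: list(tables[g].table.index) for g in grades}
    first = universes[grades[0]]
    for g in grades[1:]:
        if set(universes[g]) != set(first):
            raise ConsistencyError(f"gene universe of {g} differs")
    cells: dict[frozenset[str], set[str]] = {}
    membership = pd.DataFrame(
        {g: tables[g].table["state"] == direction for g in grades}
    )
    for gene, row in membership.iterrows():
        subset = frozenset(g for g in grades if row[g])
        if subset:
            cells.setdefault(subset, set()).add(gene)
    return SubsetPartition(direction=direction, cells=cells)


# ---------------------------------------------------------------------------
# Enrichment and grade trend
# ---------------------------------------------------------------------------


def enrichment_fisher(k: int, n: int, K: int, N: int) -> float:
    """One-sided over-representation p-value, P(X >= k) for hypergeometric
    X with ``N`` genes total, ``K`` in the category, ``n`` drawn (DE set)."""
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def grade_trend(
    counts: Sequence[float], grades: Sequence[float] = (1, 2, 3, 4)
) -> tuple[float, float]:
    """Pearson correlation of per-grade DE counts with numeric WHO grade."""
    counts = np.asarray(counts, dtype=float)
    grades = np.asarray(grades, dtype=float)
    if len(counts) != len(grades) or len(counts) < 3:
        raise ValueError("need matched counts for at least 3 grades")
    if np.all(counts == counts[0]):
        raise ValueError("correlation undefined for constant counts")
    r, p = stats.pearsonr(counts, grades)
    return float(r), float(p)


def de_counts_by_grade(tables: Mapping[str, StateTable]) -> pd.DataFrame:
    """Under / over / total DE counts per grade, in canonical grade order."""
    rows = {}
    for grade in TUMOR_GRADES:
        if grade not in tables:
            continue
        t = tables[grade]
        rows[grade] = {
            "under": len(t.de_genes(UNDER)),
            "over": len(t.de_genes(OVER)),
            "total": len(t.de_genes()),
        }
    return pd.DataFrame(rows).T
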