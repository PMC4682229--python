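"""Gene signature distinguishing PA I from the pooled adult grades.

A gene enters the signature when its discrete expression state in PA I
differs from its state in the higher grades (six set-logic criteria:
under/unchanged/over in PA I but not in AS II, AS III or GBM IV, and the
three reversed criteria) AND the absolute difference between its mean
log-ratio in PA I and in the pooled AS II + AS III + GBM IV class is at
least the fold-change threshold (default 2 log2 units, i.e. 4-fold).

The "but not in" quantifier is ambiguous in plain language; the default
disjunctive reading admits a gene whose PA I state differs from at least
one higher grade, while the strict mode requires a difference from all
three. Both are exposed; the boundary of the difference filter is
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .de import OVER, STATES, UNCHANGED, UNDER, StateTable
from .io import ADULT_GRADES, ConsistencyError, LogRatioMatrix

CRITERIA = ("i", "ii", "iii", "iv", "v", "vi")
_PA1_STATE_BY_CRITERION = {"i": UNDER, "ii": UNCHANGED, "iii": OVER}
_ADULT_STATE_BY_CRITERION = {"iv": UNDER, "v": UNCHANGED, "vi": OVER}


def matches_criteria(
    states: Mapping[str, str], mode: str = "any"
) -> tuple[bool, list[str]]:
    """Evaluate the six PA I-vs-adult state criteria for one gene.

    ``mode='any'``: PA I's state must differ from at least one higher
    grade (disjunctive reading of "but not in AS II, AS III or GBM IV").
    ``mode='all'``: it must differ from all three.
    Returns the overall match and the list of triggered criteria labels.
    """
    for grade in ("PA1",) + tuple(ADULT_GRADES):
        if grade not in states:
            raise ConsistencyError(f"missing state for grade {grade}")
        if states[grade] not in STATES:
            raise ValueError(f"unknown state {states[grade]!r}")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    quant = any if mode == "any" else all
    s_pa1 = states["PA1"]
    adult = [states[g] for g in ADULT_GRADES]
    hits: list[str] = []
    # (i)-(iii): PA I in a given state, higher grades not in that state
    for label, st in _PA1_STATE_BY_CRITERION.items():
        if s_pa1 == st and quant(a != st for a in adult):
            hits.append(label)
    # (iv)-(vi): higher grades in a given state, PA I not in that state
    for label, st in _ADULT_STATE_BY_CRITERION.items():
        if s_pa1 != st and quant(a == st for a in adult):
            hits.append(label)
    return bool(hits), hits


def class_difference(gene: str, lr: LogRatioMatrix) -> tuple[float, float, float]:
    """(PA I mean, pooled adult mean, difference) of the gene's log-ratios."""
    pa1 = lr.grade_samples("PA1")
    adult = [s for g in ADULT_GRADES for s in lr.grade_samples(g)]
    if not pa1 or not adult:
        raise ConsistencyError("both classes need at least one sample")
    row = lr.values.loc[gene]
    mean_pa1 = float(row[pa1].mean())
    mean_adult = float(row[adult].mean())
    return mean_pa1, mean_adult, mean_pa1 - mean_adult


def category_percentages(counts: Mapping[str, int], total: int) -> dict[str, int]:
    """Signature composition report: category counts as whole percentages.

    E.g. 151 TFs in a 1,089-gene signature reads as 14 %.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    return {name: round(100 * k / total) for name, k in counts.items()}


@dataclass
class Signature:
    """Signature membership table; one row per retained gene."""

    table: pd.DataFrame  # states, class means, difference, criteria
    lfc_threshold: float
    mode: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def derive_signature(
    tables: Mapping[str, StateTable],
    lr: LogRatioMatrix,
    lfc_threshold: float = 2.0,
    mode: str = "any",
) -> Signature:
    """Apply the six criteria plus the class-difference filter to all genes."""
    grades = ("PA1",) + tuple(ADULT_GRADES)
    for g in grades:
        if g not in tables:
            raise ConsistencyError(f"missing state table for grade {g}")
    universe = list(tables["PA1"].table.index)
    for g in grades[1:]:
        if set(tables[g].table.index) != set(universe):
            raise ConsistencyError(f"gene universe of {g} differs")
    if set(lr.genes) < set(universe):
        raise ConsistencyError("log-ratio matrix misses genes of the state tables")

    pa1_samples = lr.grade_samples("PA1")
    adult_samples = [s for g in ADULT_GRADES for s in lr.grade_samples(g)]
    if not pa1_samples or not adult_samples:
        raise ConsistencyError("both classes need at least one sample")
    mean_pa1 = lr.values[pa1_samples].mean(axis=1)
    mean_adult = lr.values[adult_samples].mean(axis=1)

    states = {g: tables[g].table["state"] for g in grades}
    rows = []
    for gene in universe:
        gene_states = {g: states[g][gene] for g in grades}
        ok, hits = matches_criteria(gene_states, mode=mode)
        if not ok:
            continue
        diff = float(mean_pa1[gene] - mean_adult[gene])
        if abs(diff) < lfc_threshold:  # inclusive boundary at the threshold
            continue
        rows.append(
            {
                "gene": gene,
                **{f"state_{g}": gene_states[g] for g in grades},
                "mean_pa1": float(mean_pa1[gene]),
                "mean_adult": float(mean_adult[gene]),
                "difference": diff,
                "criteria": ",".join(hits),
            }
        )
    columns = (
        ["gene"]
        + [f"state_{g}" for g in grades]
        + ["mean_pa1", "mean_adult", "difference", "criteria"]
    )
    table = pd.DataFrame(rows, columns=columns).set_index("gene")
    return Signature(table=table, lfc_threshold=lfc_threshold, mode=mode)
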