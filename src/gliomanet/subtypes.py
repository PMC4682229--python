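"""Centroid-correlation subtype classification.

Each tumor's log-ratio profile is correlated with every subtype centroid
over the shared gene set; the sample is assigned the subtype with the
greatest significant positive correlation (one-sided test of r > 0),
or left UNCLASSIFIED when no subtype is significant. The same Pearson
machinery serves generic signature-correlation probes (hypermethylator
profile, microglia/macrophage markers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CentroidSet, LogRatioMatrix

UNCLASSIFIED = "UNCLASSIFIED"


def intersect_signature(
    sample_genes: list[str], centroid_genes: list[str]
) -> tuple[list[str], float]:
    """Shared genes in centroid order, plus the centroid coverage fraction."""
    sample_set = set(sample_genes)
    common = [g for g in centroid_genes if g in sample_set]
    if not common:
        raise ValueError("no genes shared between sample and centroids")
    return common, len(common) / len(centroid_genes)


def correlation_pvalue(r: float, n: int, alternative: str = "greater") -> float:
    """P-value for a Pearson correlation via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need at least 3 observations")
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    df = n - 2
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class SubtypeCall:
    """Per-sample correlations with every centroid and the assigned label."""

    sample: str
    correlations: pd.Series
    pvalues: pd.Series
    label: str
    n_genes: int


def classify_subtype(
    sample_lr: pd.Series,
    centroids: CentroidSet,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> SubtypeCall:
    """Assign the subtype with the greatest significant positive correlation.

    Exact ties in r are broken by centroid column order; a sample with no
    significant positive subtype is labeled UNCLASSIFIED.
    """
    common, _cov = intersect_signature(list(sample_lr.index), centroids.genes)
    if len(common) < 3:
        raise ValueError("need at least 3 shared genes")
    x = sample_lr.loc[common].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError(f"sample {sample_lr.name!r} is constant; r undefined")
    n = len(common)
    xc = x - x.mean()
    xs = np.sqrt((xc * xc).sum())
    rs, ps = {}, {}
    for subtype in centroids.subtypes:
        y = centroids.values.loc[common, subtype].to_numpy(dtype=float)
        yc = y - y.mean()
        ys = np.sqrt((yc * yc).sum())
        if ys == 0.0:
            raise ValueError(f"centroid {subtype!r} is constant on shared genes")
        r = float(np.clip((xc @ yc) / (xs * ys), -1.0, 1.0))
        rs[subtype] = r
        ps[subtype] = correlation_pvalue(r, n, alternative=alternative)
    rs = pd.Series(rs)
    ps = pd.Series(ps)
    eligible = [s for s in centroids.subtypes if ps[s] < alpha and rs[s] > 0]
    if eligible:
        best_r = max(rs[s] for s in eligible)
        label = next(s for s in centroids.subtypes if s in eligible and rs[s] == best_r)
    else:
        label = UNCLASSIFIED
    return SubtypeCall(
        sample=str(sample_lr.name),
        correlations=rs,
        pvalues=ps,
        label=label,
        n_genes=n,
    )


def classify_cohort(
    lr: LogRatioMatrix,
    centroids: CentroidSet,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Classify every sample; returns one row per sample with r, p and label."""
    rows = []
    for sample in lr.samples:
        call = classify_subtype(
            lr.values[sample], centroids, alpha=alpha, alternative=alternative
        )
        row: dict = {"sample": sample, "label": call.label, "n_genes": call.n_genes}
        for s in centroids.subtypes:
            row[f"r_{s}"] = call.correlations[s]
            row[f"p_{s}"] = call.pvalues[s]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample")


def signature_correlation(
    profile_a: pd.Series,
    profile_b: pd.Series,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Pearson correlation of two per-gene profiles over their shared genes."""
    common = [g for g in profile_a.index if g in set(profile_b.index)]
    if len(common) < 3:
        raise ValueError("need at least 3 shared genes")
    a = profile_a.loc[common].to_numpy(dtype=float)
    b = profile_b.loc[common].to_numpy(dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    return r, correlation_pvalue(r, len(common), alternative=alternative)
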