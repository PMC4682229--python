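"""Signature-specific regulatory network inference.

Each signature gene's tumor log-ratio profile is modeled as a linear
combination of the log-ratios of the signature's transcription factors
(excluding the gene itself), e_id = sum_j a_ji * e_jd, with no
intercept. The model is fitted along the full lasso/LAR regularization
path; each predictor entering the path receives a p-value from the
covariance test (the drop in <y, fitted values> when the entering
variable is removed at the next knot, scaled by the noise variance,
which is asymptotically standard exponential under the null). Predictors
significant at the threshold (default P < 5e-5) become edges; the
reported coefficient a_ji comes from a least-squares refit on the
selected set, and its sign labels the TF an activator (a_ji > 0) or
repressor (a_ji < 0).

Predictors are standardized to zero mean / unit variance and the
response centered before the path is computed; knots are reported on the
lambda = max|X^T r| inner-product scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV, lars_path

from .io import ACTIVATOR, REPRESSOR, ConsistencyError, LogRatioMatrix, RegulatoryNetwork

SIGMA2_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Lasso path
# ---------------------------------------------------------------------------


@dataclass
class EntryEvent:
    """A predictor joining the active set at a path knot."""

    predictor: int
    knot: int  # index into LassoPath.knots where the coefficient is still 0
    sign: int


@dataclass
class LassoPath:
    """Piecewise-linear lasso coefficient path on standardized predictors.

    ``knots`` decrease from lambda_max = max|X^T y| to 0; ``coefs[:, k]``
    is the solution at ``knots[k]``. ``X`` and ``y`` are the standardized
    design and centered response the path was computed on.
    """

    knots: np.ndarray
    coefs: np.ndarray
    entries: list[EntryEvent]
    predictors: list[str]
    X: np.ndarray
    y: np.ndarray
    x_mean: np.ndarray = field(default_factory=lambda: np.zeros(0))
    x_scale: np.ndarray = field(default_factory=lambda: np.zeros(0))
    y_mean: float = 0.0

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    def first_entries(self) -> dict[int, EntryEvent]:
        """First entry event per predictor (re-entries after drops ignored)."""
        out: dict[int, EntryEvent] = {}
        for ev in self.entries:
            out.setdefault(ev.predictor, ev)
        return out


def _standardize(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = np.nonzero(scale == 0.0)[0]
    if constant.size:
        raise ValueError(
            "constant predictor(s): " + ", ".join(names[i] for i in constant)
        )
    return (X - mean) / scale, mean, scale


def lasso_path(X, y) -> LassoPath:
    """Full lasso/LAR path of the centered response on standardized predictors.

    ``X`` may be an array or DataFrame (samples x predictors); column
    names are kept for error messages and edge assembly.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xs, x_mean, x_scale = _standardize(X, names)
    y_mean = float(y.mean())
    yc = y - y_mean

    alphas, _active, coefs = lars_path(Xs, yc, method="lasso")
    knots = alphas * n  # back to the max|X^T r| inner-product scale

    entries: list[EntryEvent] = []
    for m in range(len(knots) - 1):
        newly = np.nonzero((coefs[:, m] == 0.0) & (coefs[:, m + 1] != 0.0))[0]
        for j in newly:
            entries.append(
                EntryEvent(
                    predictor=int(j),
                    knot=m,
                    sign=int(np.sign(coefs[j, m + 1])),
                )
            )
    return LassoPath(
        knots=knots,
        coefs=coefs,
        entries=entries,
        predictors=names,
        X=Xs,
        y=yc,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
    )


def check_kkt(path: LassoPath, tol: float = 1e-8) -> None:
    """Assert the lasso KKT conditions at every knot of the path.

    For the solution at lambda: |x_j^T r| = lambda with sign(x_j^T r) =
    sign(beta_j) for active j, and |x_j^T r| <= lambda for inactive j.
    """
    scale = max(1.0, float(path.knots[0]))
    for m, lam in enumerate(path.knots):
        beta = path.coefs[:, m]
        r = path.y - path.X @ beta
        corr = path.X.T @ r
        active = beta != 0.0
        # x_j^T r = lambda * sign(beta_j) covers both equality and sign
        if np.any(np.abs(corr[active] - lam * np.sign(beta[active])) > tol * scale):
            raise AssertionError(f"KKT equality/sign violated at knot {m}")
        if np.any(np.abs(corr[~active]) > lam + tol * scale):
            raise AssertionError(f"KKT inequality violated at knot {m}")


# ---------------------------------------------------------------------------
# Covariance test
# ---------------------------------------------------------------------------


def _restricted_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Lasso solution restricted to the given predictors at penalty ``lam``
    (inner-product scale), via the restricted path and piecewise-linear
    interpolation in lambda."""
    n = X.shape[0]
    alphas, _a, coefs = lars_path(X, y, method="lasso")
    lams = alphas * n
    if lam >= lams[0]:
        return np.zeros(X.shape[1])
    # np.interp needs increasing x; the path's lambdas decrease
    xs = lams[::-1]
    beta = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        beta[j] = np.interp(lam, xs, coefs[j, ::-1])
    return beta


def covariance_test(path: LassoPath, sigma2: float) -> pd.DataFrame:
    """Covariance-test statistic and p-value at every entry knot.

    T_k = (<y, X b(lam_{k+1})> - <y, X_A b_A(lam_{k+1})>) / sigma2, where
    A is the active set just before the entry; p = exp(-T_k), the tail of
    the statistic's asymptotic standard-exponential null distribution.
    A predictor's p-value is taken at its first entry.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rows = []
    for ev in path.entries:
        m = ev.knot
        lam_next = float(path.knots[m + 1])
        full = path.X @ path.coefs[:, m + 1]
        term_full = float(path.y @ full)
        active_before = np.nonzero(path.coefs[:, m] != 0.0)[0]
        if active_before.size:
            beta_a = _restricted_fit(path.X[:, active_before], path.y, lam_next)
            term_restricted = float(path.y @ (path.X[:, active_before] @ beta_a))
        else:
            term_restricted = 0.0
        T = max(0.0, (term_full - term_restricted) / sigma2)
        rows.append(
            {
                "predictor": path.predictors[ev.predictor],
                "knot": m,
                "statistic": T,
                "p": float(np.exp(-T)),
            }
        )
    return pd.DataFrame(rows, columns=["predictor", "knot", "statistic", "p"])


def first_entry_pvalues(path: LassoPath, sigma2: float) -> pd.Series:
    """Per-predictor covariance-test p at its first entry along the path."""
    stats = covariance_test(path, sigma2)
    if stats.empty:
        return pd.Series(dtype=float)
    return stats.groupby("predictor", sort=False)["p"].first()


# ---------------------------------------------------------------------------
# Noise variance
# ---------------------------------------------------------------------------


def estimate_noise_variance(X, y) -> float:
    """Residual variance for the covariance test.

    With n > p + 1 this is the df-corrected residual variance of the full
    least-squares fit (with intercept). Otherwise the support selected by
    a cross-validated lasso is refitted by least squares and its
    df-corrected residual variance is used. Exactly-linear responses hit
    a small variance floor (with a warning) so degenerate toys remain
    testable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    design = np.column_stack([np.ones(n), X])
    if n > p + 1:
        rank = np.linalg.matrix_rank(design)
        if rank < p + 1:
            raise ValueError("design matrix is rank deficient")
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        sigma2 = rss / (n - p - 1)
    else:
        cv = LassoCV(cv=5, fit_intercept=True).fit(X, y)
        support = np.nonzero(cv.coef_ != 0.0)[0]
        k = support.size
        if n - k - 1 <= 0:
            raise ValueError("too few samples to estimate the noise variance")
        design = np.column_stack([np.ones(n), X[:, support]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(np.sum((y - design @ beta) ** 2))
        sigma2 = rss / (n - k - 1)
    if sigma2 < SIGMA2_FLOOR:
        warnings.warn(
            "residual variance is numerically zero; using the pseudo-variance floor",
            RuntimeWarning,
            stacklevel=2,
        )
        return SIGMA2_FLOOR
    return sigma2


# ---------------------------------------------------------------------------
# Per-gene models and network assembly
# ---------------------------------------------------------------------------


def fit_gene_model(
    gene: str,
    lr: LogRatioMatrix,
    tf_set: list[str],
    p_threshold: float = 5e-5,
    coefficient_mode: str = "refit",
) -> pd.DataFrame:
    """Select the significant regulators of one signature gene.

    Returns a table (tf, coefficient, sign, p_value) of predictors whose
    covariance-test p at first entry is below ``p_threshold``. With
    ``coefficient_mode='refit'`` (default) coefficients come from a
    no-intercept least-squares refit on the selected TFs; ``'lasso'``
    reports the back-transformed path coefficient just after entry (a
    sensitivity mode; lasso estimates are shrunken).
    """
    predictors = [t for t in tf_set if t != gene]
    if not predictors:
        raise ValueError("no predictors left after self-exclusion")
    if len(lr.samples) < 3:
        raise ConsistencyError("need at least 3 tumor samples")
    X = lr.values.loc[predictors].T
    y = lr.values.loc[gene].to_numpy(dtype=float)

    path = lasso_path(X, y)
    sigma2 = estimate_noise_variance(X.to_numpy(dtype=float), y)
    pvals = first_entry_pvalues(path, sigma2)
    selected = [t for t in predictors if pvals.get(t, 1.0) < p_threshold]
    if not selected:
        return pd.DataFrame(columns=["tf", "coefficient", "sign", "p_value"])

    if coefficient_mode == "refit":
        Xsel = lr.values.loc[selected].T.to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xsel, y, rcond=None)
        coefs = dict(zip(selected, beta))
    elif coefficient_mode == "lasso":
        first = path.first_entries()
        idx = {name: j for j, name in enumerate(path.predictors)}
        coefs = {}
        for t in selected:
            ev = first[idx[t]]
            raw = path.coefs[idx[t], ev.knot + 1]
            coefs[t] = raw / path.x_scale[idx[t]]  # back to the data scale
    else:
        raise ValueError("coefficient_mode must be 'refit' or 'lasso'")

    rows = []
    for t in selected:
        c = float(coefs[t])
        if c == 0.0:
            continue
        rows.append(
            {
                "tf": t,
                "coefficient": c,
                "sign": ACTIVATOR if c > 0 else REPRESSOR,
                "p_value": float(pvals[t]),
            }
        )
    return pd.DataFrame(rows, columns=["tf", "coefficient", "sign", "p_value"])


def possible_links(tf_set, genes) -> tuple[int, int]:
    """Theoretically possible TF -> signature-gene links.

    Returns ``(|TF| * N, |TF| * N - |TF in signature|)``: the headline
    denominator counts every TF/gene pair including TF self-pairs; the
    second count removes them (the model itself never fits self-edges).
    """
    n_self = len(set(tf_set) & set(genes))
    total = len(list(tf_set)) * len(list(genes))
    return total, total - n_self


def infer_network(
    signature_genes,
    lr: LogRatioMatrix,
    tf_set: list[str],
    p_threshold: float = 5e-5,
    coefficient_mode: str = "refit",
) -> RegulatoryNetwork:
    """Union of per-gene regulator selections over all signature genes.

    ``signature_genes`` may be a Signature object or a list of gene
    identifiers; ``tf_set`` are the signature's TFs (order fixes edge
    order). The summary reports the possible-link denominator
    |TF| x N (and the self-pair-excluded count), regulator-less genes
    and TFs without outgoing links.
    """
    genes = list(getattr(signature_genes, "genes", signature_genes))
    missing = [g for g in genes if g not in set(lr.genes)]
    if missing:
        raise ConsistencyError(f"signature genes missing from log-ratios: {missing[:5]}")
    missing_tf = [t for t in tf_set if t not in set(lr.genes)]
    if missing_tf:
        raise ConsistencyError(f"TFs missing from log-ratios: {missing_tf[:5]}")

    all_edges = []
    genes_without = []
    for gene in genes:
        sel = fit_gene_model(
            gene, lr, tf_set, p_threshold=p_threshold, coefficient_mode=coefficient_mode
        )
        if sel.empty:
            genes_without.append(gene)
            continue
        sel = sel.assign(target=gene)
        all_edges.append(sel)

    if all_edges:
        edges = pd.concat(all_edges, ignore_index=True)[
            ["tf", "target", "coefficient", "sign", "p_value"]
        ]
    else:
        edges = pd.DataFrame(columns=["tf", "target", "coefficient", "sign", "p_value"])

    tfs_with_links = set(edges["tf"]) if len(edges) else set()
    total_links, self_excluded = possible_links(tf_set, genes)
    summary = {
        "n_tfs": len(tf_set),
        "n_signature_genes": len(genes),
        "possible_links": total_links,
        "possible_links_self_excluded": self_excluded,
        "selected_links": int(len(edges)),
        "activators": int((edges["sign"] == ACTIVATOR).sum()) if len(edges) else 0,
        "repressors": int((edges["sign"] == REPRESSOR).sum()) if len(edges) else 0,
        "genes_without_regulators": genes_without,
        "tfs_without_targets": [t for t in tf_set if t not in tfs_with_links],
    }
    return RegulatoryNetwork(
        edges=edges, tfs=list(tf_set), genes=genes, summary=summary
    )
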