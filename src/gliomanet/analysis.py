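"""Downstream analyses of the inferred regulatory network.

Hub ranking by outgoing links, the TF-to-TF hierarchy, predictive
validation of the network on an independent cohort (predicted vs
observed log-ratios per gene), and the integration of TF expression
contrasts with mutation (methylation / copy-number) log-ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import (
    ADULT_GRADES,
    ConsistencyError,
    LogRatioMatrix,
    MutationTable,
    RegulatoryNetwork,
)

CENTER = "CENTER"
EXPR_ONLY = "EXPR_ONLY"
MUT_ONLY = "MUT_ONLY"
CONCORDANT = "CONCORDANT"
DISCORDANT = "DISCORDANT"


def hub_ranking(
    network: RegulatoryNetwork,
    tf_set: list[str] | None = None,
    lr: LogRatioMatrix | None = None,
) -> pd.DataFrame:
    """Per-TF outgoing-link counts, total and to TFs only, sorted by hubness.

    Sorted by total out-degree descending with lexicographic ties. When a
    log-ratio matrix is given, a column with the adult-minus-PA I mean
    expression contrast is added.
    """
    tfs = list(tf_set) if tf_set is not None else list(network.tfs)
    total = network.out_degree()
    to_tfs = network.out_degree(targets=tfs)
    report = pd.DataFrame(
        {
            "out_degree": total.reindex(tfs, fill_value=0).astype(int),
            "out_degree_tf": to_tfs.reindex(tfs, fill_value=0).astype(int),
        },
        index=pd.Index(tfs, name="tf"),
    )
    if lr is not None:
        pa1 = lr.grade_samples("PA1")
        adult = [s for g in ADULT_GRADES for s in lr.grade_samples(g)]
        contrast = {}
        for tf in tfs:
            if tf in set(lr.genes) and pa1 and adult:
                row = lr.values.loc[tf]
                contrast[tf] = float(row[adult].mean() - row[pa1].mean())
            else:
                contrast[tf] = np.nan
        report["expression_contrast"] = pd.Series(contrast)
    # lexicographic tie order: stable sort on name first, then degree
    report = report.sort_index(kind="stable")
    return report.sort_values("out_degree", ascending=False, kind="stable")


def tf_hierarchy(
    network: RegulatoryNetwork, tf_set: list[str], threshold: int = 5
) -> pd.Series:
    """TFs with strictly more than ``threshold`` outgoing links to other TFs."""
    counts = network.out_degree(targets=tf_set)
    counts = counts.reindex(sorted(set(tf_set) | set(counts.index)), fill_value=0)
    return counts[counts > threshold].astype(int)


def predict_expression(
    network: RegulatoryNetwork,
    tf_lr: LogRatioMatrix,
    observed_lr: LogRatioMatrix | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predict signature-gene log-ratios from TF log-ratios via the network.

    e_hat[i, d] = sum over selected edges j->i of a_ji * e[j, d]. Returns
    the predictions and, when observations are supplied, the per-gene
    Pearson correlation over samples for genes with >= 1 regulator.
    """
    missing = sorted(set(network.edges["tf"]) - set(tf_lr.genes))
    if missing:
        affected = sorted(
            set(network.edges.loc[network.edges["tf"].isin(missing), "target"])
        )
        raise ConsistencyError(
            f"TFs {missing} absent from the log-ratio matrix; "
            f"affected genes: {affected}"
        )
    samples = tf_lr.samples
    preds: dict[str, np.ndarray] = {}
    for target, sub in network.edges.groupby("target", sort=False):
        acc = np.zeros(len(samples))
        for _, row in sub.iterrows():
            acc = acc + row["coefficient"] * tf_lr.values.loc[row["tf"]].to_numpy()
        preds[target] = acc
    predicted = pd.DataFrame(preds, index=samples).T

    correlations = pd.Series(dtype=float)
    if observed_lr is not None:
        rs = {}
        for gene in predicted.index:
            if gene not in set(observed_lr.genes):
                continue
            obs = observed_lr.values.loc[gene, samples].to_numpy(dtype=float)
            pred = predicted.loc[gene].to_numpy(dtype=float)
            if np.std(obs) == 0 or np.std(pred) == 0:
                continue
            rs[gene] = float(np.corrcoef(pred, obs)[0, 1])
        correlations = pd.Series(rs)
    return predicted, correlations


def validation_summary(correlations: pd.Series) -> dict:
    """Median per-gene r and the fraction of genes predicted positively."""
    if correlations.empty:
        return {"n_genes": 0, "median_r": float("nan"), "fraction_positive": float("nan")}
    return {
        "n_genes": int(len(correlations)),
        "median_r": float(correlations.median()),
        "fraction_positive": float((correlations > 0).mean()),
    }


def mutation_expression_map(
    expr_contrast: pd.Series,
    mutations: MutationTable,
    deviation_threshold: float = 1.0,
) -> pd.DataFrame:
    """Categorize TFs by joint expression / mutation deviation.

    CENTER: both |values| below the threshold. EXPR_ONLY / MUT_ONLY:
    exactly one deviates. Otherwise CONCORDANT when the signs match the
    layer's expected coupling (copy number: same sign; methylation:
    opposite sign, promoter hypermethylation going with underexpression),
    else DISCORDANT. TFs missing a layer value are flagged and skipped.
    """
    rows = []
    skipped = []
    for tf, e in expr_contrast.items():
        if tf not in mutations.values.index or pd.isna(mutations.values[tf]):
            skipped.append(tf)
            continue
        m = float(mutations.values[tf])
        e = float(e)
        big_e = abs(e) >= deviation_threshold
        big_m = abs(m) >= deviation_threshold
        if not big_e and not big_m:
            cat = CENTER
        elif big_e and not big_m:
            cat = EXPR_ONLY
        elif big_m and not big_e:
            cat = MUT_ONLY
        else:
            same_sign = np.sign(e) == np.sign(m)
            expected_same = mutations.layer == "copy_number"
            cat = CONCORDANT if same_sign == expected_same else DISCORDANT
        rows.append(
            {
                "tf": tf,
                "expression": e,
                "mutation": m,
                "layer": mutations.layer,
                "category": cat,
            }
        )
    table = pd.DataFrame(
        rows, columns=["tf", "expression", "mutation", "layer", "category"]
    )
    table.attrs["skipped"] = skipped
    return table.set_index("tf")
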