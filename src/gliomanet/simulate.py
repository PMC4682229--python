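"""Synthetic astrocytoma cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a normal-brain baseline per gene with Gaussian measurement noise,
* grade-specific differential-expression effects whose count grows with
  WHO grade,
* transcription factors (TFs) with a PA I-vs-adult expression contrast
  plus tumor-to-tumor variability,
* signature target genes whose log-ratios are a sparse linear
  combination of TF log-ratios (the generative analogue of the
  regulatory model fitted downstream),
* per-tumor subtype labels and per-TF mutation couplings (methylation /
  copy number) tied to TF expression.

Randomness is split into two streams seeded from the config: a
structural stream (baseline, coefficient matrix, TF effects, DE sets,
subtype labels, mutation couplings, drawn in that order) keyed by
``seed``, and a sample-noise stream keyed by ``sampling_seed``
(defaulting to ``seed``). Identical configs give bit-identical cohorts;
configs sharing ``seed`` but not ``sampling_seed`` share the planted
ground truth while their samples are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CentroidSet,
    ExpressionMatrix,
    LogRatioMatrix,
    MutationTable,
    MUTATION_LAYERS,
    TUMOR_GRADES,
)


class SimConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Stated world for one synthetic cohort.

    Defaults mirror the desk-scale analysis conditions: 20 tumors per
    grade against 20 normal references, planted DE counts increasing
    (50, 100, 150, 300) across the four grades with log2 effect size 2.0
    and measurement noise 0.5; a 20-TF x 200-target regulatory layer of
    density 0.02 with coefficient magnitudes in [1, 3].
    """

    n_genes: int = 2000
    n_tfs: int = 20
    n_targets: int = 200
    samples_per_grade: Mapping[str, int] = field(
        default_factory=lambda: {"PA1": 20, "AS2": 20, "AS3": 20, "GBM4": 20}
    )
    n_reference: int = 20
    de_counts: Mapping[str, int] = field(
        default_factory=lambda: {"PA1": 50, "AS2": 100, "AS3": 150, "GBM4": 300}
    )
    effect_size_range: tuple[float, float] = (2.0, 2.0)
    network_density: float = 0.02
    coeff_range: tuple[float, float] = (1.0, 3.0)
    tf_contrast_range: tuple[float, float] = (1.5, 2.5)
    tf_variation_sd: float = 1.0
    noise_sd: float = 0.5
    n_subtypes: int = 4
    centroid_separation: float = 1.0
    mutation_coupling_prob: float = 0.5
    mutation_strength_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0
    #: seed for the per-sample noise draws; None reuses ``seed``. Two configs
    #: sharing ``seed`` but differing here give independent cohorts from the
    #: same planted ground truth (for cross-cohort validation).
    sampling_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise SimConfigError("n_tfs must be smaller than n_genes")
        if self.n_tfs + self.n_targets > self.n_genes:
            raise SimConfigError("n_tfs + n_targets must not exceed n_genes")
        if self.n_genes <= 0 or self.n_reference <= 0:
            raise SimConfigError("gene and reference counts must be positive")
        if any(n <= 0 for n in self.samples_per_grade.values()):
            raise SimConfigError("samples per grade must be positive")
        if set(self.samples_per_grade) - set(TUMOR_GRADES):
            raise SimConfigError("unknown tumor grade in samples_per_grade")
        if any(n < 0 for n in self.de_counts.values()):
            raise SimConfigError("DE counts must be non-negative")
        pool = self.n_genes - self.n_tfs - self.n_targets
        if any(n > pool for n in self.de_counts.values()):
            raise SimConfigError(
                f"a DE count exceeds the {pool} background genes available"
            )
        if self.n_tfs > 0 and self.n_targets > 0:
            if not (0.0 < self.network_density < 1.0):
                raise SimConfigError("network_density must lie in (0, 1)")
            if self.network_density * self.n_tfs * self.n_targets < 1.0:
                raise SimConfigError(
                    "density * n_tfs * n_targets must be at least 1"
                )
        if self.noise_sd < 0 or self.tf_variation_sd < 0:
            raise SimConfigError("noise levels must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery testing."""

    de_sets: dict[str, list[tuple[str, str, float]]]
    coeff_matrix: pd.DataFrame  # TFs x target genes, zeros where no edge
    tf_grade_effects: pd.DataFrame  # TFs x tumor grades
    subtype_labels: pd.Series  # per tumor sample
    mutation_couplings: dict[str, dict[str, tuple[int, float]]]
    tf_mean_log_ratio: pd.Series
    noise_sd: float
    seed: int

    def true_edges(self) -> set[tuple[str, str]]:
        mat = self.coeff_matrix
        rows, cols = np.nonzero(mat.values)
        return {(mat.index[r], mat.columns[c]) for r, c in zip(rows, cols)}


def _gene_names(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    targets = [f"TG{i + 1:04d}" for i in range(config.n_targets)]
    n_bg = config.n_genes - config.n_tfs - config.n_targets
    background = [f"BG{i + 1:05d}" for i in range(n_bg)]
    return tfs, targets, background


def simulate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate one cohort (normal references + tumors of all four grades)."""
    # structural draws (steps 1-6) and sample noise (step 7) use separate
    # streams so cohorts can share a planted truth but differ in sampling
    rng = np.random.default_rng([config.seed, 0])
    sampling_seed = config.seed if config.sampling_seed is None else config.sampling_seed
    rng_samples = np.random.default_rng([sampling_seed, 1])
    tfs, targets, background = _gene_names(config)
    genes = tfs + targets + background

    # 1. baseline log2 means: typical microarray dynamic range
    baseline = pd.Series(rng.normal(7.0, 2.0, size=len(genes)), index=genes)

    # 2. sparse TF -> target coefficient matrix
    if config.n_tfs and config.n_targets:
        mask = rng.random((config.n_tfs, config.n_targets)) < config.network_density
        lo, hi = config.coeff_range
        mags = rng.uniform(lo, hi, size=mask.shape)
        signs = rng.choice([-1.0, 1.0], size=mask.shape)
        coeff = mask * mags * signs
    else:
        coeff = np.zeros((config.n_tfs, config.n_targets))
    coeff_matrix = pd.DataFrame(coeff, index=tfs, columns=targets)

    # 3. TF grade effects: mirrored PA I vs adult-grade contrast, so every
    # TF carries a strong class difference (>= 3 log2 units)
    lo, hi = config.tf_contrast_range
    pa1_eff = rng.uniform(lo, hi, size=config.n_tfs) * rng.choice(
        [-1.0, 1.0], size=config.n_tfs
    )
    tf_grade_effects = pd.DataFrame(
        {
            "PA1": pa1_eff,
            "AS2": -pa1_eff,
            "AS3": -pa1_eff,
            "GBM4": -pa1_eff,
        },
        index=tfs,
    )

    # 4. planted background DE sets, drawn independently per grade
    de_sets: dict[str, list[tuple[str, str, float]]] = {}
    elo, ehi = config.effect_size_range
    for grade in TUMOR_GRADES:
        count = int(config.de_counts.get(grade, 0))
        chosen = rng.choice(background, size=count, replace=False) if count else []
        entries = []
        for gene in chosen:
            direction = "OVER" if rng.random() < 0.5 else "UNDER"
            effect = float(rng.uniform(elo, ehi))
            if direction == "UNDER":
                effect = -effect
            entries.append((str(gene), direction, effect))
        de_sets[grade] = entries

    # 5. sample bookkeeping + subtype labels
    sample_ids: list[str] = []
    sample_grades: list[str] = []
    for i in range(config.n_reference):
        sample_ids.append(f"NORMAL_{i + 1:03d}")
        sample_grades.append("NORMAL")
    for grade in TUMOR_GRADES:
        for i in range(int(config.samples_per_grade.get(grade, 0))):
            sample_ids.append(f"{grade}_{i + 1:03d}")
            sample_grades.append(grade)
    tumor_ids = [s for s, g in zip(sample_ids, sample_grades) if g != "NORMAL"]
    subtype_names = [f"S{i + 1}" for i in range(config.n_subtypes)]
    subtype_labels = pd.Series(
        rng.choice(subtype_names, size=len(tumor_ids)), index=tumor_ids
    )

    # 6. mutation couplings: methylation anti-coupled, copy number co-coupled
    layer_signs = {"methylation": -1, "copy_number": 1}
    couplings: dict[str, dict[str, tuple[int, float]]] = {}
    slo, shi = config.mutation_strength_range
    for tf in tfs:
        couplings[tf] = {}
        for layer in MUTATION_LAYERS:
            if rng.random() < config.mutation_coupling_prob:
                couplings[tf][layer] = (layer_signs[layer], float(rng.uniform(slo, shi)))

    # 7. expression values (noise drawn last, per sample block)
    de_effect = pd.DataFrame(0.0, index=background, columns=list(TUMOR_GRADES))
    for grade, entries in de_sets.items():
        for gene, _direction, effect in entries:
            de_effect.loc[gene, grade] = effect

    values = np.empty((len(genes), len(sample_ids)))
    tf_lr_sum = np.zeros(config.n_tfs)
    n_tumors = 0
    for col, (sid, grade) in enumerate(zip(sample_ids, sample_grades)):
        if grade == "NORMAL":
            lr = np.zeros(len(genes))
            lr += rng_samples.normal(0.0, config.noise_sd, size=len(genes))
        else:
            tf_lr = (
                tf_grade_effects[grade].values
                + rng_samples.normal(0.0, config.tf_variation_sd, size=config.n_tfs)
            )
            target_lr = coeff_matrix.values.T @ tf_lr + rng_samples.normal(
                0.0, config.noise_sd, size=config.n_targets
            )
            bg_lr = de_effect[grade].values + rng_samples.normal(
                0.0, config.noise_sd, size=len(background)
            )
            lr = np.concatenate([tf_lr, target_lr, bg_lr])
            tf_lr_sum += tf_lr
            n_tumors += 1
        values[:, col] = baseline.values + lr

    tf_mean_lr = pd.Series(
        tf_lr_sum / max(n_tumors, 1), index=tfs, dtype=float
    )

    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=sample_ids),
        metadata=pd.DataFrame(
            {"grade": sample_grades, "cohort": "synthetic"}, index=sample_ids
        ),
    )
    truth = GroundTruth(
        de_sets=de_sets,
        coeff_matrix=coeff_matrix,
        tf_grade_effects=tf_grade_effects,
        subtype_labels=subtype_labels,
        mutation_couplings=couplings,
        tf_mean_log_ratio=tf_mean_lr,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return expr, truth


def resimulate(
    config: SimConfig, sampling_seed: int
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Independent cohort from the same planted ground truth."""
    return simulate_cohort(replace(config, sampling_seed=sampling_seed))


# ---------------------------------------------------------------------------
# Centroid fixtures and centroid-mixture samples
# ---------------------------------------------------------------------------


def make_centroids(
    n_genes: int,
    subtypes: int | list[str] = 4,
    separation: float = 1.0,
    seed: int = 0,
) -> CentroidSet:
    """Well-separated synthetic centroids (orthogonalized Gaussian columns).

    Each centroid column is scaled so its per-gene standard deviation is
    ``separation`` log2 units; columns are exactly orthogonal, so a pure
    noise sample correlates with each centroid independently.
    """
    if isinstance(subtypes, int):
        names = [f"S{i + 1}" for i in range(subtypes)]
    else:
        names = list(subtypes)
    if n_genes < len(names):
        raise ValueError("need at least as many genes as subtypes")
    rng = np.random.default_rng(seed)
    raw = rng.normal(size=(n_genes, len(names)))
    q, _ = np.linalg.qr(raw)
    values = q * separation * np.sqrt(n_genes)
    genes = [f"CG{i + 1:05d}" for i in range(n_genes)]
    return CentroidSet(values=pd.DataFrame(values, index=genes, columns=names))


def simulate_centroid_samples(
    centroids: CentroidSet,
    label: str,
    noise_sd: float,
    n: int,
    seed: int = 0,
) -> LogRatioMatrix:
    """Samples = the chosen centroid + iid Gaussian noise over genes."""
    if label not in centroids.subtypes:
        raise ValueError(f"unknown subtype label {label!r}")
    rng = np.random.default_rng(seed)
    base = centroids.values[label].values[:, None]
    noise = rng.normal(0.0, noise_sd, size=(len(centroids.genes), n))
    ids = [f"{label}_{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(base + noise, index=centroids.genes, columns=ids)
    metadata = pd.DataFrame({"grade": "GBM4", "cohort": "centroid_sim"}, index=ids)
    return LogRatioMatrix(values=values, metadata=metadata)


def simulate_mutation_layer(
    truth: GroundTruth,
    layer: str,
    noise_sd: float = 0.2,
    seed: int | None = None,
) -> MutationTable:
    """Per-TF mutation log-ratios coupled to mean TF expression.

    Coupled TFs get ``sign * strength * mean TF expression log-ratio``
    plus noise; uncoupled TFs are pure noise centered at zero.
    """
    if layer not in MUTATION_LAYERS:
        raise ValueError(f"layer must be one of {MUTATION_LAYERS}")
    rng = np.random.default_rng(truth.seed + 10_007 if seed is None else seed)
    values = {}
    for tf, layers in truth.mutation_couplings.items():
        mean_lr = float(truth.tf_mean_log_ratio.get(tf, 0.0))
        if layer in layers:
            sign, strength = layers[layer]
            v = sign * strength * mean_lr
        else:
            v = 0.0
        values[tf] = v + rng.normal(0.0, noise_sd)
    return MutationTable(values=pd.Series(values), layer=layer)
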