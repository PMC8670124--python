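"""Negative-binomial RNA-seq count simulator with planted differential
expression, covariates, batch effects, and cohort splitting.

This is the test bed standing in for real multi-center cohorts: counts
are drawn gene-by-gene from NB(mean, dispersion) with Var = mu + phi
mu^2, where log2 mean CPM is a linear function of a binary class label
(the planted log2 fold change), a centered age-like covariate and a
binary sex-like covariate.  Gene-wise dispersions are log-normal around
0.1 — a typical bulk RNA-seq regime that makes the mean-variance trend
non-trivial.  Splitting supports unequal cohort sizes (e.g. 1:2:4,
1:3:9), cohort-specific class fractions, and a cohort-level shift of
the continuous covariate's mean, so balanced and confounded multi-site
scenarios can be emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import CountMatrix, DesignMatrix, ValidationError
from .federation import add_batch_indicators

MILLION = 1e6


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset (defaults: a 150-sample,
    2000-gene two-class bulk RNA-seq study with 10% DE genes at |lfc|=2)."""

    n_genes: int = 2000
    n_samples: int = 150
    de_fraction: float = 0.1
    lfc: float = 2.0                  # |log2 FC| of DE genes; sign random
    lfc_sd: float = 0.0               # >0: N(+-lfc, lfc_sd) instead of point mass
    baseline_mean: float = 5.0        # log2-CPM scale
    baseline_sd: float = 2.0
    dispersion_median: float = 0.1    # gene-wise phi ~ lognormal
    dispersion_sigma: float = 0.3
    lib_size_range: tuple[float, float] = (1e6, 3e6)
    class_fraction: float = 0.5
    age_effect_sd: float = 0.05       # per SD of age, on 20% of genes
    sex_effect_sd: float = 0.1        # on 10% of genes
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.lib_size_range[0] <= 0:
            raise ValidationError("library sizes must be positive")
        if not 0 < self.class_fraction < 1:
            raise ValidationError("class_fraction must lie in (0, 1)")


@dataclass
class _NBModel:
    """Private generative state: everything needed to (re)draw counts."""

    log_cpm_mean: np.ndarray   # genes x samples
    phi: np.ndarray            # genes
    lib_size: np.ndarray       # samples
    seed: int


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    gene_ids: list[str]
    sample_ids: list[str]
    is_de: np.ndarray
    true_lfc: np.ndarray
    class_label: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    cohort_assignment: np.ndarray | None = None
    model: _NBModel | None = field(default=None, repr=False)


def _draw_counts(model: _NBModel) -> np.ndarray:
    """Deterministic NB draw: counts ~ NB(mu, phi), Var = mu + phi mu^2."""
    rng = np.random.default_rng([model.seed, 7919])
    mu = model.lib_size[np.newaxis, :] / MILLION * 2.0**model.log_cpm_mean
    r = 1.0 / model.phi[:, np.newaxis]
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(np.int64)


def generate_dataset(
    spec: SimulationSpec,
) -> tuple[CountMatrix, DesignMatrix, GroundTruth]:
    """Simulate one pooled dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, 104729])
    G, n = spec.n_genes, spec.n_samples
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{i:05d}" for i in range(n)]

    n_class1 = int(round(spec.class_fraction * n))
    if not 0 < n_class1 < n:
        raise ValidationError("class_fraction leaves one class empty")
    class_label = np.zeros(n, dtype=np.int64)
    class_label[rng.choice(n, size=n_class1, replace=False)] = 1

    age = rng.normal(50.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    age_c = (age - 50.0) / 10.0

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)
    phi = rng.lognormal(np.log(spec.dispersion_median), spec.dispersion_sigma, G)
    lib = rng.uniform(*spec.lib_size_range, size=n)

    n_de = int(round(spec.de_fraction * G))
    is_de = np.zeros(G, dtype=bool)
    is_de[rng.choice(G, size=n_de, replace=False)] = True
    signs = rng.choice([-1.0, 1.0], size=G)
    magnitude = np.full(G, spec.lfc)
    if spec.lfc_sd > 0:
        magnitude = rng.normal(spec.lfc, spec.lfc_sd, size=G)
    true_lfc = np.where(is_de, signs * magnitude, 0.0)

    age_coef = np.where(
        rng.random(G) < 0.2, rng.normal(0.0, spec.age_effect_sd, G), 0.0
    )
    sex_coef = np.where(
        rng.random(G) < 0.1, rng.normal(0.0, spec.sex_effect_sd, G), 0.0
    )

    log_cpm_mean = (
        baseline[:, np.newaxis]
        + np.outer(true_lfc, class_label)
        + np.outer(age_coef, age_c)
        + np.outer(sex_coef, sex)
    )
    model = _NBModel(log_cpm_mean=log_cpm_mean, phi=phi, lib_size=lib, seed=spec.seed)
    counts = _draw_counts(model)

    design = DesignMatrix(
        sample_ids=sample_ids,
        column_names=["intercept", "group", "age", "sex"],
        values=np.column_stack(
            [np.ones(n), class_label.astype(float), age_c, sex]
        ),
        group_columns=["group"],
    )
    truth = GroundTruth(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        is_de=is_de,
        true_lfc=true_lfc,
        class_label=class_label,
        age=age,
        sex=sex,
        model=model,
    )
    return CountMatrix(gene_ids, sample_ids, counts), design, truth


def _apportion(ratios: list[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n samples into len(ratios) cohorts."""
    total = sum(ratios)
    quotas = [r / total * n for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    rem = n - sum(sizes)
    order = np.argsort([s - q for s, q in zip(sizes, quotas)])
    for j in order[:rem]:
        sizes[j] += 1
    return sizes


def _class_counts(
    sizes: list[int], fractions: list[float], total_class1: int
) -> list[int]:
    """Integer class-1 counts per cohort, nearest to fractions * sizes,
    summing to the available class-1 pool.  Infeasible requests (a cohort
    more than one sample away from its target) raise an error."""
    targets = [f * s for f, s in zip(fractions, sizes)]
    counts = [int(round(t)) for t in targets]
    counts = [min(max(c, 0), s) for c, s in zip(counts, sizes)]
    deficit = total_class1 - sum(counts)
    step = 1 if deficit > 0 else -1
    for _ in range(abs(deficit)):
        # adjust the cohort that stays closest to its target
        candidates = [
            (abs(counts[j] + step - targets[j]), j)
            for j in range(len(sizes))
            if 0 <= counts[j] + step <= sizes[j]
        ]
        if not candidates:
            break
        _, j = min(candidates)
        counts[j] += step
    if sum(counts) != total_class1:
        raise ValidationError(
            f"infeasible class fractions: need {total_class1} class-1 samples "
            f"total but cohort targets allow {sum(counts)}"
        )
    for c, t in zip(counts, targets):
        if abs(c - t) > 1:
            raise ValidationError(
                f"infeasible class fractions: a cohort is {abs(c - t):.2f} "
                "samples away from its requested fraction"
            )
    return counts


def split_cohorts(
    counts: CountMatrix,
    design: DesignMatrix,
    truth: GroundTruth,
    ratios: list[float],
    class_fractions: list[float] | None = None,
    confounder_shift: list[float] | None = None,
    seed: int = 0,
) -> list[tuple[CountMatrix, DesignMatrix]]:
    """Partition one dataset into cohorts with the requested structure.

    ``ratios`` fixes relative cohort sizes (e.g. [1, 3, 9]);
    ``class_fractions`` the per-cohort fraction of class-1 samples
    (realized within one sample); ``confounder_shift`` biases cohort
    assignment toward samples with higher/lower values of the age-like
    covariate via exponential tilting, shifting the cohort means of a
    covariate that may deliberately be left out of the model (an unknown
    confounder).  The cohorts are an exact disjoint partition of the
    samples; the assignment is recorded in ``truth.cohort_assignment``.
    """
    rng = np.random.default_rng([seed, 15485863])
    n = counts.n_samples
    m = len(ratios)
    sizes = _apportion(list(ratios), n)
    labels = truth.class_label
    if class_fractions is None:
        class_fractions = [float(labels.mean())] * m
    if confounder_shift is None:
        confounder_shift = [0.0] * m
    if len(class_fractions) != m or len(confounder_shift) != m:
        raise ValidationError("per-cohort parameter lists must match ratios")
    c1 = _class_counts(sizes, list(class_fractions), int(labels.sum()))
    c0 = [s - c for s, c in zip(sizes, c1)]
    if any(c < 0 for c in c0):
        raise ValidationError("infeasible class fractions: cohort overfull")

    age_z = (truth.age - truth.age.mean()) / max(truth.age.std(), 1e-12)
    assignment = np.full(n, -1, dtype=np.int64)
    for label, need in ((1, c1), (0, c0)):
        pool = list(np.flatnonzero(labels == label))
        for j in range(m):
            take = need[j]
            if take == 0:
                continue
            pool_arr = np.array(pool)
            w = np.exp(confounder_shift[j] * age_z[pool_arr])
            chosen = rng.choice(
                len(pool_arr), size=take, replace=False, p=w / w.sum()
            )
            for idx in pool_arr[chosen]:
                assignment[idx] = j
            pool = [s for s in pool if assignment[s] < 0]
    truth.cohort_assignment = assignment

    cohorts = []
    for j in range(m):
        idx = np.flatnonzero(assignment == j)
        idx = idx[rng.permutation(idx.size)]
        cm = CountMatrix(
            list(counts.gene_ids),
            [counts.sample_ids[i] for i in idx],
            counts.counts[:, idx],
        )
        dm = DesignMatrix(
            [design.sample_ids[i] for i in idx],
            list(design.column_names),
            design.values[idx],
            list(design.group_columns),
        )
        cohorts.append((cm, dm))
    return cohorts


def inject_batch_effect(
    cohorts: list[tuple[CountMatrix, DesignMatrix]],
    truth: GroundTruth,
    shifts: list[float],
    affected_gene_fraction: float = 0.3,
    seed: int = 0,
) -> list[tuple[CountMatrix, DesignMatrix]]:
    """Plant cohort-level batch effects and add indicator covariates.

    For a random ``affected_gene_fraction`` of genes, the NB mean of
    every sample in cohort j is multiplied by 2^shifts[j] and counts are
    regenerated from the modified model (all-zero shifts reproduce the
    original counts exactly).  Each returned design gains m-1 binary
    dataset-indicator columns so the linear model can absorb the effect.
    """
    if truth.model is None or truth.cohort_assignment is None:
        raise ValidationError("truth must carry the generative model and "
                              "a cohort assignment")
    if len(shifts) != len(cohorts):
        raise ValidationError("one shift per cohort required")
    if not all(np.isfinite(shifts)):
        raise ValidationError("shifts must be finite")
    rng = np.random.default_rng([seed, 32452843])
    G = len(truth.gene_ids)
    affected = rng.random(G) < affected_gene_fraction
    log_mean = truth.model.log_cpm_mean.copy()
    for j, shift in enumerate(shifts):
        if shift == 0.0:
            continue
        cols = np.flatnonzero(truth.cohort_assignment == j)
        log_mean[np.ix_(affected, cols)] += shift
    new_counts = _draw_counts(replace(truth.model, log_cpm_mean=log_mean))

    col_of = {s: i for i, s in enumerate(truth.sample_ids)}
    designs = add_batch_indicators([dm for _, dm in cohorts])
    out = []
    for (cm, _), dm in zip(cohorts, designs):
        idx = np.array([col_of[s] for s in cm.sample_ids], dtype=int)
        out.append(
            (CountMatrix(list(cm.gene_ids), list(cm.sample_ids),
                         new_counts[:, idx]), dm)
        )
    return out
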