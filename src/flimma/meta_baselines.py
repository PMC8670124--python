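"""Meta-analysis baselines and evaluation metrics.

Four classical combiners operate on per-cohort differential-expression
results (each produced by running the centralized pipeline on one
cohort alone): Fisher's and Stouffer's p-value combination, the
DerSimonian-Laird random-effects model (REM), and the permutation-based
Rank Product.  Fisher/Stouffer/RankProd combine directionally — the
two-sided cohort p-values are split into one-sided halves by the sign
of the local fold change, so opposite-direction effects cancel instead
of reinforcing.  All combiners are invariant to cohort order.

:func:`evaluate` scores any result table against the pooled oracle with
the metrics used to compare privacy-aware methods: RMSE and Pearson /
Spearman correlation on -log10 p, and precision / recall / F1 on the
DE-call sets (|log2 FC| > 1, BH-adjusted p < 0.05 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import AnalysisConfig, DEResultTable, ValidationError
from .inference_stats import bh_adjust, de_calls

P_FLOOR = 1e-300


@dataclass
class CohortResult:
    """One cohort's local DE statistics, input to the combiners."""

    gene_ids: list[str]
    log_fc: np.ndarray
    p_value: np.ndarray        # two-sided
    effect_se: np.ndarray      # standard error of log_fc
    n_samples: int


@dataclass
class MetricReport:
    rmse: float
    precision: float
    recall: float
    f1: float
    pearson_r: float
    spearman_rho: float
    fp: int
    fn: int


def _check_cohorts(cohorts: list[CohortResult], min_k: int = 2) -> None:
    if len(cohorts) < min_k:
        raise ValidationError(f"need at least {min_k} cohorts")
    genes = cohorts[0].gene_ids
    for c in cohorts[1:]:
        if c.gene_ids != genes:
            raise ValidationError("cohorts must share an identical gene universe")


def _one_sided_halves(c: CohortResult) -> tuple[np.ndarray, np.ndarray]:
    """Split a two-sided p into (up, down) one-sided halves by effect sign."""
    p = np.clip(c.p_value, P_FLOOR, 1.0)
    half = p / 2.0
    up = np.where(c.log_fc >= 0, half, 1.0 - half)
    return up, 1.0 - up


def fisher_combine(cohorts: list[CohortResult]) -> np.ndarray:
    """Fisher's chi-square combination, directional, two-sided output.

    Per direction: chi2 = -2 sum_i ln(p_one_sided_i) with 2K df; the
    final two-sided p is min(1, 2 * min(p_up, p_down)).
    """
    _check_cohorts(cohorts)
    k = len(cohorts)
    out = []
    for direction in range(2):
        halves = [_one_sided_halves(c)[direction] for c in cohorts]
        chi2 = -2.0 * np.sum(
            [np.log(np.clip(h, P_FLOOR, 1.0)) for h in halves], axis=0
        )
        out.append(stats.chi2.sf(chi2, df=2 * k))
    p_up, p_down = out
    return np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))


def stouffer_combine(cohorts: list[CohortResult]) -> np.ndarray:
    """Stouffer's weighted z-combination (weights sqrt of cohort size)."""
    _check_cohorts(cohorts)
    w = np.array([np.sqrt(c.n_samples) for c in cohorts])
    zs = []
    for c in cohorts:
        p = np.clip(c.p_value, P_FLOOR, 1.0)
        z = stats.norm.isf(p / 2.0)          # |z| from the two-sided p
        zs.append(z * np.sign(np.where(c.log_fc == 0, 1.0, c.log_fc)))
    Z = np.tensordot(w, np.array(zs), axes=1) / np.sqrt(np.sum(w**2))
    return 2.0 * stats.norm.sf(np.abs(Z))


def rem_combine(cohorts: list[CohortResult]) -> tuple[np.ndarray, np.ndarray]:
    """DerSimonian-Laird random-effects combination.

    Per gene: fixed weights w_i = 1/v_i; Q = sum w_i (e_i - e_bar)^2;
    tau^2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w)); random
    weights w*_i = 1/(v_i + tau^2); pooled effect = sum w* e / sum w*
    with SE 1/sqrt(sum w*) and a two-sided normal p-value.
    Returns (pooled effect, p).
    """
    _check_cohorts(cohorts)
    e = np.array([c.log_fc for c in cohorts])           # K x G
    v = np.array([c.effect_se**2 for c in cohorts])
    if np.any(v <= 0):
        raise ValidationError("effect variances must be positive")
    k = e.shape[0]
    w = 1.0 / v
    sw = w.sum(axis=0)
    ebar = (w * e).sum(axis=0) / sw
    q = (w * (e - ebar) ** 2).sum(axis=0)
    denom = sw - (w**2).sum(axis=0) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.where(denom > 0, np.maximum(0.0, (q - (k - 1)) / denom), 0.0)
    wr = 1.0 / (v + tau2[np.newaxis, :])
    effect = (wr * e).sum(axis=0) / wr.sum(axis=0)
    se = 1.0 / np.sqrt(wr.sum(axis=0))
    p = 2.0 * stats.norm.sf(np.abs(effect / se))
    return effect, p


def _rank_matrix(log_fc: np.ndarray, direction: str) -> np.ndarray:
    """Within-cohort ranks (average ties): rank 1 = most extreme in direction."""
    vals = -log_fc if direction == "up" else log_fc
    return np.apply_along_axis(stats.rankdata, 1, vals)


def rank_product(
    cohorts: list[CohortResult],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation rank-product p-values, one per direction.

    Per direction, genes are ranked within each cohort by fold change
    (rank 1 = most up- or down-regulated); RP = geometric mean of ranks.
    The null shuffles ranks independently within each cohort; the
    p-value is the add-one-corrected fraction of null RP values <= the
    observed one.
    """
    _check_cohorts(cohorts)
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    ranks = {
        d: np.array(
            [_rank_matrix(c.log_fc[np.newaxis, :], d)[0] for c in cohorts]
        )
        for d in ("up", "down")
    }
    k, g = ranks["up"].shape
    obs = {d: np.log(r).mean(axis=0) for d, r in ranks.items()}
    exceed = {d: np.zeros(g, dtype=np.int64) for d in ranks}
    # one permutation set shared by both directions, so that negating all
    # fold changes exactly swaps the up and down p-values
    for _ in range(n_perm):
        perms = [rng.permutation(g) for _ in range(k)]
        for d, r in ranks.items():
            null = np.sort(
                np.log([row[p] for row, p in zip(r, perms)]).mean(axis=0)
            )
            exceed[d] += np.searchsorted(null, obs[d], side="right")
    return tuple((exceed[d] + 1.0) / (n_perm * g + 1.0) for d in ("up", "down"))


def combine_fold_changes(cohorts: list[CohortResult]) -> np.ndarray:
    """Global fold change = unweighted mean of local fold changes.

    Used by every combiner except REM, which reports its own weighted
    effect instead.
    """
    if not cohorts:
        raise ValidationError("need at least one cohort")
    return np.mean([c.log_fc for c in cohorts], axis=0)


def cohort_results(
    clients: list,
    config: AnalysisConfig,
) -> list[CohortResult]:
    """Run the centralized pipeline on each cohort alone and align results.

    Each cohort is analyzed independently (single-site run, no masking
    needed); the outputs are restricted to the genes surviving the
    expression filter in *every* cohort, in the first cohort's order.
    The effect SE is the moderated one, unscaled_se * s_post.
    """
    from dataclasses import replace

    from .federation import run_flimma_detailed

    runs = []
    for cm, dm in clients:
        cfg = replace(config, masking=False)
        runs.append(run_flimma_detailed([(cm, dm)], cfg))
    shared = set(runs[0].gene_ids)
    for r in runs[1:]:
        shared &= set(r.gene_ids)
    order = [g for g in runs[0].gene_ids if g in shared]
    if not order:
        raise ValidationError("no gene survives filtering in every cohort")
    out = []
    for (cm, _), r in zip(clients, runs):
        pos = {g: i for i, g in enumerate(r.gene_ids)}
        idx = np.array([pos[g] for g in order], dtype=int)
        j = r.state.column_names.index(config.coefficient)
        tab = r.table.reindex(order)
        out.append(
            CohortResult(
                gene_ids=list(order),
                log_fc=r.state.beta[idx, j],
                p_value=tab.p_value,
                effect_se=r.effect_se(config.coefficient)[idx],
                n_samples=cm.n_samples,
            )
        )
    return out


def meta_table(
    cohorts: list[CohortResult],
    method: str,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> DEResultTable:
    """Run one combiner and package the result as a DE table."""
    _check_cohorts(cohorts)
    if method == "fisher":
        p = fisher_combine(cohorts)
        lfc = combine_fold_changes(cohorts)
    elif method == "stouffer":
        p = stouffer_combine(cohorts)
        lfc = combine_fold_changes(cohorts)
    elif method == "rem":
        lfc, p = rem_combine(cohorts)
    elif method == "rankprod":
        p_up, p_down = rank_product(cohorts, n_perm=n_perm, rng=rng)
        p = np.minimum(1.0, 2.0 * np.minimum(p_up, p_down))
        lfc = combine_fold_changes(cohorts)
    else:
        raise ValidationError(f"unknown meta-analysis method {method!r}")
    zeros = np.zeros_like(p)
    return DEResultTable(
        gene_ids=list(cohorts[0].gene_ids),
        log_fc=lfc,
        ave_expr=zeros,
        t_mod=zeros,
        p_value=p,
        adj_p_value=bh_adjust(p),
    )


def evaluate(
    candidate: DEResultTable,
    truth: DEResultTable,
    config: AnalysisConfig | None = None,
) -> MetricReport:
    """Score a candidate table against the pooled-oracle truth table."""
    if config is None:
        config = AnalysisConfig()
    if set(candidate.gene_ids) != set(truth.gene_ids):
        raise ValidationError("candidate and truth gene universes differ")
    order = truth.gene_ids
    cand = candidate.reindex(order)
    nl_c = -np.log10(np.clip(cand.p_value, P_FLOOR, 1.0))
    nl_t = -np.log10(np.clip(truth.p_value, P_FLOOR, 1.0))
    rmse = float(np.sqrt(np.mean((nl_c - nl_t) ** 2)))
    if np.ptp(nl_c) == 0 or np.ptp(nl_t) == 0:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(nl_c, nl_t)[0])
        spearman = float(stats.spearmanr(nl_c, nl_t)[0])
    called_c = de_calls(candidate, config.lfc_threshold, config.alpha)
    called_t = de_calls(truth, config.lfc_threshold, config.alpha)
    tp = len(called_c & called_t)
    fp = len(called_c - called_t)
    fn = len(called_t - called_c)
    precision = tp / (tp + fp) if (tp + fp) else (1.0 if not called_t else 0.0)
    recall = tp / (tp + fn) if (tp + fn) else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return MetricReport(
        rmse=rmse,
        precision=precision,
        recall=recall,
        f1=f1,
        pearson_r=pearson,
        spearman_rho=spearman,
        fp=fp,
        fn=fn,
    )
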