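"""Aggregator-side empirical-Bayes moderation, moderated t, BH, DE calls.

The per-gene residual variances are shrunk toward a scaled
inverse-chi-square prior fitted by the closed-form moment method on the
log variances: with z = log(s^2) and equal residual df across genes,

    e    = z - digamma(df/2) + log(df/2)
    evar = var(e) - trigamma(df/2)

If evar > 0 the prior df is d0 = 2 * trigamma^-1(evar) and the prior
variance s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2)); otherwise the
prior is degenerate (d0 = +inf, all posterior variances equal s0^2 =
exp(mean(e))).  Posterior variances are the usual convex combination
(d0 s0^2 + df s^2) / (d0 + df), and the moderated t uses d0 + df
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data_model import AnalysisConfig, DEResultTable, ValidationError
from .fed_linear_voom import GlobalModelState


@dataclass
class SqueezeResult:
    d0: float                 # prior degrees of freedom, may be +inf
    s0_sq: float              # prior variance
    s_post_sq: np.ndarray     # posterior variance per gene


def trigamma_inverse(y: float, rtol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by safeguarded Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf), so Newton
    from any positive start converges monotonically once bracketed.
    """
    if not y > 0:
        raise ValidationError("trigamma_inverse requires y > 0")
    if y > 1e7:          # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / np.sqrt(y)
    if y < 1e-6:         # trigamma(x) ~ 1/x as x -> inf
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(special.polygamma(1, x_new) - y) <= rtol * y:
            return float(x_new)
        x = x_new
    return float(x)


def squeeze_var(sigma_sq: np.ndarray, df_residual: int) -> SqueezeResult:
    """Moment fit of the scaled inverse-chi-square prior + posterior variances."""
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    if df_residual < 1:
        raise ValidationError("df_residual must be >= 1")
    pos = sigma_sq > 0
    if int(pos.sum()) < 2:
        raise ValidationError(
            "need at least two genes with positive residual variance "
            "to fit the variance prior"
        )
    df = float(df_residual)
    z = np.log(sigma_sq[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    g = e.size
    evar = float(np.var(e)) * g / (g - 1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
        s_post = (d0 * s0_sq + df * sigma_sq) / (d0 + df)
    else:
        # degenerate prior: no excess dispersion beyond chi-square noise,
        # so the prior variance is the plain mean of the sample variances
        d0 = np.inf
        s0_sq = float(np.mean(np.maximum(sigma_sq, 0.0)))
        s_post = np.full_like(sigma_sq, s0_sq)
    return SqueezeResult(d0=float(d0), s0_sq=s0_sq, s_post_sq=s_post)


def moderated_t(
    beta_j: np.ndarray,
    unscaled_se_j: np.ndarray,
    s_post_sq: np.ndarray,
    d0: float,
    df_residual: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values for one coefficient.

    t = beta / (unscaled_se * s_post); the reference distribution is
    Student t with d0 + df_residual degrees of freedom (normal when the
    prior df is infinite).
    """
    t = beta_j / (unscaled_se_j * np.sqrt(s_post_sq))
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=d0 + df_residual)
    return t, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_calls(
    table: DEResultTable, lfc_threshold: float = 1.0, alpha: float = 0.05
) -> set[str]:
    """Genes called differentially expressed: |log2 FC| > threshold AND
    BH-adjusted p < alpha (both strict)."""
    mask = (np.abs(table.log_fc) > lfc_threshold) & (table.adj_p_value < alpha)
    return {g for g, m in zip(table.gene_ids, mask) if m}


def infer_full(
    state: GlobalModelState, gene_ids: list[str], config: AnalysisConfig
) -> tuple[DEResultTable, SqueezeResult]:
    """eBayes moderation + moderated t + BH for the tested coefficient."""
    j = state.column_names.index(config.coefficient)
    squeeze = squeeze_var(state.sigma**2, state.df_residual)
    t, p = moderated_t(
        state.beta[:, j],
        state.unscaled_se[:, j],
        squeeze.s_post_sq,
        squeeze.d0,
        state.df_residual,
    )
    table = DEResultTable(
        gene_ids=list(gene_ids),
        log_fc=state.beta[:, j],
        ave_expr=state.amean,
        t_mod=t,
        p_value=p,
        adj_p_value=bh_adjust(p),
    )
    return table, squeeze


def infer(
    state: GlobalModelState, gene_ids: list[str], config: AnalysisConfig
) -> DEResultTable:
    return infer_full(state, gene_ids, config)[0]
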