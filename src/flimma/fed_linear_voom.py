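"""Federated per-gene linear regression and voom precision weights.

The per-gene weighted least-squares fit is federated through masked
aggregation of the normal-equation blocks: each client contributes
(X_i^T W_i X_i, X_i^T W_i Y_i) under Gaussian masking; the aggregator
denoises their sums and solves for the coefficients.  Residual variance
is likewise assembled from masked per-client sums of squared errors.

The mean-variance trend (LOWESS of sqrt residual SD against average
log2 count) is fitted wholly on the aggregator from global per-gene
statistics; clients turn the broadcast trend into per-observation
precision weights w = trend(fitted log2 count)^-4 locally.

Two passes: pass 1 fits with unit weights (following the plain
sum-of-squares definition of the residual variance), derives the trend
and the weights; pass 2 refits with the voom weights, using the
weighted SSE so that the residual variance matches the weighted
regression the moderated t-statistic assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .data_model import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .federation import FederatedNetwork

logger = logging.getLogger("flimma")

LOG2_MILLION = np.log2(1e6)
COND_LIMIT = 1e12       # condition number above which a fit is declared singular
TREND_FLOOR = 1e-6      # lower bound on trend values, keeps weights finite
LOWESS_SPAN = 0.5
LOWESS_ITER = 3


@dataclass
class GlobalModelState:
    """The aggregator's view of the fitted per-gene linear models."""

    beta: np.ndarray            # genes x k, log2-CPM units
    unscaled_se: np.ndarray     # genes x k, sqrt(diag((X'WX)^-1))
    sigma: np.ndarray           # genes, residual standard deviation
    amean: np.ndarray           # genes, mean log2-CPM over pooled samples
    df_residual: int            # pooled n - k
    column_names: list[str]


@dataclass
class TrendCurve:
    """Piecewise-linear mean-variance trend with clamp-to-knot extrapolation."""

    x: np.ndarray   # strictly increasing average log2 counts
    y: np.ndarray   # sqrt residual SD at each knot, floored > 0

    def __call__(self, xnew: np.ndarray) -> np.ndarray:
        return np.interp(xnew, self.x, self.y)  # np.interp clamps outside range


def local_normal_equations(
    X: np.ndarray, Y: np.ndarray, W: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One client's contribution to the per-gene normal equations.

    X is samples x k, Y is genes x samples, W (optional) genes x samples
    positive weights.  Returns (XtWX: genes x k x k, XtWY: genes x k);
    with unit weights XtWX is identical across genes but still returned
    batched for a uniform interface.
    """
    if W is None:
        W = np.ones_like(Y)
    if not np.all(np.isfinite(W)) or np.any(W <= 0):
        raise ValidationError("weights must be finite and > 0")
    XtWX = np.einsum("gs,si,sj->gij", W, X, X, optimize=True)
    XtWY = np.einsum("gs,si->gi", W * Y, X, optimize=True)
    return XtWX, XtWY


def global_fit(XtWX: np.ndarray, XtWY: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve the denoised normal equations per gene.

    Returns (beta: genes x k, unscaled_se: genes x k) where the unscaled
    standard errors are sqrt(diag((X^T W X)^-1)) — the factor the
    residual SD multiplies to give the coefficient standard error.
    """
    cond = np.linalg.cond(XtWX)
    bad = np.flatnonzero(~np.isfinite(cond) | (cond > COND_LIMIT))
    if bad.size:
        raise ValidationError(
            f"singular or ill-conditioned design for {bad.size} gene(s) "
            f"(first indices {bad[:5].tolist()}); check for collinear columns"
        )
    inv = np.linalg.inv(XtWX)
    beta = np.einsum("gij,gj->gi", inv, XtWY)
    unscaled_se = np.sqrt(np.diagonal(inv, axis1=1, axis2=2))
    return beta, unscaled_se


def local_sse(
    X: np.ndarray, beta: np.ndarray, Y: np.ndarray, W: np.ndarray | None = None
) -> np.ndarray:
    """Per-gene (weighted) sum of squared residuals on one client."""
    fitted = beta @ X.T                   # genes x samples
    resid2 = (Y - fitted) ** 2
    if W is not None:
        resid2 = W * resid2
    return resid2.sum(axis=1)


def global_sigma(sse: np.ndarray, n_total: int, k: int) -> tuple[np.ndarray, int]:
    """Residual SD per gene from the denoised pooled SSE."""
    df = n_total - k
    if df < 1:
        raise ValidationError(f"non-positive residual df: n={n_total}, k={k}")
    # Gaussian-mask cancellation can leave a tiny negative where SSE ~ 0
    return np.sqrt(np.maximum(sse, 0.0) / df), df


def fit_trend(
    amean: np.ndarray, sigma: np.ndarray, mean_log2_lib: float
) -> TrendCurve:
    """LOWESS mean-variance trend on the aggregator.

    x = average log2 count = amean + mean(log2(effective lib size + 1))
    - log2(1e6); y = sqrt(residual SD).  Span 0.5 with 3 robustifying
    iterations; a degenerate x-range falls back to a constant trend at
    the median of y.
    """
    if amean.size < 10:
        raise ValidationError("too few genes to fit a mean-variance trend")
    sx = amean + mean_log2_lib - LOG2_MILLION
    sy = np.sqrt(sigma)
    if np.ptp(sx) == 0:
        const = max(float(np.median(sy)), TREND_FLOOR)
        return TrendCurve(np.array([0.0, 1.0]) + sx[0], np.array([const, const]))
    delta = 0.01 * float(np.ptp(sx))
    fitted = sm_lowess(
        sy, sx, frac=LOWESS_SPAN, it=LOWESS_ITER, delta=delta, return_sorted=True
    )
    xs, ys = fitted[:, 0], fitted[:, 1]
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.zeros_like(ux)
    cnt = np.zeros_like(ux)
    np.add.at(uy, inv, ys)
    np.add.at(cnt, inv, 1.0)
    uy /= cnt
    return TrendCurve(ux, np.maximum(uy, TREND_FLOOR))


def local_voom_weights(
    X: np.ndarray,
    beta: np.ndarray,
    eff_lib_sizes: np.ndarray,
    trend: TrendCurve,
) -> np.ndarray:
    """Per-observation precision weights from the broadcast trend.

    The fitted log2 count for gene g, sample s is x_s beta_g +
    log2(effective lib size_s + 1) - log2(1e6); the weight is the trend
    value there, raised to the -4 (inverse predicted variance of
    log-CPM).  Interpolation clamps to the knot range, so weights are
    always finite and positive.
    """
    fitted_cpm = beta @ X.T  # genes x samples, log2-CPM scale
    lam = fitted_cpm + (np.log2(eff_lib_sizes + 1.0) - LOG2_MILLION)[np.newaxis, :]
    return trend(lam) ** -4.0


def run_two_pass(net: "FederatedNetwork") -> GlobalModelState:
    """Full federated voom + weighted fit (the two blue fitting steps)."""
    from .fed_preprocess import effective_lib_size  # local import: no cycle at load

    clients = net.clients
    k = clients[0].design.k
    n_total = net.sum_int_scalar("fit_n_samples", [c.m_i for c in clients])
    if n_total <= k:
        raise ValidationError(
            f"pooled sample count {n_total} must exceed design rank {k}"
        )
    G = clients[0].log_cpm.shape[0]

    # average log2-CPM per gene (masked sum of local row sums)
    row_sums = net.sum_real(
        "amean_row_sums", [c.log_cpm.sum(axis=1) for c in clients]
    )
    amean = row_sums / n_total

    # pass 1: unweighted fit --------------------------------------------------
    xtx = net.sum_real(
        "pass1_xtx", [c.design.values.T @ c.design.values for c in clients]
    )
    xty = net.sum_real(
        "pass1_xty", [c.log_cpm @ c.design.values for c in clients]
    )
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise ValidationError(
            "pooled design matrix is rank deficient or ill conditioned "
            f"(condition number {cond:.3g}); columns "
            f"{clients[0].design.column_names} are collinear when pooled"
        )
    beta1, _ = global_fit(
        np.broadcast_to(xtx, (G, k, k)), xty
    )
    sse1 = net.sum_real(
        "pass1_sse",
        [local_sse(c.design.values, beta1, c.log_cpm) for c in clients],
    )
    sigma1, _ = global_sigma(sse1, n_total, k)

    # mean log2 effective library size (one masked scalar round)
    log2_lib_sum = float(
        net.sum_real(
            "mean_log2_lib",
            [
                [
                    float(
                        np.log2(
                            effective_lib_size(c.lib_sizes, c.norm_factors) + 1.0
                        ).sum()
                    )
                ]
                for c in clients
            ],
        )[0]
    )
    mean_log2_lib = log2_lib_sum / n_total

    trend = fit_trend(amean, sigma1, mean_log2_lib)

    def set_weights(c) -> None:
        eff = effective_lib_size(c.lib_sizes, c.norm_factors)
        c.weights = local_voom_weights(c.design.values, beta1, eff, trend)

    net.broadcast(set_weights)

    # pass 2: voom-weighted fit ----------------------------------------------
    payloads = [
        local_normal_equations(c.design.values, c.log_cpm, c.weights)
        for c in clients
    ]
    xtwx = net.sum_real("pass2_xtwx", [p[0] for p in payloads])
    xtwy = net.sum_real("pass2_xtwy", [p[1] for p in payloads])
    beta2, unscaled_se = global_fit(xtwx, xtwy)
    sse2 = net.sum_real(
        "pass2_sse",
        [
            local_sse(c.design.values, beta2, c.log_cpm, c.weights)
            for c in clients
        ],
    )
    sigma2, df = global_sigma(sse2, n_total, k)

    return GlobalModelState(
        beta=beta2,
        unscaled_se=unscaled_se,
        sigma=sigma2,
        amean=amean,
        df_residual=df,
        column_names=list(clients[0].design.column_names),
    )
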