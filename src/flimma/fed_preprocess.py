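"""Federated gene filtering, upper-quartile normalization, and log-CPM.

Everything exchanged in this module is either a per-gene aggregate
(total counts, CPM-pass counts), a global scalar (pooled sample counts,
sums of log quantiles, order-statistic counts for the median library
size) or a per-sample scalar normalization factor — never a per-sample
expression value.

Filtering follows the two filterByExpr-style rules: a gene is kept iff

* its pooled total count strictly exceeds ``min_total_count``, and
* at least ``min_n_samples`` pooled samples have CPM >= the cutoff
  ``min_count / median_library_size * 1e6``, where CPM uses each
  sample's own (raw, pre-normalization) library size and
  ``min_n_samples`` is the smallest pooled group size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .data_model import AnalysisConfig, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .federation import FederatedNetwork

logger = logging.getLogger("flimma")

MILLION = 1e6


@dataclass
class FilterDecision:
    """Outcome of the federated expression filter."""

    keep: np.ndarray            # boolean mask over the harmonized gene universe
    cpm_cutoff: float
    min_n_samples: int
    median_lib_size: float


@dataclass
class NormFactors:
    """Per-sample upper-quartile normalization factors (pooled view)."""

    sample_ids: list[str]
    lib_size: np.ndarray
    uq_statistic: np.ndarray
    scaled_factor: np.ndarray


def _ensure_lib_sizes(net: "FederatedNetwork") -> None:
    for c in net.clients:
        if c.lib_sizes is None:
            c.lib_sizes = c.counts.library_sizes().astype(np.int64)


def federated_median_lib_size(net: "FederatedNetwork") -> float:
    """Exact median of the pooled library sizes via masked binary search.

    Library sizes are integers, so the j-th pooled order statistic can be
    located by bisection on the value range: each iteration exchanges
    only the masked count of samples with library size <= pivot.  For an
    even pooled count the median is the mean of the two middle order
    statistics.
    """
    _ensure_lib_sizes(net)
    n = net.sum_int_scalar("median_n_samples", [c.m_i for c in net.clients])
    if n == 0:
        raise ValidationError("no samples: cannot compute median library size")
    hi = net.sum_int_scalar(
        "median_total_reads", [int(c.lib_sizes.sum()) for c in net.clients]
    )

    def kth_smallest(k: int) -> int:
        lo_v, hi_v = 0, hi
        while lo_v < hi_v:
            mid = (lo_v + hi_v) // 2
            cnt = net.sum_int_scalar(
                "median_count_leq",
                [int(np.count_nonzero(c.lib_sizes <= mid)) for c in net.clients],
            )
            if cnt >= k:
                hi_v = mid
            else:
                lo_v = mid + 1
        return lo_v

    if n % 2 == 1:
        return float(kth_smallest((n + 1) // 2))
    return (kth_smallest(n // 2) + kth_smallest(n // 2 + 1)) / 2.0


def _min_group_size(net: "FederatedNetwork", config: AnalysisConfig) -> int:
    """Smallest pooled group size, from masked group-indicator column sums.

    If exactly one 0/1 group column is given the two-group design is
    implied, so the complementary group (samples with a 0) is included
    in the minimum.  Without any group column the tested coefficient is
    used when it is a 0/1 indicator; otherwise all samples count as a
    single group.
    """
    ref = net.clients[0].design
    group_cols = list(ref.group_columns)
    if not group_cols and config.coefficient in ref.column_names:
        col_idx = ref.column_names.index(config.coefficient)
        if all(
            np.all(np.isin(c.design.values[:, col_idx], (0.0, 1.0)))
            for c in net.clients
        ):
            group_cols = [config.coefficient]
    n_total = net.sum_int_scalar("filter_n_samples", [c.m_i for c in net.clients])
    if not group_cols:
        logger.warning(
            "no 0/1 group column available; using the pooled sample count "
            "as the smallest group size"
        )
        return n_total
    sums = net.sum_int(
        "filter_group_sizes",
        [
            np.array(
                [int(c.design.column(g).sum()) for g in group_cols], dtype=np.int64
            )
            for c in net.clients
        ],
    )
    sizes = [int(s) for s in sums]
    if len(group_cols) == 1:
        sizes.append(n_total - sizes[0])
    if min(sizes) == 0:
        raise ValidationError(
            f"empty group among columns {group_cols}: smallest group size is 0"
        )
    return min(sizes)


def federated_filter_by_expr(
    net: "FederatedNetwork", config: AnalysisConfig
) -> FilterDecision:
    """Decide which genes survive both expression filters (federated)."""
    _ensure_lib_sizes(net)
    median_lib = federated_median_lib_size(net)
    cpm_cutoff = config.min_count / median_lib * MILLION
    min_n = _min_group_size(net, config)

    totals = net.sum_int(
        "filter_gene_totals",
        [c.counts.counts.sum(axis=1).astype(np.int64) for c in net.clients],
    )
    pass_counts = net.sum_int(
        "filter_cpm_pass_counts",
        [
            (
                c.counts.counts / c.lib_sizes[np.newaxis, :] * MILLION >= cpm_cutoff
            ).sum(axis=1).astype(np.int64)
            for c in net.clients
        ],
    )
    totals = np.array([int(t) for t in totals], dtype=np.int64)
    pass_counts = np.array([int(t) for t in pass_counts], dtype=np.int64)
    keep = (totals > config.min_total_count) & (pass_counts >= min_n)
    return FilterDecision(
        keep=keep,
        cpm_cutoff=float(cpm_cutoff),
        min_n_samples=int(min_n),
        median_lib_size=float(median_lib),
    )


def centralized_filter_mask(
    counts: np.ndarray, group_sizes: list[int], config: AnalysisConfig
) -> np.ndarray:
    """Direct (non-federated) evaluation of the same two filtering rules.

    Used as the plain-data reference the protocol must reproduce.
    """
    lib = counts.sum(axis=0)
    median_lib = float(np.median(lib))
    cutoff = config.min_count / median_lib * MILLION
    cpm = counts / lib[np.newaxis, :] * MILLION
    return (counts.sum(axis=1) > config.min_total_count) & (
        (cpm >= cutoff).sum(axis=1) >= min(group_sizes)
    )


def apply_filter(net: "FederatedNetwork", decision: FilterDecision) -> None:
    """Drop filtered genes on every client (library sizes stay pre-filter)."""
    _ensure_lib_sizes(net)
    if int(decision.keep.sum()) == 0:
        raise ValidationError("expression filter removed every gene")
    for c in net.clients:
        c.counts = c.counts.subset_genes(decision.keep)


def federated_uq_factors(net: "FederatedNetwork") -> NormFactors:
    """Upper-quartile normalization factors, rescaled to geometric mean 1.

    Per sample the UQ statistic is the 75th percentile (linear
    interpolation) of counts / library_size over the kept genes.  The
    rescaling constant exp(mean(log uq)) over all pooled samples is
    obtained from one masked sum of logs and one masked sample count;
    factors themselves are computed locally.
    """
    _ensure_lib_sizes(net)
    local_uq = []
    for c in net.clients:
        rel = c.counts.counts / c.lib_sizes[np.newaxis, :]
        uq = np.quantile(rel, 0.75, axis=0)  # type-7 linear interpolation
        zero = np.flatnonzero(uq == 0)
        if zero.size:
            raise ValidationError(
                f"upper-quartile statistic is zero for sample "
                f"{c.counts.sample_ids[zero[0]]!r} (sample too sparse)"
            )
        local_uq.append(uq)
    log_sum = float(
        net.sum_real("uq_log_sum", [[float(np.log(u).sum())] for u in local_uq])[0]
    )
    n = net.sum_int_scalar("uq_n_samples", [c.m_i for c in net.clients])
    mean_log = log_sum / n
    for c, uq in zip(net.clients, local_uq):
        c.norm_factors = uq / np.exp(mean_log)
    return NormFactors(
        sample_ids=[s for c in net.clients for s in c.counts.sample_ids],
        lib_size=np.concatenate([c.lib_sizes for c in net.clients]),
        uq_statistic=np.concatenate(local_uq),
        scaled_factor=np.concatenate([c.norm_factors for c in net.clients]),
    )


def effective_lib_size(lib_sizes: np.ndarray, norm_factors: np.ndarray) -> np.ndarray:
    return lib_sizes * norm_factors


def log_cpm(
    counts: np.ndarray, lib_sizes: np.ndarray, norm_factors: np.ndarray
) -> np.ndarray:
    """log2 counts-per-million with the standard 0.5 / 1.0 offsets.

    Purely local: log2((count + 0.5) / (lib_size * factor + 1) * 1e6).
    """
    eff = effective_lib_size(lib_sizes, norm_factors)
    return np.log2((counts + 0.5) / (eff + 1.0)[np.newaxis, :] * MILLION)
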