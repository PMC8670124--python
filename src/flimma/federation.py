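"""Three-party protocol orchestration: clients, aggregator, compensator.

The transport is an in-process synchronous bus with a narrow per-round
send/receive interface, so a real network transport could be substituted
without touching the algorithm.  Role separation is structural: the
aggregator object only accepts :class:`MaskedMessage` payloads and the
compensator only :class:`NoiseShare` payloads; handing either the wrong
type raises a protocol error.  All parties are assumed honest-but-curious
and non-colluding.

:func:`run_flimma` drives the full federated limma-voom workflow:
federated expression filtering, federated upper-quartile normalization,
log-CPM, a two-pass federated voom/lmFit, and aggregator-side
empirical-Bayes inference.  Run with a single client it *is* the
centralized pipeline (same code path), which defines the pooled oracle.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import fed_preprocess, fed_linear_voom, inference_stats
from .data_model import (
    AnalysisConfig,
    CountMatrix,
    DEResultTable,
    DesignMatrix,
    ValidationError,
    check_pairing,
)
from .secure_masking import (
    GAUSSIAN,
    MODULAR,
    MaskedMessage,
    NoiseShare,
    ProtocolError,
    denoise,
    aggregate_noise,
    mask_integer,
    mask_real,
)

logger = logging.getLogger("flimma")


@dataclass
class ClientState:
    """One participant's private data plus per-round caches."""

    client_id: str
    counts: CountMatrix
    design: DesignMatrix
    lib_sizes: np.ndarray | None = None       # per sample, over all genes
    norm_factors: np.ndarray | None = None    # per sample UQ scaled factors
    log_cpm: np.ndarray | None = None         # kept genes x samples
    weights: np.ndarray | None = None         # voom precision weights

    def __post_init__(self) -> None:
        check_pairing(self.counts, self.design)

    @property
    def m_i(self) -> int:
        return self.counts.n_samples


class Compensator:
    """Aggregates noise shares; never sees a masked (noisy) payload."""

    def __init__(self, modulus: int):
        self.modulus = modulus

    def aggregate(self, round_name: str, shares: Sequence[NoiseShare]) -> np.ndarray:
        for s in shares:
            if not isinstance(s, NoiseShare):
                raise ProtocolError(
                    f"compensator received a non-noise payload in round {round_name!r}"
                )
        return aggregate_noise(list(shares), self.modulus)


class Aggregator:
    """Sums masked payloads and denoises with the compensator's aggregate.

    Every payload it receives is logged to ``received_log`` so tests can
    assert that raw (unmasked, un-aggregated) data never reaches it.
    """

    def __init__(self, modulus: int):
        self.modulus = modulus
        self.received_log: list[tuple[str, str, tuple[int, ...]]] = []

    def combine(
        self,
        round_name: str,
        messages: Sequence[MaskedMessage],
        global_noise: np.ndarray,
    ) -> np.ndarray:
        for m in messages:
            if not isinstance(m, MaskedMessage):
                raise ProtocolError(
                    f"aggregator received a non-masked payload in round {round_name!r}"
                )
            self.received_log.append((round_name, m.scheme, m.shape))
        try:
            return denoise(list(messages), global_noise, self.modulus)
        except ProtocolError as exc:
            raise ProtocolError(f"round {round_name!r}: {exc}") from exc


class FederatedNetwork:
    """Synchronous round-based bus connecting K clients to the two servers."""

    def __init__(self, clients: list[ClientState], config: AnalysisConfig):
        self.clients = clients
        self.config = config
        self.aggregator = Aggregator(config.modulus_p)
        self.compensator = Compensator(config.modulus_p)
        self._round_counter: dict[str, int] = {}

    @property
    def n_clients(self) -> int:
        return len(self.clients)

    def _rng(self, client_index: int, round_name: str) -> np.random.Generator:
        # per-client per-round noise stream: reproducible, never reused
        tag = zlib.crc32(round_name.encode())
        return np.random.default_rng([self.config.seed, client_index, tag])

    def exchange(
        self,
        round_name: str,
        payloads: Sequence[np.ndarray],
        scheme: str,
    ) -> np.ndarray:
        """Run one protocol round and return the denoised global sum."""
        if len(payloads) != self.n_clients:
            raise ProtocolError(
                f"round {round_name!r}: {len(payloads)} payloads for "
                f"{self.n_clients} clients"
            )
        shapes = {np.asarray(p).shape for p in payloads}
        if len(shapes) != 1:
            raise ProtocolError(
                f"round {round_name!r}: mismatched payload shapes {sorted(shapes)}"
            )
        n = self._round_counter.get(round_name, 0)
        self._round_counter[round_name] = n + 1
        unique = round_name if n == 0 else f"{round_name}#{n}"
        messages, shares = [], []
        for i, payload in enumerate(payloads):
            rng = self._rng(i, unique)
            if scheme == MODULAR:
                msg, share = mask_integer(
                    payload, self.config.modulus_p, rng, masking=self.config.masking
                )
            elif scheme == GAUSSIAN:
                msg, share = mask_real(
                    payload, self.config.gauss_var, rng, masking=self.config.masking
                )
            else:
                raise ProtocolError(f"unknown scheme {scheme!r}")
            messages.append(msg)
            shares.append(share)
        global_noise = self.compensator.aggregate(unique, shares)
        result = self.aggregator.combine(unique, messages, global_noise)
        logger.debug("round %-28s scheme=%-8s shape=%s", unique, scheme, result.shape)
        return result

    def sum_int(self, round_name: str, payloads: Sequence) -> np.ndarray:
        """Masked integer aggregation; returns exact arbitrary-precision ints."""
        arrays = [np.atleast_1d(np.asarray(p)) for p in payloads]
        return self.exchange(round_name, arrays, MODULAR)

    def sum_real(self, round_name: str, payloads: Sequence[np.ndarray]) -> np.ndarray:
        arrays = [np.atleast_1d(np.asarray(p, dtype=float)) for p in payloads]
        return self.exchange(round_name, arrays, GAUSSIAN)

    def sum_int_scalar(self, round_name: str, values: Sequence[int]) -> int:
        return int(self.sum_int(round_name, [[int(v)] for v in values])[0])

    def broadcast(self, fn: Callable[[ClientState], None]) -> None:
        """Apply an aggregator->clients broadcast step to every client."""
        for c in self.clients:
            fn(c)


def exchange_round(
    net: FederatedNetwork,
    round_name: str,
    payloads: Sequence[np.ndarray],
    scheme: str = GAUSSIAN,
) -> np.ndarray:
    """Functional wrapper over :meth:`FederatedNetwork.exchange`."""
    return net.exchange(round_name, payloads, scheme)


def harmonize_genes(clients: list[ClientState]) -> list[str]:
    """Global gene universe: intersection of gene ids, in client-1 order.

    Genes missing from any client are dropped with a warning (the
    protocol needs every client to report on the same universe).
    """
    common = set(clients[0].counts.gene_ids)
    for c in clients[1:]:
        common &= set(c.counts.gene_ids)
    universe = [g for g in clients[0].counts.gene_ids if g in common]
    dropped = [g for g in clients[0].counts.gene_ids if g not in common]
    if dropped:
        logger.warning(
            "%d genes absent from some client were dropped (e.g. %s)",
            len(dropped),
            dropped[:5],
        )
    if not universe:
        raise ValidationError("no genes shared by all clients")
    for c in clients:
        if c.counts.gene_ids != universe:
            c.counts = c.counts.subset_genes(universe)
    return universe


def _validate_designs(clients: list[ClientState], config: AnalysisConfig) -> None:
    ref = clients[0].design
    for c in clients[1:]:
        if c.design.column_names != ref.column_names:
            raise ValidationError(
                f"design columns of client {c.client_id!r} differ from "
                f"client {clients[0].client_id!r}: "
                f"{c.design.column_names} vs {ref.column_names}"
            )
    if config.coefficient not in ref.column_names:
        raise ValidationError(
            f"tested coefficient {config.coefficient!r} not among design "
            f"columns {ref.column_names}"
        )


def _privacy_check_design(net: FederatedNetwork) -> None:
    """Refuse designs where a column singles out one sample globally.

    A column that is zero everywhere except a single sample would make
    that sample's expression recoverable from the global model, so the
    run is refused.  Only the per-column count of nonzero entries is
    exchanged (masked integers).
    """
    payloads = [
        (c.design.values != 0).sum(axis=0).astype(np.int64) for c in net.clients
    ]
    nonzero = net.sum_int("privacy_nonzero_count", payloads)
    for j, cnt in enumerate(int(v) for v in nonzero):
        if cnt == 1:
            name = net.clients[0].design.column_names[j]
            raise ValidationError(
                f"privacy refusal: design column {name!r} is nonzero for a "
                "single sample in the pooled design; its coefficient would "
                "expose that sample's expression profile"
            )


def add_batch_indicators(
    designs: list[DesignMatrix], prefix: str = "batch"
) -> list[DesignMatrix]:
    """Append m-1 binary dataset-indicator columns across m cohorts.

    Cohort 0 is the reference level (all its indicators are zero); cohort
    j >= 1 gets a 1 in column ``{prefix}{j}``.  Batch effects between
    datasets are then absorbed by the linear model.
    """
    m = len(designs)
    out = []
    for j, dm in enumerate(designs):
        extra = np.zeros((dm.n_samples, m - 1))
        if j >= 1:
            extra[:, j - 1] = 1.0
        names = dm.column_names + [f"{prefix}{i}" for i in range(1, m)]
        out.append(
            DesignMatrix(
                list(dm.sample_ids),
                names,
                np.hstack([dm.values, extra]),
                list(dm.group_columns),
            )
        )
    return out


def pool_clients(
    clients: Sequence[tuple[CountMatrix, DesignMatrix]],
) -> tuple[CountMatrix, DesignMatrix]:
    """Concatenate cohorts sample-wise into one centralized dataset."""
    cms = [c for c, _ in clients]
    dms = [d for _, d in clients]
    genes = cms[0].gene_ids
    for cm in cms[1:]:
        if cm.gene_ids != genes:
            raise ValidationError("cannot pool clients with different gene ids")
    counts = np.hstack([cm.counts for cm in cms])
    samples = [s for cm in cms for s in cm.sample_ids]
    values = np.vstack([dm.values for dm in dms])
    design = DesignMatrix(
        samples, list(dms[0].column_names), values, list(dms[0].group_columns)
    )
    return CountMatrix(list(genes), samples, counts), design


@dataclass
class RunResult:
    """Full output of one pipeline run (table plus fitted model internals)."""

    table: DEResultTable
    state: "fed_linear_voom.GlobalModelState"
    squeeze: "inference_stats.SqueezeResult"
    gene_ids: list[str]

    def effect_se(self, coefficient: str) -> np.ndarray:
        """Moderated standard error of the coefficient, per gene."""
        j = self.state.column_names.index(coefficient)
        return self.state.unscaled_se[:, j] * np.sqrt(self.squeeze.s_post_sq)


def run_flimma_detailed(
    clients: Sequence[tuple[CountMatrix, DesignMatrix]],
    config: AnalysisConfig,
) -> RunResult:
    """Run the full federated differential-expression workflow.

    Steps, in order: federated filterByExpr-style gene filtering,
    federated upper-quartile normalization, local log-CPM, a two-pass
    federated voom + weighted linear fit, and aggregator-side
    empirical-Bayes moderated t-statistics with BH adjustment.

    With ``len(clients) == 1`` this is exactly the centralized pipeline.
    """
    if not clients:
        raise ValidationError("at least one client is required")
    if len(clients) < 3:
        logger.warning(
            "running with %d client(s); the protocol's privacy rationale "
            "assumes more than two participants",
            len(clients),
        )
    states = [
        ClientState(f"client{i}", cm, dm) for i, (cm, dm) in enumerate(clients)
    ]
    net = FederatedNetwork(states, config)
    harmonize_genes(states)
    _validate_designs(states, config)
    _privacy_check_design(net)

    decision = fed_preprocess.federated_filter_by_expr(net, config)
    logger.info(
        "filtering: kept %d / %d genes (cpm cutoff %.4g, min samples %d)",
        int(decision.keep.sum()),
        decision.keep.size,
        decision.cpm_cutoff,
        decision.min_n_samples,
    )
    fed_preprocess.apply_filter(net, decision)
    fed_preprocess.federated_uq_factors(net)
    for c in states:
        c.log_cpm = fed_preprocess.log_cpm(
            c.counts.counts, c.lib_sizes, c.norm_factors
        )

    state = fed_linear_voom.run_two_pass(net)
    gene_ids = list(net.clients[0].counts.gene_ids)
    table, squeeze = inference_stats.infer_full(state, gene_ids, config)
    return RunResult(table=table, state=state, squeeze=squeeze, gene_ids=gene_ids)


def run_flimma(
    clients: Sequence[tuple[CountMatrix, DesignMatrix]],
    config: AnalysisConfig,
) -> DEResultTable:
    """As :func:`run_flimma_detailed`, returning only the result table."""
    return run_flimma_detailed(clients, config).table
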