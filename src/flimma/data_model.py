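"""Core domain types and TSV readers/writers shared by all modules.

Count matrices are genes x samples with non-negative integer entries;
design matrices are samples x covariates with an explicitly supplied
intercept column.  All files are plain TSV (UTF-8, '.' decimal); this is
the only dialect supported, which keeps round trips bit-exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import sympy

DEFAULT_MODULUS = 2**54 - 33  # largest prime below 2^54
DEFAULT_GAUSS_VAR = 1e12


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


@dataclass
class CountMatrix:
    """Raw read counts for one client: genes x samples, integers >= 0."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.all(np.isfinite(self.counts)):
                    raise ValidationError("counts contain non-finite entries")
                if np.any(self.counts != np.floor(self.counts)):
                    g, s = np.argwhere(self.counts != np.floor(self.counts))[0]
                    raise ValidationError(
                        f"non-integer count for gene {self.gene_ids[g]!r}, "
                        f"sample {self.sample_ids[s]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
            if np.any(self.counts < 0):
                g, s = np.argwhere(self.counts < 0)[0]
                raise ValidationError(
                    f"negative count for gene {self.gene_ids[g]!r}, "
                    f"sample {self.sample_ids[s]!r}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Column sums over ALL genes (computed before any filtering)."""
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
            genes = [self.gene_ids[i] for i in idx]
        else:
            pos = {g: i for i, g in enumerate(self.gene_ids)}
            idx = np.array([pos[g] for g in keep], dtype=int)
            genes = list(keep)
        return CountMatrix(genes, list(self.sample_ids), self.counts[idx])


@dataclass
class DesignMatrix:
    """Per-sample covariates: samples x k real matrix.

    ``group_columns`` marks 0/1 target-class indicator columns used to
    determine the smallest group size for expression filtering.  The
    intercept must be an explicit column; it is never added implicitly.
    """

    sample_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    group_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.column_names)):
            raise ValidationError(
                f"design shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.column_names)} columns"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.column_names, "design column")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("design matrix contains non-finite entries")
        for name in self.group_columns:
            if name not in self.column_names:
                raise ValidationError(f"group column {name!r} not in design")
            col = self.values[:, self.column_names.index(name)]
            if not np.all(np.isin(col, (0.0, 1.0))):
                raise ValidationError(
                    f"group column {name!r} must contain only 0/1 values"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.column_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


@dataclass
class AnalysisConfig:
    """Run-wide parameters of the federated analysis.

    ``modulus_p`` is the prime of the integer secret-sharing field and
    ``gauss_var`` the variance of the Gaussian masking noise; the defaults
    are the production values (largest prime below 2^54, sigma^2 = 1e12).
    """

    coefficient: str = "group"
    min_count: int = 10
    min_total_count: int = 15
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    modulus_p: int = DEFAULT_MODULUS
    gauss_var: float = DEFAULT_GAUSS_VAR
    seed: int = 0
    n_clients: int = 1
    masking: bool = True

    def __post_init__(self) -> None:
        if not sympy.isprime(self.modulus_p):
            raise ValidationError(f"modulus_p={self.modulus_p} is not prime")
        if not self.gauss_var > 0:
            raise ValidationError("gauss_var must be > 0")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class DEResultTable:
    """Per-gene differential expression results, sorted by p-value.

    Columns mirror limma's topTable: log2 fold change, average log2-CPM,
    moderated t, raw and BH-adjusted p-value.  Ties in p are broken by
    gene id so output order is deterministic.
    """

    gene_ids: list[str]
    log_fc: np.ndarray
    ave_expr: np.ndarray
    t_mod: np.ndarray
    p_value: np.ndarray
    adj_p_value: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("log_fc", "ave_expr", "t_mod", "p_value", "adj_p_value"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
            setattr(self, name, arr)
        if n:
            if np.any((self.p_value < 0) | (self.p_value > 1)):
                raise ValidationError("p_value outside [0, 1]")
            if np.any((self.adj_p_value < 0) | (self.adj_p_value > 1)):
                raise ValidationError("adj_p_value outside [0, 1]")
        self._sort()

    def _sort(self) -> None:
        order = sorted(
            range(len(self.gene_ids)),
            key=lambda i: (self.p_value[i], self.gene_ids[i]),
        )
        idx = np.array(order, dtype=int)
        self.gene_ids = [self.gene_ids[i] for i in order]
        for name in ("log_fc", "ave_expr", "t_mod", "p_value", "adj_p_value"):
            setattr(self, name, getattr(self, name)[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "logFC": self.log_fc,
                "AveExpr": self.ave_expr,
                "t": self.t_mod,
                "P.Value": self.p_value,
                "adj.P.Val": self.adj_p_value,
            }
        )

    def subset(self, gene_ids: Sequence[str]) -> "DEResultTable":
        """New table restricted to the given genes (re-sorted, re-validated)."""
        view = self.reindex(gene_ids)
        return DEResultTable(
            gene_ids=list(view.gene_ids),
            log_fc=view.log_fc,
            ave_expr=view.ave_expr,
            t_mod=view.t_mod,
            p_value=view.p_value,
            adj_p_value=view.adj_p_value,
        )

    def reindex(self, gene_ids: Sequence[str]) -> "DEResultTable":
        """Return arrays aligned to an arbitrary gene order (no re-sort)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in gene_ids], dtype=int)
        out = DEResultTable.__new__(DEResultTable)
        out.gene_ids = list(gene_ids)
        for name in ("log_fc", "ave_expr", "t_mod", "p_value", "adj_p_value"):
            setattr(out, name, getattr(self, name)[idx])
        return out


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV: header row of sample ids, first column gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric count entry in {path}: {exc}") from exc
    return CountMatrix(genes, samples, body)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_design(path: str | Path, group_columns: Sequence[str] = ()) -> DesignMatrix:
    """Read a design TSV: first column sample ids, remaining columns numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = [str(s) for s in df.index]
    cols = [str(c) for c in df.columns]
    for g in group_columns:
        if g not in cols:
            raise ValidationError(f"group column {g!r} missing from {path}")
    try:
        vals = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric design entry in {path}: {exc}") from exc
    return DesignMatrix(samples, cols, vals, list(group_columns))


def write_design(dm: DesignMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.column_names)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def check_pairing(counts: CountMatrix, design: DesignMatrix) -> None:
    """Counts and design must list identical sample ids in identical order."""
    if counts.sample_ids != design.sample_ids:
        raise ValidationError(
            "sample ids of counts and design differ in content or order: "
            f"{counts.sample_ids[:5]}... vs {design.sample_ids[:5]}..."
        )


def write_results(table: DEResultTable, path: str | Path) -> None:
    """Write a results TSV with full double precision (17 significant digits)."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> DEResultTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return DEResultTable(
        gene_ids=[str(g) for g in df["gene"]],
        log_fc=df["logFC"].to_numpy(float),
        ave_expr=df["AveExpr"].to_numpy(float),
        t_mod=df["t"].to_numpy(float),
        p_value=df["P.Value"].to_numpy(float),
        adj_p_value=df["adj.P.Val"].to_numpy(float),
    )


def geometric_mean(x: np.ndarray) -> float:
    return float(math.exp(np.mean(np.log(x))))
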