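"""Hybrid additive-masking primitives.

Two schemes, following the hybrid secret-sharing design used for
privacy-aware aggregation:

* ``modular`` — non-negative integer parameters are hidden by adding
  uniform noise from the prime field Z_p and reducing mod p.  Arithmetic
  is exact (arbitrary-precision Python integers), so the aggregate is
  recovered bit-exactly whenever the true sum stays below p.
* ``gaussian`` — real parameters are hidden by adding N(0, sigma^2)
  noise; the aggregate is recovered up to floating-point rounding.

The noisy share goes to the aggregator, the noise share to a separate
compensator; neither alone learns the local parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import DEFAULT_GAUSS_VAR, DEFAULT_MODULUS

MODULAR = "modular"
GAUSSIAN = "gaussian"


class MaskingError(ValueError):
    pass


class ProtocolError(RuntimeError):
    pass


@dataclass
class MaskedMessage:
    """Noisy parameter share M' = mask(M, N), destined for the aggregator."""

    scheme: str
    noisy: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.noisy.shape


@dataclass
class NoiseShare:
    """Noise share N of identical shape, destined for the compensator."""

    scheme: str
    noise: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.noise.shape


def _to_object_int(M: np.ndarray) -> np.ndarray:
    """Promote to arbitrary-precision ints so modular sums never overflow."""
    out = np.empty(M.shape, dtype=object)
    flat_in = M.ravel()
    flat_out = out.ravel()
    for i in range(flat_in.size):
        flat_out[i] = int(flat_in[i])
    return out


def _uniform_zp(shape: tuple[int, ...], p: int, rng: np.random.Generator) -> np.ndarray:
    # p < 2^63 always (default is ~2^54), so integers() covers the field
    draw = rng.integers(0, p, size=shape, dtype=np.int64)
    return _to_object_int(draw)


def mask_integer(
    M: np.ndarray,
    p: int = DEFAULT_MODULUS,
    rng: np.random.Generator | None = None,
    *,
    masking: bool = True,
) -> tuple[MaskedMessage, NoiseShare]:
    """Additively secret-share a non-negative integer matrix over Z_p.

    Returns (M + N mod p, N) with N uniform over Z_p.  All entries of M
    must lie in [0, p).  With ``masking=False`` the noise is identically
    zero (test hook / unmasked mode).
    """
    M = np.asarray(M)
    Mi = _to_object_int(M)
    if Mi.size and (np.min(M) < 0 or any(int(v) >= p for v in Mi.ravel())):
        raise MaskingError(f"integer parameter outside [0, {p})")
    if masking:
        if rng is None:
            rng = np.random.default_rng()
        N = _uniform_zp(Mi.shape, p, rng)
    else:
        N = _to_object_int(np.zeros(Mi.shape, dtype=np.int64))
    noisy = (Mi + N) % p
    return MaskedMessage(MODULAR, noisy), NoiseShare(MODULAR, N)


def mask_real(
    M: np.ndarray,
    sigma2: float = DEFAULT_GAUSS_VAR,
    rng: np.random.Generator | None = None,
    *,
    masking: bool = True,
) -> tuple[MaskedMessage, NoiseShare]:
    """Mask a real matrix with zero-mean Gaussian noise of variance sigma2."""
    if not sigma2 > 0:
        raise MaskingError("sigma2 must be > 0")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise MaskingError("real parameter contains non-finite entries")
    if masking:
        if rng is None:
            rng = np.random.default_rng()
        N = rng.normal(0.0, np.sqrt(sigma2), size=M.shape)
    else:
        N = np.zeros_like(M)
    return MaskedMessage(GAUSSIAN, M + N), NoiseShare(GAUSSIAN, N)


def aggregate_noise(noises: list[NoiseShare], p: int = DEFAULT_MODULUS) -> np.ndarray:
    """Compensator side: sum the noise shares (modular or ordinary)."""
    _check_consistent([n.scheme for n in noises], [n.shape for n in noises])
    scheme = noises[0].scheme
    if scheme == MODULAR:
        total = noises[0].noise
        for n in noises[1:]:
            total = (total + n.noise) % p
        return total
    return np.sum([n.noise for n in noises], axis=0)


def aggregate_denoise(
    messages: list[MaskedMessage],
    noises: list[NoiseShare],
    p: int = DEFAULT_MODULUS,
) -> np.ndarray:
    """Aggregator + compensator composition: recover sum_i M_i.

    Modular scheme: exact, provided the caller guarantees sum_i M_i < p.
    Gaussian scheme: exact up to floating-point rounding.  The noise
    aggregation is logically the compensator's job; callers that need the
    role separation enforced structurally use the federation module.
    """
    _check_consistent(
        [m.scheme for m in messages] + [n.scheme for n in noises],
        [m.shape for m in messages] + [n.shape for n in noises],
    )
    global_noise = aggregate_noise(noises, p)
    return denoise(messages, global_noise, p)


def denoise(
    messages: list[MaskedMessage],
    global_noise: np.ndarray,
    p: int = DEFAULT_MODULUS,
) -> np.ndarray:
    """Aggregator side: sum noisy shares and remove the aggregate noise."""
    _check_consistent([m.scheme for m in messages], [m.shape for m in messages])
    scheme = messages[0].scheme
    if scheme == MODULAR:
        total = messages[0].noisy
        for m in messages[1:]:
            total = (total + m.noisy) % p
        return (total - global_noise) % p
    total = np.sum([m.noisy for m in messages], axis=0)
    return total - global_noise


def _check_consistent(schemes: list[str], shapes: list[tuple[int, ...]]) -> None:
    if not schemes:
        raise ProtocolError("empty message list")
    if len(set(schemes)) != 1:
        raise ProtocolError(f"mixed masking schemes: {sorted(set(schemes))}")
    if len(set(shapes)) != 1:
        raise ProtocolError(f"mismatched payload shapes: {sorted(set(shapes))}")


def mi_bound(var_local: float, sigma2: float, scheme: str = GAUSSIAN) -> float:
    """Upper bound (bits) on mutual information between M and its noisy share.

    Gaussian scheme: (1/2) log2(1 + var_local / sigma2).  Modular scheme:
    exactly 0 — a uniformly masked field element is independent of M.
    """
    if var_local < 0:
        raise MaskingError("variance must be non-negative")
    if not sigma2 > 0:
        raise MaskingError("sigma2 must be > 0")
    if scheme == MODULAR:
        return 0.0
    return 0.5 * float(np.log2(1.0 + var_local / sigma2))


def object_to_int64(M: np.ndarray) -> np.ndarray:
    """Demote an exact object-int matrix back to int64 (values must fit)."""
    return np.asarray(M, dtype=object).astype(np.int64)
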