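"""RBF kernel, bandwidth heuristic and the biased MMD estimator.

The maximum mean discrepancy (MMD) between two read samples
``X = (x_1..x_m)`` and ``Y = (y_1..y_n)`` — read midpoints in bp within a
peak — is estimated by the biased V-statistic

    MMD^2 = 1/m^2 sum_ij k(x_i, x_j)
          - 2/(mn) sum_ij k(x_i, y_j)
          + 1/n^2 sum_ij k(y_i, y_j),

with ``k(x, x') = exp(-(x - x')^2 / (2 sigma^2))`` and the bandwidth set
by the median heuristic ``sigma^2 = 1/2 * med^2`` where ``med`` is the
median pairwise absolute difference of the pooled positions.  The
diagonal (i = j) terms are included; the estimate is always
non-negative and is zero iff the two position multisets coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from peakshape.errors import DegenerateSampleError, InvalidParameterError

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

__all__ = [
    "ReadSample",
    "KernelParams",
    "rbf_kernel",
    "median_heuristic_sigma",
    "mmd",
    "pairwise_mmd_matrix",
]

#: Default budget of position pairs for the median heuristic; beyond it a
#: seeded uniform subsample of pairs is used (the exact median is O(N^2)).
DEFAULT_PAIR_CAP = 100_000


@dataclass(frozen=True)
class ReadSample:
    """Read midpoints of one sample within one peak.

    Positions are bp offsets from the region start, in [0, region_length).
    The sample may be empty; operations that need observations raise
    :class:`DegenerateSampleError` on empty input.
    """

    positions: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.positions, dtype=np.float64).ravel()
        if arr.size and arr.min() < 0:
            raise InvalidParameterError("read positions must be non-negative offsets")
        object.__setattr__(self, "positions", arr)

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class KernelParams:
    """RBF bandwidth and how it was obtained."""

    sigma: float
    heuristic_used: bool = True
    pair_subsample_cap: int | None = DEFAULT_PAIR_CAP
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")


def _positions(sample: ReadSample | np.ndarray) -> np.ndarray:
    if isinstance(sample, ReadSample):
        return sample.positions
    return np.asarray(sample, dtype=np.float64).ravel()


def rbf_kernel(x, x_prime, sigma: float):
    """Gaussian kernel exp(-(x - x')^2 / (2 sigma^2)); vectorises over inputs."""
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    d = x - x_prime
    out = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def median_heuristic_sigma(
    pooled_positions,
    cap: int | None = DEFAULT_PAIR_CAP,
    seed: int = 0,
) -> float:
    """Bandwidth from the median pairwise distance of the pooled positions.

    Returns ``sigma = sqrt(0.5 * med^2) = med / sqrt(2)`` where ``med`` is
    the median of ``|x_i - x_j|`` over all i < j pairs.  If the number of
    pairs exceeds ``cap``, a seeded uniform subsample of ``cap`` pairs is
    used instead of the full enumeration (``cap=None`` disables).

    Raises
    ------
    DegenerateSampleError
        If fewer than two positions are given or the median distance is
        zero (all positions identical); the caller should skip the peak.
    """
    x = np.asarray(pooled_positions, dtype=np.float64).ravel()
    n = x.size
    if n < 2:
        raise DegenerateSampleError("median heuristic needs at least 2 positions")
    n_pairs = n * (n - 1) // 2
    if cap is not None and cap < 1:
        raise InvalidParameterError("pair cap must be >= 1 or None")
    if cap is None or n_pairs <= cap:
        med = float(np.median(pdist(x[:, None], metric="cityblock")))
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=cap)
        j = rng.integers(0, n, size=cap)
        keep = i != j
        med = float(np.median(np.abs(x[i[keep]] - x[j[keep]])))
    if med == 0.0:
        raise DegenerateSampleError("median pairwise distance is zero")
    return med / math.sqrt(2.0)


def _kernel_sum(a: np.ndarray, b: np.ndarray, sigma: float) -> float:
    d = a[:, None] - b[None, :]
    return float(np.exp(-(d * d) / (2.0 * sigma * sigma)).sum())


def _mmd_from_sums(s_aa: float, s_ab: float, s_bb: float, m: int, n: int) -> float:
    mmd2 = (s_aa / (m * m) + s_bb / (n * n)) - 2.0 * s_ab / (m * n)
    return math.sqrt(max(mmd2, 0.0))


def mmd(sample_a, sample_b, sigma: float) -> float:
    """Biased MMD estimate between two read samples at bandwidth ``sigma``.

    Includes the diagonal self-pair terms; tiny negative MMD^2 from
    floating-point cancellation is clamped to zero before the square root.
    The two inputs are put in a canonical order internally so that
    ``mmd(a, b)`` and ``mmd(b, a)`` are bit-identical.
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    a = _positions(sample_a)
    b = _positions(sample_b)
    if a.size == 0 or b.size == 0:
        raise DegenerateSampleError("MMD requires both samples non-empty")
    if (b.size, b.tobytes()) < (a.size, a.tobytes()):
        a, b = b, a
    s_aa = _kernel_sum(a, a, sigma)
    s_bb = _kernel_sum(b, b, sigma)
    s_ab = _kernel_sum(a, b, sigma)
    return _mmd_from_sums(s_aa, s_ab, s_bb, a.size, b.size)


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _block_sums_numba(z, offsets, inv_two_sigma2):  # pragma: no cover - jitted
        k = offsets.size - 1
        S = np.zeros((k, k))
        for a in range(k):
            lo, hi = offsets[a], offsets[a + 1]
            # self block: upper triangle doubled, unit diagonal
            tot = 0.0
            for i in range(lo, hi):
                zi = z[i]
                for j in range(i + 1, hi):
                    d = zi - z[j]
                    tot += np.exp(-d * d * inv_two_sigma2)
            S[a, a] = 2.0 * tot + (hi - lo)
            for b in range(a + 1, k):
                tot = 0.0
                for i in range(lo, hi):
                    zi = z[i]
                    for j in range(offsets[b], offsets[b + 1]):
                        d = zi - z[j]
                        tot += np.exp(-d * d * inv_two_sigma2)
                S[a, b] = tot
                S[b, a] = tot
        return S


def _block_sums_numpy(z, offsets, inv_two_sigma2):
    d = z[:, None] - z[None, :]
    K = np.exp(-(d * d) * inv_two_sigma2)
    rows = np.add.reduceat(K, offsets[:-1], axis=0)
    return np.add.reduceat(rows, offsets[:-1], axis=1)


def pairwise_mmd_matrix(samples, sigma: float, engine: str = "auto") -> np.ndarray:
    """All pairwise MMDs between a list of read samples at one peak.

    Computes the kernel Gram block sums over the concatenated positions
    once and assembles every pairwise biased MMD from them, so all pairs
    share identical per-sample self terms.  ``engine`` selects the block
    summation path: "numba" (default when available), "numpy".

    Returns an (s, s) symmetric matrix with zeros on the diagonal.
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    arrays = [_positions(s) for s in samples]
    sizes = np.array([a.size for a in arrays], dtype=np.int64)
    if (sizes == 0).any():
        raise DegenerateSampleError("all samples must be non-empty")
    z = np.concatenate(arrays)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    inv = 1.0 / (2.0 * sigma * sigma)
    if engine == "auto":
        engine = "numba" if _HAVE_NUMBA else "numpy"
    if engine == "numba":
        S = _block_sums_numba(z, offsets, inv)
    elif engine == "numpy":
        S = _block_sums_numpy(z, offsets, inv)
    else:
        raise InvalidParameterError(f"unknown engine {engine!r}")
    k = sizes.size
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = _mmd_from_sums(
                S[a, a], S[a, b], S[b, b], sizes[a], sizes[b]
            )
    return out
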