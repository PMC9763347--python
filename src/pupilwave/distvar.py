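"""Distance variance of a coefficient vector.

The (squared) sample distance variance of x = (x_1, ..., x_n) is

    nu2(x) = (1/n^2) * sum_ij A_ij^2,

where a_ij = |x_i - x_j| and A is the double-centered distance matrix
(row means, column means subtracted, grand mean added back).  It is
translation invariant and a^2-scale-equivariant, so swapping the
classical level variance for the distance variance shifts a log2-energy
wavelet spectrum only by an intercept: the spectral slope, and hence
the Hurst exponent H = -(slope+1)/2, keeps its meaning.  Unlike the
classical variance it is resistant to a minority of outlying
coefficients.

Two implementations are provided: a naive O(n^2) double-centering
reference, and an O(n log n) sort/partial-sum evaluation in the spirit
of Chaudhuri & Hu's fast univariate distance-covariance algorithm.
The biased 1/n^2 normalization is used throughout (matching the
double-centering with 1/n row/column means), not the unbiased
U-statistic variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyEstimator:
    """How level energies are measured: classical variance or distance
    variance, the latter via the naive or the fast algorithm."""

    kind: str = "distance_variance"  # "variance" | "distance_variance"
    algorithm: str = "fast"  # "naive" | "fast" (distance_variance only)

    def __post_init__(self) -> None:
        if self.kind not in ("variance", "distance_variance"):
            raise DomainError(f"unknown estimator kind {self.kind!r}")
        if self.algorithm not in ("naive", "fast"):
            raise DomainError(f"unknown algorithm {self.algorithm!r}")


VARIANCE = EnergyEstimator(kind="variance")
DISTANCE_VARIANCE = EnergyEstimator(kind="distance_variance", algorithm="fast")


def _check_input(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DomainError("input must be one-dimensional")
    if x.size < 2:
        raise DomainError(f"need at least 2 elements, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DomainError("input contains non-finite values")
    return x


def distance_variance_naive(x: np.ndarray) -> float:
    """Squared sample distance variance via explicit double centering, O(n^2)."""
    x = _check_input(x)
    n = x.size
    a = np.abs(x[:, None] - x[None, :])
    A = a - a.mean(axis=0)[None, :] - a.mean(axis=1)[:, None] + a.mean()
    return float((A**2).sum() / n**2)


def distance_variance_fast(x: np.ndarray) -> float:
    """Squared sample distance variance in O(n log n).

    After sorting, all three pairwise-distance moments reduce to
    prefix sums:

        S1 = (1/n^2) sum_ij a_ij^2
        S2 = ((1/n^2) sum_ij a_ij)^2
        S3 = (1/n^3) sum_i (sum_j a_ij)^2

    and nu2 = S1 + S2 - 2*S3.  Agrees with the naive version to ~1e-12
    relative; ties are handled automatically since the statistic
    depends only on values.
    """
    x = _check_input(x)
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    total = xs.sum()
    prefix = np.cumsum(xs)
    # row sums of a_ij for sorted x
    row = (2 * i - n) * xs + total - 2 * prefix
    s1 = (2 * n * (xs**2).sum() - 2 * total**2) / n**2
    s2 = (row.sum() / n**2) ** 2
    s3 = (row**2).sum() / n**3
    return max(float(s1 + s2 - 2 * s3), 0.0)


def level_energy(coeffs: np.ndarray, estimator: EnergyEstimator = DISTANCE_VARIANCE) -> float:
    """Energy of one level's coefficients under the chosen estimator.

    ``variance``: mean squared deviation from the level mean
    (denominator n).  ``distance_variance``: nu2 via the chosen
    algorithm.  Requires at least 2 coefficients.
    """
    coeffs = _check_input(coeffs)
    if estimator.kind == "variance":
        return float(np.var(coeffs))
    if estimator.algorithm == "naive":
        return distance_variance_naive(coeffs)
    return distance_variance_fast(coeffs)
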