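"""Synthetic inputs: Brownian motion, fractional Brownian motion,
contaminated wavelet coefficients, and pupillometry-like cohorts.

The cohort generator emulates the *statistical* structure the analysis
consumes — per-participant multi-session recordings whose
self-similarity (Hurst exponent) differs between cases and controls,
with bursty missing segments mimicking blinks — not a physiological
pupil model.  Fractional Brownian motion is the canonical
H-parameterized self-similar process, simulated exactly in law by
circulant embedding of the fractional Gaussian noise covariance (with
a Cholesky fallback), so recovery of a known ground-truth H can be
tested for any H in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .dwt import WaveletDecomposition
from .signal_io import Signal, TimeSeriesRecording


class DomainError(ValueError):
    pass


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_brownian(n: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Standard Brownian motion path: cumulative sum of n iid N(0,1)
    increments.  Its theoretical Hurst exponent is 0.5."""
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    rng = _rng(seed)
    return np.cumsum(rng.standard_normal(n))


def fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    """Autocovariance gamma(k), k = 0..n-1, of unit-scale fractional
    Gaussian noise: gamma(k) = ((k+1)^2H - 2 k^2H + |k-1|^2H) / 2."""
    k = np.arange(n, dtype=float)
    return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))


def fbm_covariance(n: int, hurst: float) -> np.ndarray:
    """Analytic fBm covariance Cov(X_s, X_t) = (s^2H + t^2H - |s-t|^2H)/2
    on the integer grid s, t = 1..n."""
    t = np.arange(1, n + 1, dtype=float)
    s2h = t ** (2 * hurst)
    return 0.5 * (s2h[:, None] + s2h[None, :] - np.abs(t[:, None] - t[None, :]) ** (2 * hurst))


def simulate_fbm(
    n: int,
    hurst: float,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
) -> np.ndarray:
    """Exact fractional Brownian motion path of length n.

    ``method``: "circulant" (Davies-Harte style embedding, O(n log n)),
    "cholesky" (exact factorization of the fGn covariance, O(n^3), for
    tiny n), or "auto" (circulant with Cholesky fallback should the
    embedding eigenvalues go negative; for fGn they are provably
    non-negative, so the fallback is defensive).
    """
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    if not 0.0 < hurst < 1.0:
        raise DomainError(f"hurst must be in (0, 1), got {hurst}")
    if method not in ("auto", "circulant", "cholesky"):
        raise DomainError(f"unknown method {method!r}")
    rng = _rng(seed)
    if method == "cholesky":
        return _fbm_cholesky(n, hurst, rng)
    g = fgn_autocovariance(n + 1, hurst)
    circ = np.concatenate([g, g[-2:0:-1]])  # length 2(n+1)... circulant row
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-8 * lam.max():
        if method == "circulant":
            raise DomainError("circulant embedding failed (negative eigenvalues)")
        return _fbm_cholesky(n, hurst, rng)
    lam = np.clip(lam, 0.0, None)
    m = circ.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    # real part of FFT(z * sqrt(lam/m)) is stationary Gaussian with
    # autocovariance exactly circ
    increments = np.fft.fft(z * np.sqrt(lam / m)).real[:n]
    return np.cumsum(increments)


def _fbm_cholesky(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    cov = toeplitz(fgn_autocovariance(n, hurst))
    L = cholesky(cov + 1e-12 * np.eye(n), lower=True)
    return np.cumsum(L @ rng.standard_normal(n))


def contaminate_coefficients(
    decomp: WaveletDecomposition,
    n_per_level: int,
    noise_sd: float | dict[int, float],
    seed: int | np.random.Generator | None = None,
) -> WaveletDecomposition:
    """Add Gaussian noise to randomly chosen detail coefficients.

    At each detail level, min(n_per_level, level size) distinct
    positions chosen uniformly without replacement receive additive
    N(0, sd^2) noise; smooth coefficients and all unselected positions
    are bit-identical to the input.  ``noise_sd`` may be one scalar or
    a per-level mapping {level: sd}.
    """
    if n_per_level < 0:
        raise DomainError(f"n_per_level must be >= 0, got {n_per_level}")
    sds = (
        noise_sd
        if isinstance(noise_sd, dict)
        else {j: float(noise_sd) for j in decomp.levels}
    )
    for j, sd in sds.items():
        if sd < 0:
            raise DomainError(f"noise_sd must be >= 0 (level {j}: {sd})")
    rng = _rng(seed)
    out = decomp.copy()
    for j in out.levels:
        d = out.details[j]
        m = min(n_per_level, d.size)
        if m == 0 or sds.get(j, 0.0) == 0.0:
            continue
        idx = rng.choice(d.size, size=m, replace=False)
        d[idx] += rng.standard_normal(m) * sds[j]
    return out


@dataclass
class CohortSpec:
    """Study conditions for a synthetic two-group cohort.

    Defaults mirror the pupillometry study layout this package targets:
    28 cases vs 22 controls, 8 sessions each of 165,000 samples at
    1 kHz, with the case group less regular (smaller H) than controls,
    and ~30% of samples masked in contiguous blink-like bursts.
    """

    n_cases: int = 28
    n_controls: int = 22
    H_case: float = 0.89
    H_control: float = 0.95
    sessions_per_subject: int = 8
    session_length: int = 165000
    missing_fraction: float = 0.3
    blink_burst_length: int = 200
    seed: int = 0
    sampling_rate: float = 1000.0
    # affine rescaling of the fBm path into a plausible pupil range
    pupil_mean: float = 3.5
    pupil_sd: float = 0.3

    def __post_init__(self) -> None:
        for name in ("H_case", "H_control"):
            h = getattr(self, name)
            if not 0.0 < h < 1.0:
                raise DomainError(f"{name} must be in (0, 1), got {h}")
        if not 0.0 <= self.missing_fraction < 0.8:
            raise DomainError(
                "missing_fraction must be in [0, 0.8) so signals survive "
                f"the cleaning rule, got {self.missing_fraction}"
            )
        if self.n_cases < 0 or self.n_controls < 0:
            raise DomainError("group sizes must be non-negative")


def _blink_mask(n: int, fraction: float, burst: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous bursts at random starts until >= fraction of samples
    are masked (blinks are bursty, not iid missingness)."""
    mask = np.zeros(n, dtype=bool)
    if fraction <= 0 or burst <= 0:
        return mask
    target = fraction * n
    while mask.sum() < target:
        start = int(rng.integers(0, max(n - burst, 1)))
        mask[start : start + burst] = True
    return mask


def simulate_cohort(spec: CohortSpec) -> list[TimeSeriesRecording]:
    """Generate a labeled cohort of multi-session recordings.

    Each session is an independent fBm path at the subject's group H,
    affinely rescaled to a pupil-like range (the spectral slope is
    invariant to affine rescaling) and masked with blink bursts.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    recordings = []
    plan = [("case", spec.H_case, spec.n_cases), ("control", spec.H_control, spec.n_controls)]
    for group, hurst, count in plan:
        for i in range(count):
            sessions = []
            for s in range(spec.sessions_per_subject):
                path = simulate_fbm(spec.session_length, hurst, rng)
                sd = path.std()
                values = spec.pupil_mean + spec.pupil_sd * (path - path.mean()) / (sd if sd > 0 else 1.0)
                mask = _blink_mask(
                    spec.session_length, spec.missing_fraction, spec.blink_burst_length, rng
                )
                sessions.append(Signal(values=values, missing_mask=mask, session_index=s))
            recordings.append(
                TimeSeriesRecording(
                    participant_id=f"{group}_{i:03d}",
                    group=group,
                    sessions=sessions,
                    sampling_rate=spec.sampling_rate,
                )
            )
    return recordings
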