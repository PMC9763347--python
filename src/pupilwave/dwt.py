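"""Orthogonal discrete wavelet transform (Mallat pyramid).

The transform is the orthogonal matrix product d = W·Y computed by the
fast pyramid algorithm, with *periodic* boundary handling so that it is
exactly orthogonal (Parseval holds to machine precision) and a signal
of length 2^J yields detail levels j = J0 … J-1 with exactly 2^j
coefficients each, plus 2^J0 smooth (approximation) coefficients at the
coarsest level J0.

Level convention: j = J-1 is the *finest* detail level.  For
self-similar signals the level energies decrease in j, so the wavelet
spectrum has a negative slope and H = -(slope+1)/2.  "n_levels = L"
means L detail levels, i.e. J0 = J - L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

SUPPORTED_FAMILIES = ("haar", "db", "sym")


class DomainError(ValueError):
    """Input violates an operation's preconditions."""


class DecompositionError(ValueError):
    """A WaveletDecomposition has inconsistent structure."""


def _check_wavelet(wavelet_name: str) -> pywt.Wavelet:
    if not wavelet_name.startswith(SUPPORTED_FAMILIES):
        raise DomainError(
            f"unsupported wavelet {wavelet_name!r}: expected an orthogonal "
            f"family among {SUPPORTED_FAMILIES} (e.g. 'haar', 'db6', 'sym8')"
        )
    try:
        w = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise DomainError(str(exc)) from exc
    if not w.orthogonal:
        raise DomainError(f"wavelet {wavelet_name!r} is not orthogonal")
    return w


@dataclass
class WaveletDecomposition:
    """Multiresolution coefficient hierarchy of a length-2^J signal.

    ``smooth`` holds the coarsest approximation coefficients (length
    2^J0); ``details[j]`` holds the detail coefficients of level j
    (length 2^j) for J0 <= j <= J-1.
    """

    smooth: np.ndarray
    details: dict[int, np.ndarray]
    wavelet_name: str
    n_original: int

    def __post_init__(self) -> None:
        self.smooth = np.asarray(self.smooth, dtype=float)
        self.details = {int(j): np.asarray(d, dtype=float) for j, d in self.details.items()}
        J = int(np.log2(self.n_original))
        if 2**J != self.n_original:
            raise DecompositionError(f"n_original={self.n_original} is not a power of two")
        levels = sorted(self.details)
        if levels != list(range(levels[0], J)):
            raise DecompositionError(f"detail levels {levels} are not contiguous up to J-1={J-1}")
        for j in levels:
            if self.details[j].size != 2**j:
                raise DecompositionError(
                    f"level {j} has {self.details[j].size} coefficients, expected {2**j}"
                )
        if self.smooth.size != 2 ** levels[0]:
            raise DecompositionError(
                f"smooth has {self.smooth.size} coefficients, expected {2**levels[0]}"
            )

    @property
    def coarsest_level(self) -> int:
        return min(self.details)

    @property
    def levels(self) -> list[int]:
        return sorted(self.details)

    def total_energy(self) -> float:
        return float((self.smooth**2).sum() + sum((d**2).sum() for d in self.details.values()))

    def copy(self) -> "WaveletDecomposition":
        return WaveletDecomposition(
            smooth=self.smooth.copy(),
            details={j: d.copy() for j, d in self.details.items()},
            wavelet_name=self.wavelet_name,
            n_original=self.n_original,
        )


def dwt_forward(
    signal: np.ndarray, wavelet_name: str = "db6", coarsest_level: int = 1
) -> WaveletDecomposition:
    """Decompose a length-2^J signal down to coarsest level J0.

    Produces J - J0 detail levels (J0 = 0 gives the full decomposition
    with a single smooth coefficient).  Raises :class:`DomainError` if
    the length is not a power of two (truncate to the largest power of
    two or pad before calling) or if J0 is out of [0, J-1].
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise DomainError("signal must be one-dimensional")
    n = x.size
    J = int(np.log2(n)) if n > 0 else 0
    if n < 2 or 2**J != n:
        raise DomainError(
            f"signal length {n} is not a power of two; truncate to {2**J if n >= 2 else 2} "
            "(largest power of two <= length) or pad to the next power of two"
        )
    if not 0 <= coarsest_level <= J - 1:
        raise DomainError(f"coarsest_level must be in [0, {J - 1}], got {coarsest_level}")
    wavelet = _check_wavelet(wavelet_name)
    n_levels = J - coarsest_level
    with warnings.catch_warnings():
        # deep decompositions (level data shorter than the filter) are
        # well-defined under periodization; silence pywt's level warning
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=n_levels)
    details = {coarsest_level + k: coeffs[1 + k] for k in range(n_levels)}
    return WaveletDecomposition(
        smooth=coeffs[0], details=details, wavelet_name=wavelet_name, n_original=n
    )


def dwt_inverse(decomp: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the signal; inverse of :func:`dwt_forward` to ~1e-10."""
    wavelet = _check_wavelet(decomp.wavelet_name)
    coeffs = [decomp.smooth] + [decomp.details[j] for j in decomp.levels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return pywt.waverec(coeffs, wavelet, mode="periodization")
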