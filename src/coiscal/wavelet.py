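"""Analytic Morlet CWT with explicit convolution-mode semantics.

The scalogram of a finite signal is built row by row from linear
convolutions of the signal with scaled wavelets.  The three convolution
modes (``full``, ``same``, ``valid``) differ only in which slice of the
full convolution they return, and this slicing is exactly what defines
the cone of influence (COI): the coefficients of the ``same`` output that
coincide with ``valid`` outputs were computed from complete
wavelet-signal overlap and are accurate; the rest are edge artifacts.

Everything here is 0-based and COI intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Signal",
    "WaveletParams",
    "FrequencyGrid",
    "CoefficientMatrix",
    "Scalogram",
    "COIBoundary",
    "morlet",
    "convolve",
    "wavelet_footprint",
    "cwt_scalogram",
    "compute_coi",
    "quality_rho",
    "quality_beta",
]

ConvMode = Literal["full", "same", "valid"]
TruncationRule = Literal["2pct", "1/e", "half", "energy95"]

# envelope exp(-t^2 / 2 sigma_t^2) cutoff multipliers: |t| <= c * sigma_t
_TRUNC_MULTIPLIER = {
    "2pct": np.sqrt(2.0 * np.log(50.0)),  # envelope down to 2% of peak
    "1/e": np.sqrt(2.0),                  # envelope down to 1/e
}


@dataclass(frozen=True)
class Signal:
    """A finite real-valued signal with its sampling rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class WaveletParams:
    """Analytic Morlet configuration.

    ``cycles`` is the number of oscillation cycles inside the Gaussian
    envelope (the product of center frequency and envelope width up to a
    2*pi factor): at band frequency f the envelope width is
    ``sigma_t = cycles / (2 pi f)``.  ``truncation`` picks the rule that
    converts the infinite envelope into a finite discrete footprint.
    """

    cycles: float = 6.0
    truncation: TruncationRule = "2pct"

    def __post_init__(self) -> None:
        if not self.cycles > 0:
            raise ValueError("cycles must be positive")
        if self.truncation not in ("2pct", "1/e", "half", "energy95"):
            raise ValueError(f"unknown truncation rule: {self.truncation!r}")

    def sigma_t(self, f0: float) -> float:
        """Envelope standard deviation (seconds) at center frequency f0."""
        if not f0 > 0:
            raise ValueError("center frequency must be positive")
        return self.cycles / (2.0 * np.pi * f0)

    def half_extent(self, f0: float) -> float:
        """Half-length (seconds) of the truncated wavelet support at f0."""
        sigma = self.sigma_t(f0)
        if self.truncation in _TRUNC_MULTIPLIER:
            return _TRUNC_MULTIPLIER[self.truncation] * sigma
        if self.truncation == "half":
            return 0.5 * _TRUNC_MULTIPLIER["2pct"] * sigma
        # energy95: |t| <= c sigma where the Gaussian power encloses 95%
        # of total energy; |Psi|^2 has std sigma/sqrt(2).
        from scipy.stats import norm

        return float(norm.ppf(0.975)) * sigma / np.sqrt(2.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """Band center frequencies for the discrete scalogram rows."""

    frequencies: np.ndarray
    spacing: Literal["logarithmic", "linear"] = "logarithmic"
    voices_per_octave: int | None = None

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.ndim != 1 or freqs.size < 1:
            raise ValueError("grid needs at least one frequency")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be positive")
        diffs = np.diff(freqs)
        if freqs.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("frequencies must be strictly monotone")

    @property
    def J(self) -> int:
        return int(self.frequencies.size)

    @classmethod
    def logarithmic(
        cls, f_min: float, f_max: float, voices_per_octave: int = 12
    ) -> "FrequencyGrid":
        """Log-spaced grid from f_min up to at most f_max, ascending."""
        if not 0 < f_min < f_max:
            raise ValueError("need 0 < f_min < f_max")
        n_octaves = np.log2(f_max / f_min)
        n_bands = int(np.floor(n_octaves * voices_per_octave)) + 1
        freqs = f_min * 2.0 ** (np.arange(n_bands) / voices_per_octave)
        return cls(freqs, "logarithmic", voices_per_octave)

    @classmethod
    def linear(cls, f_min: float, f_max: float, n_bands: int) -> "FrequencyGrid":
        return cls(np.linspace(f_min, f_max, n_bands), "linear", None)


@dataclass(frozen=True)
class CoefficientMatrix:
    """Complex CWT coefficients, one row per grid band."""

    W: np.ndarray
    grid: FrequencyGrid
    mode: ConvMode

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=complex)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != self.grid.J:
            raise ValueError("coefficient matrix must be J x N")
        if not np.all(np.isfinite(W)):
            raise ValueError("coefficient matrix contains non-finite entries")


@dataclass(frozen=True)
class Scalogram:
    """Nonnegative |W| or |W|^2 matrix with band metadata."""

    G: np.ndarray
    kind: Literal["power", "amplitude"]
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "G", G)
        if G.ndim != 2 or G.shape[0] != self.grid.J:
            raise ValueError("scalogram must be J x N")
        if np.any(G < 0):
            raise ValueError("scalogram values must be nonnegative")
        if self.kind not in ("power", "amplitude"):
            raise ValueError(f"unknown scalogram kind: {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape


@dataclass(frozen=True)
class COIBoundary:
    """Per-band half-open valid index intervals in same-mode coordinates."""

    n_start: np.ndarray
    n_end: np.ndarray
    footprint: np.ndarray
    N: int

    def __post_init__(self) -> None:
        for name in ("n_start", "n_end", "footprint"):
            arr = np.asarray(getattr(self, name), dtype=int)
            object.__setattr__(self, name, arr)
        if not (self.n_start.shape == self.n_end.shape == self.footprint.shape):
            raise ValueError("per-band arrays must share shape")

    @property
    def J(self) -> int:
        return int(self.n_start.size)

    @property
    def Nf(self) -> np.ndarray:
        """In-COI sample count per band."""
        return np.maximum(0, self.n_end - self.n_start)

    @property
    def n_valid(self) -> int:
        """Total in-COI coefficient count (sum of Nf)."""
        return int(self.Nf.sum())

    @classmethod
    def from_counts(cls, nf: Sequence[int], N: int) -> "COIBoundary":
        """Boundary with given per-band in-COI counts, centered per band.

        Each count Nf implies the footprint L = N - Nf + 1 that a valid
        convolution would need to produce exactly Nf outputs; the interval
        is placed where that footprint's same-mode slice would put it.
        """
        nf = np.asarray(nf, dtype=int)
        if np.any(nf < 0) or np.any(nf > N):
            raise ValueError("counts must lie in [0, N]")
        L = np.where(nf > 0, N - nf + 1, N + 1)
        start = np.where(nf > 0, (L - 1) - (L - 1) // 2, 0)
        end = np.where(nf > 0, start + nf, 0)
        return cls(start, end, L, int(N))

    def mask(self) -> np.ndarray:
        """J x N binary matrix, 1 exactly at in-COI positions."""
        cols = np.arange(self.N)[None, :]
        return (
            (cols >= self.n_start[:, None]) & (cols < self.n_end[:, None])
        ).astype(np.uint8)


def morlet(
    time_grid: np.ndarray, params: WaveletParams, f0: float
) -> np.ndarray:
    """Sample the unit-energy analytic Morlet wavelet on ``time_grid``.

    The wavelet is ``A exp(-t^2 / 2 sigma^2) exp(j 2 pi f0 t)`` with ``A``
    chosen so the discrete energy ``sum |Psi|^2 dt`` equals one on the
    given grid.
    """
    t = np.asarray(time_grid, dtype=float)
    if not f0 > 0:
        raise ValueError("center frequency must be positive")
    sigma = params.sigma_t(f0)
    psi = np.exp(-(t**2) / (2.0 * sigma**2)) * np.exp(2j * np.pi * f0 * t)
    if t.size > 1:
        dt = float(t[1] - t[0])
    else:
        dt = 1.0
    energy = np.sum(np.abs(psi) ** 2) * dt
    return psi / np.sqrt(energy)


def convolve(x: Sequence[float], h: Sequence[float], mode: ConvMode) -> np.ndarray:
    """Linear convolution with explicit full/same/valid slice semantics.

    full  -> length N + L - 1, every partial-overlap term included;
    same  -> length N, the centered slice full[(L-1)//2 : (L-1)//2 + N];
    valid -> length N - L + 1, only complete-overlap terms.
    """
    x = np.asarray(x)
    h = np.asarray(h)
    if x.ndim != 1 or h.ndim != 1 or x.size < 1 or h.size < 1:
        raise ValueError("x and h must be non-empty 1-D sequences")
    n, ell = x.size, h.size
    full = np.convolve(x, h, mode="full")
    if mode == "full":
        return full
    if mode == "same":
        start = (ell - 1) // 2
        return full[start : start + n]
    if mode == "valid":
        if ell > n:
            raise ValueError(
                f"valid mode needs kernel length {ell} <= signal length {n}"
            )
        return full[ell - 1 : n]
    raise ValueError(f"unknown convolution mode: {mode!r}")


def wavelet_footprint(f0: float, fs: float, params: WaveletParams) -> int:
    """Discrete support length (odd sample count) of the truncated wavelet."""
    half = int(np.ceil(params.half_extent(f0) * fs))
    return 2 * half + 1


def _band_kernel(f0: float, fs: float, params: WaveletParams) -> np.ndarray:
    L = wavelet_footprint(f0, fs, params)
    half = (L - 1) // 2
    t = np.arange(-half, half + 1) / fs
    return morlet(t, params, f0)


def cwt_scalogram(
    signal: Signal,
    grid: FrequencyGrid,
    params: WaveletParams,
    mode: ConvMode = "same",
    kind: Literal["power", "amplitude"] = "power",
) -> tuple[CoefficientMatrix, Scalogram]:
    """CWT coefficient matrix and scalogram over a frequency grid.

    Row f is the mode-convolution of the signal with the conjugated,
    time-reversed band-f wavelet so each coefficient is the correlation
    of the signal with the wavelet centered at that sample.  Rows are
    scale-normalized by 1/sqrt(a) with a = f_ref / f (f_ref = highest
    band).  Only ``same`` mode guarantees a rectangular J x N output;
    other modes raise if the rows would disagree in length.
    """
    nyquist = signal.fs / 2.0
    if np.any(grid.frequencies > nyquist):
        raise ValueError(
            f"band frequencies above Nyquist ({nyquist} Hz) would alias"
        )
    f_ref = float(np.max(grid.frequencies))
    rows = []
    for f0 in grid.frequencies:
        kernel = _band_kernel(float(f0), signal.fs, params)
        if kernel.size < 1:
            raise ValueError("empty wavelet footprint")
        scale = f_ref / float(f0)
        # correlation = convolution with conjugated, reversed kernel
        row = convolve(signal.samples, np.conj(kernel[::-1]), mode)
        rows.append(row / np.sqrt(scale))
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(
            f"mode {mode!r} yields unequal row lengths; use 'same' for a matrix"
        )
    W = np.vstack(rows)
    coeffs = CoefficientMatrix(W, grid, mode)
    amp = np.abs(W)
    G = amp**2 if kind == "power" else amp
    return coeffs, Scalogram(G, kind, grid)


def compute_coi(
    grid: FrequencyGrid, N: int, fs: float, params: WaveletParams
) -> COIBoundary:
    """Delineate the cone of influence for a J x N same-mode scalogram.

    A coefficient is inside the COI iff the truncated wavelet footprint
    centered on it lies entirely within [0, N) — exactly the positions a
    valid-mode convolution would produce.  Bands whose footprint exceeds
    N get an empty interval.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    starts, ends, footprints = [], [], []
    for f0 in grid.frequencies:
        L = wavelet_footprint(float(f0), fs, params)
        nf = max(0, N - L + 1)
        # valid output k maps to same-mode index k + (L-1) - (L-1)//2
        start = (L - 1) - (L - 1) // 2
        starts.append(start if nf > 0 else 0)
        ends.append(start + nf if nf > 0 else 0)
        footprints.append(L)
    return COIBoundary(
        np.array(starts), np.array(ends), np.array(footprints), int(N)
    )


def quality_rho(coi: COIBoundary, J: int | None = None, N: int | None = None) -> float:
    """Fraction of scalogram coefficients inside the COI (in [0, 1])."""
    J = coi.J if J is None else int(J)
    N = coi.N if N is None else int(N)
    total = J * N
    if total == 0:
        raise ValueError("J * N must be positive")
    return float(coi.Nf.sum()) / total


def quality_beta(W: CoefficientMatrix | np.ndarray, coi: COIBoundary) -> float:
    """Fraction of total scalogram power enclosed by the COI (in [0, 1])."""
    import warnings

    arr = W.W if isinstance(W, CoefficientMatrix) else np.asarray(W)
    if arr.shape != (coi.J, coi.N):
        raise ValueError(
            f"coefficient matrix shape {arr.shape} does not match COI "
            f"({coi.J}, {coi.N})"
        )
    power = np.abs(arr) ** 2
    total = float(power.sum())
    if total == 0.0:
        warnings.warn("zero total power; beta defined as 0", RuntimeWarning)
        return 0.0
    inside = float((power * coi.mask()).sum())
    return inside / total
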