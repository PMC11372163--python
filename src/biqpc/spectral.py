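"""Welch segmentation, cross-spectra, cross-bispectra and cross-bicoherence.

Estimation follows the direct (FFT-based) approach: the record is cut into
50 %-overlapping segments, each segment is standardized (zero mean, unit
variance) and transformed without a taper, and third-order moments are
averaged across segments.  The magnitude-squared cross-bicoherence

    b2_ijk(f1, f2) = |<Xi(f1) Xj(f2) Xk*(f1+f2)>|^2
                     / (<|Xi(f1) Xj(f2)|^2> <|Xk(f1+f2)|^2>)

is bounded in [0, 1] by the Cauchy-Schwarz inequality and has null mean
about ``1/L`` for ``L`` independent segments of a linear Gaussian process.

The bifrequency grid over ``(0, f_Nyquist]^2`` is partitioned into the three
sectors Q_I (f1+f2 <= Nyquist), Q_II (above Nyquist, f1 > f2) and Q_III
(above Nyquist, f1 <= f2); quadratic interactions whose sum frequency
exceeds the Nyquist limit alias into Q_II/Q_III.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .signal_model import EpochedSeries

__all__ = [
    "Sector",
    "SegmentPlan",
    "SegmentSpectra",
    "BifrequencyGrid",
    "BicoherenceMap",
    "nearest_power_of_two_fraction",
    "segment_series",
    "cross_spectrum",
    "cross_bispectrum",
    "cross_bicoherence",
    "classify_sector",
]


class Sector(enum.IntEnum):
    Q1 = 1
    Q2 = 2
    Q3 = 3


def nearest_power_of_two_fraction(x: float) -> float:
    """The value ``2**k`` (integer ``k``) closest to ``x``; ties go to the smaller."""
    if not x > 0:
        raise ValueError("x must be positive")
    k = math.log2(x)
    candidates = (2.0 ** math.floor(k), 2.0 ** math.ceil(k))
    return min(candidates, key=lambda c: abs(c - x))


@dataclass(frozen=True)
class SegmentPlan:
    """Welch segmentation geometry and the bispectral frequency grid.

    The experimental resolution is ``fs / segment_length``; the bispectral
    grid spacing ``delta_f`` is the nearest fractional power of two to it,
    realized by truncating each segment to ``dft_length = fs / delta_f``
    samples before the DFT.
    """

    fs: float
    segment_length: int
    overlap_fraction: float = 0.5
    delta_f: float = None  # type: ignore[assignment]
    dft_length: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segment_length must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.delta_f is None:
            object.__setattr__(
                self, "delta_f", nearest_power_of_two_fraction(self.fs / self.segment_length)
            )
        if self.dft_length is None:
            m = self.fs / self.delta_f
            if abs(m - round(m)) > 1e-9:
                raise ValueError("fs / delta_f must be an integer DFT length")
            object.__setattr__(self, "dft_length", int(round(m)))

    @property
    def f_nyquist(self) -> float:
        return self.fs / 2.0

    @property
    def experimental_delta_f(self) -> float:
        return self.fs / self.segment_length

    @property
    def step(self) -> int:
        return max(1, int(round(self.segment_length * (1.0 - self.overlap_fraction))))

    def segment_starts(self, total: int, per_epoch_length: int | None = None) -> np.ndarray:
        """Start indices of the sliding segments over a record of ``total`` samples.

        With ``per_epoch_length`` set, segments are confined within epochs
        instead of sliding across the merged record.
        """
        if per_epoch_length is None:
            if total < self.segment_length:
                raise ValueError("record shorter than one segment")
            return np.arange(0, total - self.segment_length + 1, self.step)
        if per_epoch_length < self.segment_length:
            raise ValueError("epoch shorter than one segment")
        inner = np.arange(0, per_epoch_length - self.segment_length + 1, self.step)
        offs = np.arange(0, total, per_epoch_length)
        return (offs[:, None] + inner[None, :]).ravel()


@dataclass
class SegmentSpectra:
    """Per-segment DFT coefficients for each channel.

    ``coeffs`` has shape ``(L, channels, dft_length // 2 + 1)`` (one-sided).
    Coefficients at frequencies above the Nyquist bin follow from Hermitian
    symmetry of real input and are exposed through :meth:`bin_values`.
    """

    coeffs: np.ndarray
    plan: SegmentPlan

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def bin_values(self, channel: int, k) -> np.ndarray:
        """DFT coefficients of ``channel`` at integer bins ``k`` in ``[0, dft_length)``.

        Bins beyond the one-sided range are folded via conjugate symmetry.
        """
        k = np.asarray(k)
        m = self.plan.dft_length
        if np.any((k < 0) | (k >= m)):
            raise IndexError("bin index out of range")
        half = m // 2
        folded = np.where(k > half, m - k, k)
        vals = self.coeffs[:, channel, :][:, folded]
        return np.where(k > half, np.conj(vals), vals)


def segment_series(
    series: EpochedSeries, plan: SegmentPlan, per_epoch: bool = False
) -> SegmentSpectra:
    """Slice, standardize and transform a record according to ``plan``.

    Segments slide with the plan's overlap across the concatenated record
    (or within epochs when ``per_epoch``).  Each segment is mean-removed and
    variance-normalized, then truncated (or zero-padded) to ``dft_length``
    and transformed without a taper.
    """
    x = series.concatenated()
    starts = plan.segment_starts(
        x.shape[1], series.samples_per_epoch if per_epoch else None
    )
    seg_len = plan.segment_length
    m = plan.dft_length
    idx = starts[:, None] + np.arange(seg_len)[None, :]
    segs = x[:, idx]  # channels x L x seg_len
    mu = segs.mean(axis=2, keepdims=True)
    sd = segs.std(axis=2, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant segment cannot be standardized")
    segs = (segs - mu) / sd
    if m <= seg_len:
        segs = segs[:, :, :m]
    else:
        segs = np.pad(segs, ((0, 0), (0, 0), (0, m - seg_len)))
    coeffs = np.fft.rfft(segs, axis=2)
    return SegmentSpectra(coeffs=np.swapaxes(coeffs, 0, 1), plan=plan)


def cross_spectrum(spectra: SegmentSpectra, i: int, j: int) -> np.ndarray:
    """Segment-averaged cross-spectrum ``<Xi(f) Xj*(f)>`` on the one-sided grid."""
    nc = spectra.n_channels
    if not (0 <= i < nc and 0 <= j < nc):
        raise IndexError("channel index out of range")
    return np.mean(spectra.coeffs[:, i, :] * np.conj(spectra.coeffs[:, j, :]), axis=0)


def classify_sector(f1: float, f2: float, f_nyquist: float) -> Sector:
    """Sector of the bifrequency ``(f1, f2)``; the ``f1+f2 = Nyquist`` boundary is Q_I."""
    if not (0 < f1 <= f_nyquist and 0 < f2 <= f_nyquist):
        raise ValueError("frequencies must lie in (0, f_nyquist]")
    if f1 + f2 <= f_nyquist + 1e-12:
        return Sector.Q1
    return Sector.Q2 if f1 > f2 else Sector.Q3


@dataclass
class BifrequencyGrid:
    """Bifrequency bins at integer multiples of ``delta_f`` in ``(0, f_Nyquist]``.

    ``sectors[a, b]`` labels the bin ``(freqs[a], freqs[b])``; ``mask`` marks
    the usable (principal-domain) bins, excluding the single corner whose sum
    frequency folds onto DC.
    """

    freqs: np.ndarray
    delta_f: float
    f_nyquist: float
    sectors: np.ndarray
    mask: np.ndarray

    @classmethod
    def from_plan(cls, plan: SegmentPlan) -> "BifrequencyGrid":
        half = plan.dft_length // 2
        k = np.arange(1, half + 1)
        freqs = k * plan.delta_f
        f1 = freqs[:, None]
        f2 = freqs[None, :]
        sectors = np.where(
            f1 + f2 <= plan.f_nyquist + 1e-12,
            int(Sector.Q1),
            np.where(f1 > f2, int(Sector.Q2), int(Sector.Q3)),
        ).astype(np.int8)
        ksum = k[:, None] + k[None, :]
        mask = (ksum % plan.dft_length) != 0
        return cls(
            freqs=freqs,
            delta_f=plan.delta_f,
            f_nyquist=plan.f_nyquist,
            sectors=sectors,
            mask=mask,
        )

    def sector_of(self, f1: float, f2: float) -> Sector:
        return classify_sector(f1, f2, self.f_nyquist)

    def nearest_index(self, f: float) -> int:
        return int(np.argmin(np.abs(self.freqs - f)))


def cross_bispectrum(spectra: SegmentSpectra, i: int, j: int, k: int) -> np.ndarray:
    """Segment-averaged cross-bispectrum ``<Xi(f1) Xj(f2) Xk*(f1+f2)>``.

    Returned on the ``(f1, f2)`` grid of positive bins up to the Nyquist bin;
    sum frequencies beyond Nyquist use the conjugate-symmetric (aliased)
    coefficients.  With ``i == j == k`` this is the single-channel bispectrum.
    """
    half = spectra.plan.dft_length // 2
    kk = np.arange(1, half + 1)
    ksum = (kk[:, None] + kk[None, :]) % spectra.plan.dft_length
    xi = spectra.coeffs[:, i, 1 : half + 1]
    xj = spectra.coeffs[:, j, 1 : half + 1]
    acc = np.zeros((half, half), dtype=complex)
    xk_full = _extended_coeffs(spectra, k)  # L x dft_length
    for s in range(spectra.n_segments):
        acc += np.outer(xi[s], xj[s]) * np.conj(xk_full[s, ksum])
    return acc / spectra.n_segments


def _extended_coeffs(spectra: SegmentSpectra, channel: int) -> np.ndarray:
    """Full-circle DFT coefficients (L x dft_length) via Hermitian symmetry."""
    one_sided = spectra.coeffs[:, channel, :]
    m = spectra.plan.dft_length
    full = np.empty((spectra.n_segments, m), dtype=complex)
    half = m // 2
    full[:, : half + 1] = one_sided
    full[:, half + 1 :] = np.conj(one_sided[:, 1:half][:, ::-1])
    return full


@dataclass
class BicoherenceMap:
    """Magnitude-squared cross-bicoherence on the bifrequency grid.

    ``b2[a, b]`` corresponds to ``(grid.freqs[a], grid.freqs[b])``; bins with a
    vanishing denominator are set to 0 and flagged in ``zero_denominator``.
    """

    b2: np.ndarray
    grid: BifrequencyGrid
    n_segments: int
    channels: tuple[int, int, int]
    zero_denominator: np.ndarray

    def values_in_domain(self) -> np.ndarray:
        return self.b2[self.grid.mask]


def cross_bicoherence(spectra: SegmentSpectra, i: int, j: int, k: int) -> BicoherenceMap:
    """Cross-bicoherence of channels ``(i, j, k)`` over the bifrequency grid."""
    if spectra.n_segments < 2:
        raise ValueError("at least 2 segments are required for bicoherence")
    plan = spectra.plan
    half = plan.dft_length // 2
    kk = np.arange(1, half + 1)
    ksum = (kk[:, None] + kk[None, :]) % plan.dft_length
    xi = spectra.coeffs[:, i, 1 : half + 1]
    xj = spectra.coeffs[:, j, 1 : half + 1]
    xk_full = _extended_coeffs(spectra, k)
    num_acc = np.zeros((half, half), dtype=complex)
    den1_acc = np.zeros((half, half))
    for s in range(spectra.n_segments):
        pair = np.outer(xi[s], xj[s])
        num_acc += pair * np.conj(xk_full[s, ksum])
        den1_acc += np.abs(pair) ** 2
    L = spectra.n_segments
    den2 = np.mean(np.abs(xk_full) ** 2, axis=0)[ksum]
    den = (den1_acc / L) * den2
    num = np.abs(num_acc / L) ** 2
    zero = den == 0
    b2 = np.zeros_like(den)
    np.divide(num, den, out=b2, where=~zero)
    grid = BifrequencyGrid.from_plan(plan)
    return BicoherenceMap(
        b2=b2, grid=grid, n_segments=L, channels=(i, j, k), zero_denominator=zero
    )
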