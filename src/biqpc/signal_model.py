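"""Three-channel noisy instantaneous-multiplier model of bifrequency interaction.

Two channels carry periodic inputs (a triangular wave ``I1`` and a rectangular
wave ``I2``) buried in unit Gaussian noise; a third channel receives a cosine
carrier, its own noise, and the instantaneous product of the first two channels
scaled by a coupling strength ``W``:

    X1 = I1 + xi1
    X2 = I2 + xi2
    X3 = W * X1 * X2 + I3 + xi3

Each epoch draws independent carrier phases (uniform on ``[0, 2*pi)``) and
independent noise, which makes the epochs exchangeable realizations of a
stationary process exhibiting quadratic phase coupling at the carrier
bifrequency ``(F1, F2)``.

The module also provides the analytic signal-to-noise ratios of the three
channels and an empirical SNR estimator based on harmonic regression at the
(aliased) harmonic frequencies of the declared carriers.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "WaveformKind",
    "WaveformSpec",
    "ConditionSpec",
    "EpochedSeries",
    "SnrReport",
    "CARRIER_FREQS_HZ",
    "waveform_sample",
    "sample_phases",
    "simulate_condition",
    "expected_snr",
    "empirical_snr",
    "harmonic_frequencies",
]

TWO_PI = 2.0 * math.pi

#: The study's carrier frequency set (Hz).  The frequencies are divided by
#: ``2*pi`` so that the carriers complete an integer number of radians per
#: second, which keeps them incommensurate with the sampling grid.
CARRIER_FREQS_HZ: tuple[float, ...] = (
    70.0 / TWO_PI,
    80.0 / TWO_PI,
    120.0 / TWO_PI,
    150.0 / TWO_PI,
    230.0 / TWO_PI,
    50.0 - 10.0 / TWO_PI,
)


class WaveformKind(str, enum.Enum):
    """Periodic carrier shapes available to the model."""

    TRIANGULAR = "triangular"
    RECTANGULAR = "rectangular"
    COSINE = "cosine"


class InvalidSpecError(ValueError):
    """Raised for malformed waveform or condition specifications."""


@dataclass(frozen=True)
class WaveformSpec:
    """A periodic carrier: shape, frequency (Hz) and initial phase (radians).

    The triangular wave ranges over ``[-pi, pi]``, the rectangular wave over
    ``{-1, +1}`` (the ``+1`` branch on the half-open phase interval
    ``[0, pi)``), and the cosine over ``[-1, 1]``.
    """

    kind: WaveformKind
    frequency: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        try:
            object.__setattr__(self, "kind", WaveformKind(self.kind))
        except ValueError as exc:
            raise InvalidSpecError(f"unknown waveform kind: {self.kind!r}") from exc
        if not (self.frequency > 0 and math.isfinite(self.frequency)):
            raise InvalidSpecError(f"frequency must be positive, got {self.frequency}")


def waveform_sample(spec: WaveformSpec, t):
    """Evaluate the carrier ``I(t)`` of `spec` at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidSpecError("t must be finite")
    arg = TWO_PI * spec.frequency * t + spec.phase
    if spec.kind is WaveformKind.TRIANGULAR:
        return 2.0 * np.arcsin(np.sin(arg))
    if spec.kind is WaveformKind.RECTANGULAR:
        return np.where(np.mod(arg, TWO_PI) < math.pi, 1.0, -1.0)
    return np.cos(arg)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the three-channel model.

    ``F3`` must differ from ``F1``, ``F2`` and ``F1 + F2`` so that the output
    carrier does not sit on top of the quadratic interaction products; pass
    ``allow_degenerate=True`` to explore such configurations anyway.
    """

    F1: float
    F2: float
    F3: float
    W: float = 0.0
    fs: float = 100.0
    epoch_duration: float = 5.0
    n_epochs: int = 128
    noise_sd: float = 1.0
    seed: int = 0
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("F1", "F2", "F3"):
            f = getattr(self, name)
            if not f > 0:
                raise InvalidSpecError(f"{name} must be positive, got {f}")
        if self.W < 0:
            raise InvalidSpecError("coupling strength W must be >= 0")
        n = self.fs * self.epoch_duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidSpecError("fs * epoch_duration must be an integer number of samples")
        if self.n_epochs < 1:
            raise InvalidSpecError("n_epochs must be >= 1")
        if not self.allow_degenerate:
            tol = 1e-9
            for bad, label in ((self.F1, "F1"), (self.F2, "F2"), (self.F1 + self.F2, "F1+F2")):
                if abs(self.F3 - bad) <= tol:
                    raise InvalidSpecError(
                        f"F3 coincides with {label}; pass allow_degenerate=True to override"
                    )

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * self.epoch_duration))


@dataclass
class EpochedSeries:
    """Multichannel samples organized in equal-length epochs.

    ``data`` has shape ``(channels, epochs, samples)``.  ``phases`` records the
    per-epoch carrier phases drawn during simulation (``channels x epochs``),
    kept for reproducibility checks; it is ``None`` for data read from disk.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ("X1", "X2", "X3")
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x epochs x samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]

    def concatenated(self) -> np.ndarray:
        """Channels x total-samples view with epochs merged in order."""
        return self.data.reshape(self.n_channels, -1)


def sample_phases(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` carrier phases uniformly from ``[0, 2*pi)``."""
    return rng.uniform(0.0, TWO_PI, size=n)


def simulate_condition(cond: ConditionSpec) -> EpochedSeries:
    """Generate the three-channel model for one condition.

    Fully reproducible from ``cond.seed``: a master ``SeedSequence`` spawns one
    child stream per epoch, so epochs are statistically independent and the
    realization of any epoch does not depend on ``n_epochs``.
    """
    n = cond.samples_per_epoch
    t = np.arange(n) / cond.fs
    master = np.random.SeedSequence(cond.seed)
    children = master.spawn(cond.n_epochs)

    data = np.empty((3, cond.n_epochs, n))
    phases = np.empty((3, cond.n_epochs))
    kinds = (WaveformKind.TRIANGULAR, WaveformKind.RECTANGULAR, WaveformKind.COSINE)
    freqs = (cond.F1, cond.F2, cond.F3)
    for e, child in enumerate(children):
        rng = np.random.default_rng(child)
        omega = sample_phases(rng, 3)
        noise = rng.normal(0.0, cond.noise_sd, size=(3, n))
        phases[:, e] = omega
        carriers = [
            waveform_sample(WaveformSpec(kind, f, w), t)
            for kind, f, w in zip(kinds, freqs, omega)
        ]
        x1 = carriers[0] + noise[0]
        x2 = carriers[1] + noise[1]
        x3 = cond.W * x1 * x2 + carriers[2] + noise[2]
        data[0, e] = x1
        data[1, e] = x2
        data[2, e] = x3
    return EpochedSeries(data=data, fs=cond.fs, phases=phases)


def expected_snr(channel: int, W: float = 0.0) -> float:
    """Analytic SNR of channel 1, 2 or 3 (``W`` only matters for channel 3).

    Channel 1 (triangular carrier, unit noise): ``pi**2 / 3``.
    Channel 2 (rectangular): ``1``.
    Channel 3 (cosine plus coupled product): ``(2*pi**2/3 + 2) * W**2 + 1/2``.
    """
    if channel == 1:
        return math.pi**2 / 3.0
    if channel == 2:
        return 1.0
    if channel == 3:
        if W < 0:
            raise InvalidSpecError("W must be >= 0")
        return (2.0 * math.pi**2 / 3.0 + 2.0) * W**2 + 0.5
    raise InvalidSpecError(f"channel must be 1, 2 or 3, got {channel}")


def _fold(f: float, fs: float) -> float:
    """Alias a continuous-time frequency into the baseband ``[0, fs/2]``."""
    r = math.fmod(f, fs)
    if r < 0:
        r += fs
    return fs - r if r > fs / 2 else r


def harmonic_frequencies(
    kind: WaveformKind,
    frequency: float,
    fs: float,
    max_harmonic: int | None = None,
) -> np.ndarray:
    """Folded harmonic line frequencies of a carrier, within ``(0, fs/2)``.

    Triangular and rectangular carriers hold only odd harmonics; sampling
    aliases harmonics above the Nyquist frequency back into the baseband.
    The truncation defaults reflect the spectral decay of each shape
    (``1/n**4`` in power for triangular, ``1/n**2`` for rectangular, so the
    rectangular set must reach much higher orders to capture the same power
    fraction).
    """
    kind = WaveformKind(kind)
    if kind is WaveformKind.COSINE:
        orders = [1]
    else:
        if max_harmonic is None:
            max_harmonic = 19 if kind is WaveformKind.TRIANGULAR else 199
        orders = list(range(1, max_harmonic + 1, 2))
    eps = 1e-9
    lines = []
    for m in orders:
        f = _fold(m * frequency, fs)
        if eps < f < fs / 2 - eps:
            lines.append(f)
    return np.asarray(sorted(lines))


def _dedupe_lines(lines: np.ndarray, min_sep: float) -> np.ndarray:
    """Merge lines closer than ``min_sep`` (unresolvable within one epoch)."""
    if lines.size == 0:
        return lines
    kept = [lines[0]]
    for f in lines[1:]:
        if f - kept[-1] >= min_sep:
            kept.append(f)
    return np.asarray(kept)


@dataclass
class SnrReport:
    """Empirical and analytic SNR per channel, plus the channel-3 efficiency.

    ``efficiency`` is the ratio of the empirical to the analytic SNR of the
    output channel; values below 1 mean the estimator attributes part of the
    coupled power to the noise floor (a conservative detection regime).
    """

    empirical: np.ndarray
    expected: np.ndarray
    W: float

    @property
    def efficiency(self) -> float:
        return float(self.empirical[2] / self.expected[2])


def _condition_lines(cond: ConditionSpec) -> list[np.ndarray]:
    """Declared harmonic line sets for the three channels of a condition."""
    fs = cond.fs
    lines1 = harmonic_frequencies(WaveformKind.TRIANGULAR, cond.F1, fs)
    lines2 = harmonic_frequencies(WaveformKind.RECTANGULAR, cond.F2, fs)
    lines3 = list(harmonic_frequencies(WaveformKind.COSINE, cond.F3, fs))
    if cond.W > 0:
        # quadratic products of the two input carriers: n*F1 +/- m*F2, odd n, m
        eps = 1e-9
        for n in range(1, 10, 2):
            for m in range(1, 40, 2):
                for f in (n * cond.F1 + m * cond.F2, abs(n * cond.F1 - m * cond.F2)):
                    fb = _fold(f, fs)
                    if eps < fb < fs / 2 - eps:
                        lines3.append(fb)
    return [np.asarray(sorted(set(np.round(lines1, 9)))),
            np.asarray(sorted(set(np.round(lines2, 9)))),
            np.asarray(sorted(set(np.round(lines3, 9))))]


def empirical_snr(series: EpochedSeries, cond: ConditionSpec) -> SnrReport:
    """Estimate per-channel SNR by harmonic regression on each epoch.

    Each epoch of a channel is regressed (ordinary least squares) on sine and
    cosine pairs at that channel's declared harmonic frequencies (folded into
    the baseband, merged when closer than the epoch's Rayleigh resolution).
    The noise power is the residual variance corrected for the regression's
    degrees of freedom; the signal power is the fitted power minus the noise
    power absorbed by the fitted parameters.  The SNR is the ratio of the
    epoch-averaged powers, matching the analytic limits for long records.
    """
    if series.n_channels != 3:
        raise ValueError("expected a three-channel series")
    n = series.samples_per_epoch
    t = np.arange(n) / series.fs
    rayleigh = 1.0 / (n / series.fs)  # one-over-epoch-duration resolution
    line_sets = [_dedupe_lines(l, 0.5 * rayleigh) for l in _condition_lines(cond)]

    empirical = np.empty(3)
    for ch, lines in enumerate(line_sets):
        if lines.size == 0:
            raise InvalidSpecError(f"channel {ch + 1} has no resolvable harmonic lines")
        cols = [np.ones(n)]
        for f in lines:
            w = TWO_PI * f * t
            cols.append(np.cos(w))
            cols.append(np.sin(w))
        design = np.column_stack(cols)
        k_params = design.shape[1]
        if k_params >= n:
            raise InvalidSpecError("harmonic design exceeds epoch length")
        x = series.data[ch]  # epochs x samples
        coeffs, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        fitted = design @ coeffs
        resid = x.T - fitted
        ss_res = np.sum(resid**2, axis=0)
        ss_fit = np.sum(fitted**2, axis=0)
        noise_var = ss_res / (n - k_params)
        p_noise = float(np.mean(noise_var))
        if p_noise <= 0:
            raise ZeroDivisionError("zero noise floor")
        p_signal = float(np.mean(ss_fit / n - noise_var * k_params / n))
        empirical[ch] = max(p_signal, 0.0) / p_noise

    expected = np.array([expected_snr(1), expected_snr(2), expected_snr(3, cond.W)])
    return SnrReport(empirical=empirical, expected=expected, W=cond.W)
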