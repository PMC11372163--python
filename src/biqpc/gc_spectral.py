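"""Bivariate spectral Granger causality from a product process, and R_GQPC.

To localize quadratic phase coupling with Granger causality, the point-wise
product ``U(t) = Xi(t) * Xj(t)`` is paired with the putative output ``Xk(t)``
and Geweke's frequency-domain decomposition of the causality from ``U`` to
``Xk`` is computed from a bivariate VAR fitted on each Welch segment; the
per-frequency median across segments is the bivariate GC spectrum (BGCS).
A genuine quadratic interaction at bifrequency ``(f1, f2)`` produces causal
power near the sum frequency ``f1 + f2`` (aliased back into the baseband when
it exceeds the Nyquist frequency).

Significance is assessed by a residual bootstrap under the no-causality null:
the output channel is resimulated from its own reduced autoregressive model,
the median BGCS is recomputed for each bootstrap draw, and per-frequency
p-values are converted to q-values (Storey pFDR with a Benjamini-Hochberg
fallback).  The significance threshold ``theta`` is the smallest significant
value of the median spectrum.  R_GQPC is the fraction of the significant
causal mass that falls inside the spectral interval of interest.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import lfilter

from . import fdr as _fdr
from .qpc_bispec import qpc_ratio
from .signal_model import EpochedSeries
from .spectral import SegmentPlan

__all__ = [
    "SelectedLag",
    "GcSpectrum",
    "GqpcResult",
    "select_lag",
    "bgcs",
    "nboots_rule",
    "bootstrap_significance",
    "interval_of_interest",
    "r_gqpc",
    "geweke_spectrum",
    "time_domain_gc",
]

logger = logging.getLogger(__name__)

_RIDGE = 1e-10


def _standardize(x: np.ndarray, axis: int = -1) -> np.ndarray:
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


@dataclass
class SelectedLag:
    """Selected VAR order with the Schwarz-criterion values over 1..lag_max."""

    lag: int
    sc: np.ndarray  # sc[l-1] is the criterion at order l

    @property
    def argmin(self) -> int:
        return int(np.argmin(self.sc)) + 1


def select_lag(z: np.ndarray, lag_max: int = 50) -> SelectedLag:
    """VAR order by the 95 %-of-lowest-Schwarz-criterion heuristic.

    The Schwarz criterion ``SC(l) = ln det(Sigma_l) + l K^2 ln(T)/T`` is
    evaluated on a common estimation window for every order 1..lag_max; the
    selected order is the smallest ``l`` with
    ``SC(l) <= SC_min + 0.05 |SC_min|`` — an anti-overfitting relaxation that
    never exceeds the argmin.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("z must be an (n, 2) array")
    n = z.shape[0]
    if n < 2 * lag_max:
        lag_max = max(1, n // 4)
        warnings.warn(f"series too short; reducing lag_max to {lag_max}", RuntimeWarning)
    K = 2
    T = n - lag_max
    # design at the maximal order; order-l fits reuse its leading columns
    sw = sliding_window_view(z, lag_max, axis=0)  # (n-lag_max+1, 2, lag_max)
    X = sw[:T, :, ::-1].transpose(0, 2, 1).reshape(T, lag_max * K)
    Y = z[lag_max:]
    G = X.T @ X
    C = X.T @ Y
    S0 = Y.T @ Y
    sc = np.empty(lag_max)
    for l in range(1, lag_max + 1):
        m = l * K
        Gl = G[:m, :m] + _RIDGE * np.eye(m)
        beta = np.linalg.solve(Gl, C[:m])
        sigma = (S0 - C[:m].T @ beta) / T
        det = np.linalg.det(sigma)
        sc[l - 1] = (math.log(det) if det > 0 else -np.inf) + l * K**2 * math.log(T) / T
    sc_min = float(np.min(sc))
    threshold = sc_min + 0.05 * abs(sc_min)
    lag = int(np.argmax(sc <= threshold)) + 1
    return SelectedLag(lag=lag, sc=sc)


def _fit_var_segments(segs: np.ndarray, l: int):
    """Batched OLS VAR(l) over segments.

    ``segs`` is (L, T, 2); returns coefficient tensors ``A`` (L, l, 2, 2) with
    ``A[s, m-1]`` the lag-m matrix, and residual covariances (L, 2, 2).
    """
    L, T, K = segs.shape
    if T <= l * K + 2:
        raise ValueError("segments too short for the requested lag order")
    sw = sliding_window_view(segs, l, axis=1)  # (L, T-l+1, 2, l)
    X = np.ascontiguousarray(
        sw[:, : T - l, :, ::-1].transpose(0, 1, 3, 2).reshape(L, T - l, l * K)
    )
    Y = segs[:, l:, :]
    Xt = X.transpose(0, 2, 1)
    G = Xt @ X + _RIDGE * np.eye(l * K)
    C = Xt @ Y
    beta = np.linalg.solve(G, C)  # (L, l*K, 2)
    resid = Y - X @ beta
    Sigma = resid.transpose(0, 2, 1) @ resid / (T - l)
    A = beta.reshape(L, l, K, K).transpose(0, 1, 3, 2)  # A[s, m, eq, var]
    return A, Sigma


def _geweke_batched(A: np.ndarray, Sigma: np.ndarray, freqs: np.ndarray, fs: float):
    """Geweke causality channel 1 -> channel 0 for a batch of VAR models.

    Returns an (L, F) array; entries are NaN for segments with a degenerate
    residual covariance.
    """
    L, l, _, _ = A.shape
    omega = 2.0 * math.pi * np.asarray(freqs) / fs
    E = np.exp(-1j * np.outer(omega, np.arange(1, l + 1)))  # (F, l)
    Aw = np.eye(2)[None, None] - np.einsum("fm,smij->sfij", E, A)
    det = Aw[..., 0, 0] * Aw[..., 1, 1] - Aw[..., 0, 1] * Aw[..., 1, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        H00 = Aw[..., 1, 1] / det
        H01 = -Aw[..., 0, 1] / det
        s00 = Sigma[:, 0, 0][:, None]
        s01 = Sigma[:, 0, 1][:, None]
        s11 = Sigma[:, 1, 1][:, None]
        H00t = H00 + (s01 / s00) * H01
        intrinsic = np.abs(H00t) ** 2 * s00
        Syy = intrinsic + np.abs(H01) ** 2 * (s11 - s01**2 / s00)
        out = np.log(Syy / intrinsic)
    out = np.where(np.isfinite(out), out, np.nan)
    return np.clip(out.real, 0.0, None)


def geweke_spectrum(A: np.ndarray, Sigma: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Geweke spectral causality (channel 1 -> channel 0) of a single VAR model."""
    out = _geweke_batched(A[None], Sigma[None], np.asarray(freqs, dtype=float), fs)[0]
    return out


def time_domain_gc(z: np.ndarray, l: int) -> float:
    """Time-domain Geweke statistic ``ln(var_reduced / var_full)`` for col 1 -> col 0."""
    z = np.asarray(z, dtype=float)
    y = z[:, 0]
    sw = sliding_window_view(y, l)[:-1]  # rows t-l..t-1
    Xr = sw[:, ::-1]
    Yr = y[l:]
    beta, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    var_reduced = float(np.mean((Yr - Xr @ beta) ** 2))
    _, Sigma = _fit_var_segments(z[None], l)
    return math.log(var_reduced / Sigma[0, 0, 0])


@dataclass
class GcSpectrum:
    """Median bivariate GC spectrum with (optional) bootstrap significance.

    ``bgcs`` is the per-frequency median across Welch segments of the Geweke
    causality from the product process to the output channel.  After
    :func:`bootstrap_significance`, ``p``/``q`` hold per-frequency bootstrap
    p-values and q-values, ``significant`` the spectrum restricted to
    ``q < 0.05`` (0 elsewhere) and ``theta`` the smallest significant value
    (``None`` when nothing is significant).
    """

    freqs: np.ndarray
    bgcs: np.ndarray
    lag: int
    n_segments: int
    plan: SegmentPlan
    p: np.ndarray | None = None
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    theta: float | None = None
    nboots: int | None = None
    _u: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    _starts: np.ndarray | None = field(default=None, repr=False)

    @property
    def experimental_delta_f(self) -> float:
        return self.plan.experimental_delta_f


def _segment_matrix(y: np.ndarray, u: np.ndarray, starts: np.ndarray, seg_len: int):
    idx = starts[:, None] + np.arange(seg_len)[None, :]
    segs = np.stack([y[idx], u[idx]], axis=2)  # (L, T, 2): col 0 target, col 1 driver
    return _standardize(segs, axis=1)


def _median_bgcs(segs: np.ndarray, l: int, freqs: np.ndarray, fs: float) -> np.ndarray:
    A, Sigma = _fit_var_segments(segs, l)
    spec = _geweke_batched(A, Sigma, freqs, fs)
    good = ~np.any(np.isnan(spec), axis=1)
    if good.sum() < 0.5 * len(good):
        raise RuntimeError("more than half of the segment VAR fits are singular")
    if not good.all():
        logger.info("skipping %d singular segment fits", int((~good).sum()))
    return np.median(spec[good], axis=0)


def bgcs(
    series: EpochedSeries,
    i: int,
    j: int,
    k: int,
    plan: SegmentPlan,
    lag: int | None = None,
    lag_max: int = 50,
) -> GcSpectrum:
    """Median BGCS of the product ``Xi * Xj`` onto ``Xk`` across Welch segments.

    The VAR order is selected once on the full (standardized) record by the
    Schwarz-criterion heuristic, then a bivariate VAR of that order is fitted
    on every segment and the Geweke causality spectrum is evaluated on the
    Fourier grid of the experimental resolution; the point-wise median across
    segments is returned.
    """
    x = series.concatenated()
    u = x[i] * x[j]
    y = x[k]
    zfull = np.column_stack([_standardize(y), _standardize(u)])
    if lag is None:
        sel = select_lag(zfull, lag_max=lag_max)
        lag = sel.lag
        logger.info("selected VAR lag %d (argmin %d)", lag, sel.argmin)
    starts = plan.segment_starts(x.shape[1])
    segs = _segment_matrix(zfull[:, 0], zfull[:, 1], starts, plan.segment_length)
    df = plan.experimental_delta_f
    n_half = plan.segment_length // 2
    freqs = df * np.arange(1, n_half)  # the open band (0, f_Nyquist)
    med = _median_bgcs(segs, lag, freqs, series.fs)
    logger.info("BGCS: %d segments, lag %d, %d frequencies", len(starts), lag, len(freqs))
    return GcSpectrum(
        freqs=freqs, bgcs=med, lag=lag, n_segments=segs.shape[0], plan=plan,
        _u=zfull[:, 1], _y=zfull[:, 0], _starts=starts,
    )


def nboots_rule(delta_f_exp: float) -> int:
    """Number of bootstrap series: ``round(sqrt(delta_f) * 1000)``."""
    if not delta_f_exp > 0:
        raise ValueError("spectral resolution must be positive")
    return int(round(math.sqrt(delta_f_exp) * 1000.0))


def _fit_ar(y: np.ndarray, l: int):
    sw = sliding_window_view(y, l)[:-1]
    X = sw[:, ::-1]
    Y = y[l:]
    phi, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ phi
    return phi, resid


def _var_residuals(z: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Residuals of a bivariate VAR with coefficient tensor ``A`` on record ``z``."""
    l = A.shape[0]
    sw = sliding_window_view(z, l, axis=0)  # (n-l+1, 2, l)
    X = sw[: z.shape[0] - l, :, ::-1].transpose(0, 2, 1).reshape(-1, 2 * l)
    return z[l:] - X @ _coeff_matrix(A)


def _coeff_matrix(A: np.ndarray) -> np.ndarray:
    """(2l, 2) regression layout of the VAR tensor, matching ``_fit_var_segments``."""
    l = A.shape[0]
    # _fit_var_segments: A = beta.reshape(L, l, K, K).transpose(0, 1, 3, 2)
    # i.e. beta[(m, var), eq] = A[m, eq, var]; invert that layout here
    return A.transpose(0, 2, 1).reshape(l * 2, 2)


def _stabilize_var(A: np.ndarray, margin: float = 0.999) -> np.ndarray:
    """Shrink VAR coefficients so the companion matrix is strictly stable."""
    l = A.shape[0]
    comp = np.zeros((2 * l, 2 * l))
    for m in range(l):
        comp[0:2, 2 * m : 2 * m + 2] = A[m]
    if l > 1:
        comp[2:, :-2] = np.eye(2 * (l - 1))
    radius = float(np.max(np.abs(np.linalg.eigvals(comp))))
    if radius < margin:
        return A
    shrink = margin / radius
    return A * (shrink ** np.arange(1, l + 1))[:, None, None]


def _simulate_var_batch(
    A: np.ndarray, resid: np.ndarray, rng: np.random.Generator, nb: int, n: int, burn: int
) -> np.ndarray:
    """Resimulate ``nb`` records of length ``n`` from a fitted bivariate VAR.

    Residual rows are resampled jointly (preserving the instantaneous
    covariance); the recursion is vectorized across bootstrap replicates.
    """
    l = A.shape[0]
    total = n + burn
    idx = rng.integers(0, resid.shape[0], size=(nb, total))
    z = resid[idx]  # (nb, total, 2): innovations, overwritten by the recursion
    for t in range(l, total):
        past = z[:, t - l : t][:, ::-1]  # (nb, l, 2), lag 1 first
        z[:, t] += np.einsum("bmj,mij->bi", past, A)
    return z[:, burn:]


def bootstrap_significance(
    spec: GcSpectrum,
    nboots: int | None = None,
    seed: int | np.random.SeedSequence = 0,
    q_threshold: float = 0.05,
    null_model: str = "prominence",
) -> GcSpectrum:
    """Bootstrap significance of the median BGCS, frequency by frequency.

    With the default ``"prominence"`` null the full bivariate VAR fitted to
    the whole record is resimulated from jointly resampled residuals, the
    median BGCS is recomputed per draw, and the p-value at frequency ``f`` is
    the fraction of draws in which the causality at ``f`` does not exceed the
    spectrum-wide median — a one-sided test of whether ``f`` carries
    consistently prominent causal mass.  With ``null_model="reduced"`` the
    output channel is resimulated from its own reduced autoregression (a
    global no-causality null) and the p-value compares the bootstrap spectra
    with the observed one point-wise.

    q-values use Storey pFDR (Benjamini-Hochberg fallback for degenerate
    p-samples); ``theta`` is the smallest significant median-BGCS value
    (``None`` when nothing is significant).
    """
    if spec._u is None or spec._y is None or spec._starts is None:
        raise ValueError("spectrum does not carry the data needed for bootstrapping")
    if null_model not in ("prominence", "reduced"):
        raise ValueError("null_model must be 'prominence' or 'reduced'")
    if nboots is None:
        nboots = nboots_rule(spec.experimental_delta_f)
    if nboots < 100:
        warnings.warn("nboots < 100: reduced-precision bootstrap", RuntimeWarning)
    rng = np.random.default_rng(seed)
    l = spec.lag
    y = spec._y
    u = spec._u
    n = y.size
    burn = 20 * l
    count = np.zeros_like(spec.bgcs)
    if null_model == "prominence":
        z = np.column_stack([y, u])
        A, _ = _fit_var_segments(z[None], l)
        A = _stabilize_var(A[0])
        resid = _var_residuals(z, A)
        chunk = max(1, min(nboots, int(4e6 // max(n, 1))))
        done = 0
        while done < nboots:
            nb = min(chunk, nboots - done)
            zb = _simulate_var_batch(A, resid, rng, nb, n, burn)
            for b in range(nb):
                segs = _segment_matrix(
                    zb[b, :, 0], zb[b, :, 1], spec._starts, spec.plan.segment_length
                )
                boot = _median_bgcs(segs, l, spec.freqs, spec.plan.fs)
                count += boot <= np.median(boot) + 1e-15
            done += nb
    else:
        phi, resid_r = _fit_ar(y, l)
        a_poly = np.concatenate([[1.0], -phi])
        for _ in range(nboots):
            e = rng.choice(resid_r, size=n + burn, replace=True)
            y_star = lfilter([1.0], a_poly, e)[burn:]
            segs = _segment_matrix(y_star, u, spec._starts, spec.plan.segment_length)
            boot = _median_bgcs(segs, l, spec.freqs, spec.plan.fs)
            count += boot >= spec.bgcs - 1e-15
    # raw bootstrap proportions: a frequency that is prominent in every draw
    # gets p = 0, hence q = 0, so an isolated genuine peak can define theta
    p = count / nboots
    q = _fdr.qvalues(p, pfdr=True)
    sig_mask = q < q_threshold
    if sig_mask.any():
        theta = float(np.min(spec.bgcs[sig_mask]))
        # theta is an amplitude threshold on the causality spectrum: every
        # frequency whose median BGCS reaches it carries significant mass
        significant = np.where(spec.bgcs >= theta, spec.bgcs, 0.0)
    else:
        theta = None
        significant = np.zeros_like(spec.bgcs)
    logger.info(
        "bootstrap: nboots=%d, %d/%d q<%.2f frequencies, theta=%s",
        nboots, int(sig_mask.sum()), len(p), q_threshold,
        f"{theta:.6g}" if theta is not None else "undefined",
    )
    return replace(spec, p=p, q=q, significant=significant, theta=theta, nboots=nboots)


def interval_of_interest(
    f1: float, f2: float, d: float, f_nyquist: float, fs: float
) -> tuple[float, float]:
    """Spectral interval of interest around the (possibly aliased) sum frequency.

    The interval is centered at ``f1 + f2`` when the sum lies below the
    Nyquist frequency, and at its fold-back ``fs - (f1 + f2)`` otherwise, with
    half-width ``2 d``, clipped to the open band ``(0, f_nyquist)``.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    s = f1 + f2
    center = s if s <= f_nyquist + 1e-12 else fs - s
    lo = max(center - 2.0 * d, 0.0)
    hi = min(center + 2.0 * d, f_nyquist)
    if hi <= 0.0 or lo >= f_nyquist or hi < lo:
        raise ValueError("interval of interest is empty after clipping")
    return (lo, hi)


@dataclass
class GqpcResult:
    """R_GQPC with its numerator/denominator sums (``None`` ratio for 0/0)."""

    numerator: float
    denominator: float
    interval: tuple[float, float]

    @property
    def ratio(self) -> float | None:
        return qpc_ratio(self.numerator, self.denominator)

    @property
    def flag(self) -> str:
        r = self.ratio
        if r is None:
            return "undefined"
        if r == 0.0:
            return "zero"
        if abs(r - 1.0) <= 1e-12:
            return "one"
        return "ok"


def r_gqpc(spec: GcSpectrum, interval: tuple[float, float]) -> GqpcResult:
    """Fraction of significant causal mass inside the interval of interest."""
    if spec.significant is None:
        raise ValueError("bootstrap significance has not been computed")
    lo, hi = interval
    tol = 1e-9
    if lo > spec.freqs[-1] + tol or hi < spec.freqs[0] - tol:
        raise ValueError("interval lies outside the frequency grid")
    in_band = (spec.freqs >= lo - tol) & (spec.freqs <= hi + tol)
    num = float(np.sum(spec.significant[in_band]))
    den = float(np.sum(spec.significant))
    return GqpcResult(numerator=num, denominator=den, interval=(lo, hi))
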