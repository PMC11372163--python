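"""Empirical-Bayes FDR significance for cross-bicoherence, plus q-value tools.

The observed cross-bicoherence values over the bifrequency domain are modeled
as a two-class mixture

    F(x) = p0 * F0(x) + (1 - p0) * FA(x)

on the chi-square scale ``x = 2 L b2`` (for zero true bicoherence, ``2 L b2``
is asymptotically chi-square with 2 degrees of freedom, i.e. exponential with
mean 2).  The null component is a scaled chi2_2 whose scale and weight ``p0``
are fitted to the modal bulk of the histogram (bin width 0.001, ``p0``
constrained to [0, 0.9]); right-tail FDR q-values follow from the fitted null
survival against the empirical survival.

The module also provides Storey-type pFDR q-values for bootstrap p-values,
with a Benjamini-Hochberg fallback when the p-value sample is degenerate.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import BicoherenceMap

__all__ = [
    "MixtureFit",
    "SignificanceMap",
    "fit_null_mixture",
    "significance_map",
    "qvalues",
    "DegenerateSampleError",
]

logger = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """Raised when the statistic sample carries no usable variation."""


@dataclass
class MixtureFit:
    """Fitted two-class mixture over a cross-bicoherence sample.

    ``null_mean`` is the mean of the fitted null component on the
    ``2 L b2`` scale (2.0 for the theoretical chi2_2 null); ``p0`` is the
    fitted null fraction.  ``values`` and ``q`` hold the input statistics
    (b2 scale, original order) and their right-tail FDR q-values.
    """

    p0: float
    null_mean: float
    L: int
    bin_width: float
    values: np.ndarray
    q: np.ndarray
    theoretical_fallback: bool = False

    def q_of(self, values: np.ndarray) -> np.ndarray:
        """q-values for arbitrary statistics on the same scale as the fit."""
        order = np.argsort(self.values)
        return np.interp(values, self.values[order], self.q[order])


def _histogram_mode(x: np.ndarray, bin_width: float) -> tuple[int, np.ndarray, np.ndarray]:
    """Smoothed-histogram mode: 3-bin moving average, ties to the smaller bin."""
    hi = float(np.max(x))
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(counts, kernel, mode="same")
    mode_bin = int(np.argmax(smooth))  # argmax takes the first (smallest) tie
    return mode_bin, counts, edges


def _rebin(counts: np.ndarray, edges: np.ndarray, factor: int):
    """Aggregate histogram bins by an integer factor (for stable regression)."""
    if factor <= 1:
        centers = 0.5 * (edges[:-1] + edges[1:])
        return counts.astype(float), centers
    n_blocks = len(counts) // factor
    trimmed = counts[: n_blocks * factor].reshape(n_blocks, factor)
    block_counts = trimmed.sum(axis=1).astype(float)
    block_centers = edges[0] + (np.arange(n_blocks) + 0.5) * factor * (edges[1] - edges[0])
    return block_counts, block_centers


def fit_null_mixture(
    values: np.ndarray,
    L: int,
    bin_width: float = 0.001,
    p0_bounds: tuple[float, float] = (0.0, 0.9),
    min_values: int = 500,
) -> MixtureFit:
    """Fit the null component of the cross-bicoherence mixture by mode matching.

    ``values`` are raw b2 statistics; they are rescaled to ``x = 2 L b2`` and
    histogrammed at ``bin_width``.  The null (scaled chi2_2, i.e. exponential)
    is anchored at the histogram's smoothed mode and its mean is refined by
    iteratively reweighted log-linear regression over the modal bulk; the null
    fraction ``p0`` follows from the regression intercept, boxed to
    ``p0_bounds``.  If the mode sits at the right edge of the histogram the
    theoretical chi2_2 null is used instead (with a warning).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < min_values:
        raise ValueError(f"need at least {min_values} values, got {values.size}")
    if np.ptp(values) == 0:
        raise DegenerateSampleError("all statistic values are identical")
    if L < 2:
        raise ValueError("segment count L must be >= 2")

    x = 2.0 * L * values
    n = x.size
    mode_bin, counts, edges = _histogram_mode(x, bin_width)
    fallback = mode_bin >= len(counts) - 2
    if not fallback:
        # the base histogram at bin_width defines the statistic's resolution;
        # the regression below runs on blocks coarse enough that the bulk of
        # the sample spans ~150 blocks (stable Poisson counts per block)
        q90 = float(np.quantile(x, 0.9))
        factor = max(1, int(math.ceil(q90 / bin_width / 150.0)))
        block_counts, block_centers = _rebin(counts, edges, factor)
        smooth = np.convolve(block_counts, np.ones(3) / 3.0, mode="same")
        bmode = int(np.argmax(smooth))
        # initial null scale from the mode's half-maximum width (an
        # exponential falls to half its modal density at m * ln 2)
        below = np.nonzero(smooth[bmode:] <= 0.5 * smooth[bmode])[0]
        if below.size:
            m_hat = max(
                (block_centers[bmode + below[0]] - block_centers[bmode]) / math.log(2.0),
                bin_width,
            )
        else:
            m_hat = max(float(np.median(x)) / math.log(2.0), bin_width)
        p0 = 1.0
        start = block_centers[bmode]
        converged = False
        for _ in range(50):
            lo, hi = start, start + 2.5 * m_hat
            sel = (block_centers >= lo) & (block_centers <= hi) & (block_counts > 0)
            if sel.sum() < 3:
                break
            yv = np.log(block_counts[sel])
            c = block_centers[sel]
            wts = np.sqrt(block_counts[sel])  # Poisson: var(log count) ~ 1/count
            A = np.column_stack([np.ones(c.size), c])
            beta, *_ = np.linalg.lstsq(A * wts[:, None], yv * wts, rcond=None)
            slope = beta[1]
            if slope >= 0:
                break
            m_new = -1.0 / slope
            p0 = float(np.exp(beta[0]) * m_new / (n * factor * bin_width))
            if abs(m_new - m_hat) < 1e-8 * m_hat:
                m_hat = m_new
                converged = True
                break
            m_hat = m_new
        if not converged and not (m_hat > 0 and math.isfinite(m_hat)):
            fallback = True
    if fallback:
        warnings.warn(
            "histogram mode at the right edge; falling back to the theoretical chi2_2 null",
            RuntimeWarning,
        )
        m_hat = 2.0
        p0 = p0_bounds[1]
    p0 = float(np.clip(p0, *p0_bounds))

    # right-tail FDR against the fitted null survival
    order = np.argsort(x)[::-1]
    x_desc = x[order]
    surv0 = np.exp(-x_desc / m_hat)
    ranks = np.arange(1, n + 1)
    fdr = np.clip(p0 * n * surv0 / ranks, 0.0, 1.0)
    # q(x) = min FDR over thresholds <= x (suffix minimum in descending order),
    # which makes q monotone non-increasing in the statistic
    q_desc = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_desc
    logger.info(
        "mixture fit: p0=%.3f null_mean=%.4f (2L scale), L=%d, n=%d%s",
        p0, m_hat, L, n, " [theoretical fallback]" if fallback else "",
    )
    return MixtureFit(
        p0=p0, null_mean=m_hat, L=L, bin_width=bin_width,
        values=values, q=q, theoretical_fallback=fallback,
    )


@dataclass
class SignificanceMap:
    """q-values and the thresholded cross-bicoherence map.

    ``b2_significant`` carries the raw b2 at bins with ``q < threshold`` and
    0 elsewhere; bins outside the principal domain are never significant.
    """

    q: np.ndarray
    significant: np.ndarray
    b2_significant: np.ndarray
    threshold: float
    grid: "object"

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.significant))


def significance_map(
    bmap: BicoherenceMap, fit: MixtureFit, threshold: float = 0.05
) -> SignificanceMap:
    """Apply a fitted mixture to a bicoherence map at FDR level ``threshold``."""
    domain = bmap.grid.mask
    if fit.values.size != int(np.count_nonzero(domain)):
        raise ValueError("mixture fit does not match the map's principal domain")
    q = np.ones_like(bmap.b2)
    q[domain] = fit.q_of(bmap.b2[domain])
    sig = (q < threshold) & domain
    b2_sig = np.where(sig, bmap.b2, 0.0)
    return SignificanceMap(
        q=q, significant=sig, b2_significant=b2_sig, threshold=threshold, grid=bmap.grid
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n + 1)
    q_sorted = p[order] * n / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def qvalues(
    pvalues: np.ndarray,
    pfdr: bool = True,
    lambda_: float = 0.5,
    variance_tol: float = 1e-10,
    lambda_zero_fallback: bool = False,
) -> np.ndarray:
    """Storey-type (p)FDR q-values with a Benjamini-Hochberg fallback.

    The null proportion is estimated as ``#{p > lambda} / (n (1 - lambda))``;
    with ``pfdr`` the estimate conditions on at least one discovery (dividing
    by ``1 - (1 - p)^n``).  When the p-value sample variance falls below
    ``variance_tol`` (or ``lambda_zero_fallback`` is set) the conservative
    Benjamini-Hochberg procedure with ``pi0 = 1`` is used instead.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value sample")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if lambda_zero_fallback or float(np.var(p)) < variance_tol:
        return _benjamini_hochberg(p)
    pi0 = float(np.count_nonzero(p > lambda_)) / (n * (1.0 - lambda_))
    pi0 = min(max(pi0, 1.0 / n), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, n + 1)
    ps = p[order]
    q_sorted = pi0 * n * ps / ranks
    if pfdr:
        # pFDR conditions on at least one discovery; at p = 0 the numerator
        # vanishes, so the q-value is 0 in the limit — keep the denominator
        # positive there instead of producing 0/0
        denom = 1.0 - (1.0 - ps) ** n
        q_sorted = q_sorted / np.where(ps > 0, np.maximum(denom, 1e-300), 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
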