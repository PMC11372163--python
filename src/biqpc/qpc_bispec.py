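"""Ratio of bispectral quadratic phase coupling (R_BQPC).

R_BQPC measures how specific the detected quadratic phase coupling is to the
carrier bifrequency: the sum of significant cross-bicoherence inside a small
neighborhood of interest around ``(f1, f2)`` divided by the sum over *all*
significant bins in the sector containing that bifrequency.  Values near 1
mean the significant coupling is concentrated where the physics puts it;
values near 0 mean the map is dominated by incidental discoveries elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fdr import SignificanceMap
from .spectral import BifrequencyGrid, Sector

__all__ = ["Neighborhood", "BqpcResult", "neighborhood_bins", "r_bqpc", "qpc_ratio"]

_TOL = 1e-9


@dataclass
class Neighborhood:
    """Square neighborhood of interest ``G(f1, f2; d)`` clipped to its sector."""

    f1: float
    f2: float
    d: float
    mask: np.ndarray
    sector: Sector


def neighborhood_bins(
    f1: float, f2: float, d: float, grid: BifrequencyGrid
) -> Neighborhood:
    """Grid bins with centers in ``[f1-d, f1+d] x [f2-d, f2+d]``, within the sector.

    With ``d = 0`` the single nearest bin center is selected.  Bins falling in
    a different sector than ``(f1, f2)`` (a neighborhood straddling a sector
    boundary) are clipped away so that ``G`` stays inside ``Q(f1, f2)``.
    """
    if d < 0:
        raise ValueError("neighborhood half-width d must be >= 0")
    sector = grid.sector_of(f1, f2)
    in1 = np.abs(grid.freqs - f1) <= d + _TOL
    in2 = np.abs(grid.freqs - f2) <= d + _TOL
    if not in1.any():
        in1[grid.nearest_index(f1)] = True
    if not in2.any():
        in2[grid.nearest_index(f2)] = True
    mask = in1[:, None] & in2[None, :]
    mask &= grid.sectors == int(sector)
    mask &= grid.mask
    return Neighborhood(f1=f1, f2=f2, d=d, mask=mask, sector=sector)


@dataclass
class BqpcResult:
    """R_BQPC with its numerator/denominator sums.

    ``ratio`` is ``None`` when no bin in the sector is significant (the 0/0
    case, reported as undefined rather than 0).  ``flag`` is one of
    ``"ok"``, ``"undefined"``, ``"zero"``, ``"one"`` — the boundary ratios are
    flagged so that downstream aggregation can exclude them.
    """

    numerator: float
    denominator: float
    sector: Sector | None = None

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


def qpc_ratio(numerator: float, denominator: float) -> float | None:
    """The specificity ratio ``numerator / denominator``; ``None`` for 0/0."""
    if numerator < 0 or denominator < 0:
        raise ValueError("sums must be non-negative")
    if numerator > denominator + _TOL:
        raise ValueError("numerator exceeds denominator; G must be a subset of Q")
    if denominator == 0:
        return None
    return float(numerator / denominator)


def r_bqpc(sig: SignificanceMap, nbhd: Neighborhood) -> BqpcResult:
    """Evaluate R_BQPC of a significance map over a neighborhood of interest."""
    if sig.b2_significant.shape != nbhd.mask.shape:
        raise ValueError("significance map and neighborhood use different grids")
    grid = sig.grid
    sector_mask = (grid.sectors == int(nbhd.sector)) & grid.mask
    num = float(np.sum(sig.b2_significant[nbhd.mask]))
    den = float(np.sum(sig.b2_significant[sector_mask]))
    return BqpcResult(numerator=num, denominator=den, sector=nbhd.sector)
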