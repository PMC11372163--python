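"""Batch simulation study over carrier-frequency conditions and couplings.

Enumerates the admissible three-channel conditions from a carrier-frequency
set (unordered bifrequency pairs with ``F1 >= F2`` and every output carrier
``F3`` distinct from ``F1``, ``F2`` and ``F1 + F2``), runs the
cross-bicoherence arm (R_BQPC) and optionally the Granger arm (R_GQPC) plus
the SNR report for each condition, and aggregates per-coupling medians with
the boundary ratios (0, 1, undefined) excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import fdr as _fdr
from . import gc_spectral as _gc
from . import qpc_bispec as _qpc
from .signal_model import CARRIER_FREQS_HZ, ConditionSpec, empirical_snr, simulate_condition
from .spectral import SegmentPlan, cross_bicoherence, segment_series

__all__ = [
    "COUPLING_STRENGTHS",
    "StudyConfig",
    "ConditionGrid",
    "build_condition_grid",
    "run_condition",
    "run_study",
    "aggregate_medians",
]

logger = logging.getLogger(__name__)

#: The coupling strengths of the simulation study, from weak to strong.
COUPLING_STRENGTHS: tuple[float, ...] = (0.025, 0.050, 0.075, 0.150, 0.300, 0.750)


@dataclass(frozen=True)
class StudyConfig:
    """Analysis settings shared by every condition of a study run."""

    fs: float = 100.0
    epoch_duration: float = 5.0
    n_epochs: int = 128
    d: float = 0.5
    q_threshold: float = 0.05
    lag_max: int = 50
    nboots: int | None = None  # None: apply the sqrt(delta_f) * 1000 rule
    gc_enabled: bool = True
    seed: int = 0

    def plan(self) -> SegmentPlan:
        return SegmentPlan(fs=self.fs, segment_length=int(round(self.fs * self.epoch_duration)))


@dataclass
class ConditionGrid:
    """Enumerated (F1, F2, F3, W) conditions with per-condition seeds."""

    conditions: pd.DataFrame  # columns F1, F2, F3, W, seed

    def __len__(self) -> int:
        return len(self.conditions)


def build_condition_grid(
    freqs=CARRIER_FREQS_HZ,
    couplings=COUPLING_STRENGTHS,
    seed: int = 0,
) -> ConditionGrid:
    """Enumerate unordered bifrequency pairs with all admissible output carriers.

    Pairs are ordered ``F1 >= F2`` (so interactions above the Nyquist sum land
    in sector Q_II); ``F3`` runs over the remaining set values excluding
    ``F1``, ``F2`` and ``F1 + F2``.  Per-condition seeds derive from one
    master seed in enumeration order, so results do not depend on execution
    order or worker count.
    """
    freqs = sorted(float(f) for f in freqs)
    if len(freqs) < 3:
        raise ValueError("need at least 3 distinct frequencies")
    if len(set(np.round(freqs, 12))) != len(freqs):
        raise ValueError("duplicate frequencies in input")
    tol = 1e-9
    rows = []
    for a in range(len(freqs)):
        for b in range(a + 1, len(freqs)):
            f2, f1 = freqs[a], freqs[b]  # f1 >= f2
            excluded = (f1, f2, f1 + f2)
            for f3 in freqs:
                if any(abs(f3 - e) <= tol for e in excluded):
                    continue
                for w in couplings:
                    rows.append((f1, f2, f3, float(w)))
    if not rows:
        raise ValueError("empty condition grid")
    master = np.random.SeedSequence(seed)
    children = master.spawn(len(rows))
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    df = pd.DataFrame(rows, columns=["F1", "F2", "F3", "W"])
    df["seed"] = seeds
    n_per_w = len(df) // max(len(set(df["W"])), 1)
    logger.info("condition grid: %d conditions (%d per coupling value)", len(df), n_per_w)
    return ConditionGrid(conditions=df)


def run_condition(row, config: StudyConfig) -> dict:
    """Simulate one condition and evaluate both QPC indices and the SNR report.

    Returns a flat record; analysis errors in one arm are recorded in the
    ``error`` field and leave the remaining columns as NaN rather than
    aborting the study.
    """
    cond = ConditionSpec(
        F1=float(row["F1"]), F2=float(row["F2"]), F3=float(row["F3"]), W=float(row["W"]),
        fs=config.fs, epoch_duration=config.epoch_duration, n_epochs=config.n_epochs,
        seed=int(row["seed"]),
    )
    out: dict = {
        "F1": cond.F1, "F2": cond.F2, "F3": cond.F3, "W": cond.W, "seed": cond.seed,
        "sector": "", "R_BQPC": np.nan, "bqpc_flag": "", "R_GQPC": np.nan,
        "gqpc_flag": "", "theta": np.nan, "lag": -1,
        "snr1": np.nan, "snr2": np.nan, "snr3": np.nan,
        "snr1_expected": np.nan, "snr2_expected": np.nan, "snr3_expected": np.nan,
        "snr_efficiency": np.nan, "error": "",
    }
    errors = []
    series = simulate_condition(cond)
    plan = config.plan()

    try:
        spectra = segment_series(series, plan)
        bmap = cross_bicoherence(spectra, 0, 1, 2)
        fit = _fdr.fit_null_mixture(bmap.values_in_domain(), bmap.n_segments)
        sig = _fdr.significance_map(bmap, fit, threshold=config.q_threshold)
        nbhd = _qpc.neighborhood_bins(cond.F1, cond.F2, config.d, bmap.grid)
        res = _qpc.r_bqpc(sig, nbhd)
        out["sector"] = res.sector.name
        out["R_BQPC"] = np.nan if res.ratio is None else res.ratio
        out["bqpc_flag"] = res.flag
    except Exception as exc:  # recorded per row, row retained
        errors.append(f"bicoherence: {exc}")

    if config.gc_enabled:
        try:
            spec = _gc.bgcs(series, 0, 1, 2, plan, lag_max=config.lag_max)
            spec = _gc.bootstrap_significance(
                spec, nboots=config.nboots,
                seed=np.random.SeedSequence([cond.seed, 1]),
                q_threshold=config.q_threshold,
            )
            interval = _gc.interval_of_interest(
                cond.F1, cond.F2, config.d, plan.f_nyquist, plan.fs
            )
            gres = _gc.r_gqpc(spec, interval)
            out["R_GQPC"] = np.nan if gres.ratio is None else gres.ratio
            out["gqpc_flag"] = gres.flag
            out["theta"] = np.nan if spec.theta is None else spec.theta
            out["lag"] = spec.lag
        except Exception as exc:
            errors.append(f"granger: {exc}")

    try:
        snr = empirical_snr(series, cond)
        out.update(
            snr1=snr.empirical[0], snr2=snr.empirical[1], snr3=snr.empirical[2],
            snr1_expected=snr.expected[0], snr2_expected=snr.expected[1],
            snr3_expected=snr.expected[2], snr_efficiency=snr.efficiency,
        )
    except Exception as exc:
        errors.append(f"snr: {exc}")

    out["error"] = "; ".join(errors)
    return out


def run_study(grid: ConditionGrid, config: StudyConfig, n_jobs: int = 1) -> pd.DataFrame:
    """Run every condition of the grid; rows are independent jobs."""
    rows = list(grid.conditions.to_dict("records"))
    results = Parallel(n_jobs=n_jobs)(delayed(run_condition)(r, config) for r in rows)
    return pd.DataFrame(results)


def _usable(series: pd.Series, flags: pd.Series) -> pd.Series:
    return series[(flags == "ok") & series.notna()]


def aggregate_medians(table: pd.DataFrame) -> pd.DataFrame:
    """Per-coupling medians of R_BQPC, R_GQPC and the SNR efficiency.

    Boundary ratios (0, 1) and undefined results are excluded, mirroring the
    outlier handling of the condition study; groups left empty after the
    exclusion are omitted with a warning.
    """
    records = []
    for w, sub in table.groupby("W"):
        rec = {"W": float(w), "n_conditions": len(sub)}
        b = _usable(sub["R_BQPC"], sub["bqpc_flag"])
        if len(b):
            rec["median_R_BQPC"] = float(b.median())
            rec["n_BQPC"] = len(b)
        else:
            logger.warning("no usable R_BQPC values at W=%g; group omitted", w)
        if "R_GQPC" in sub:
            g = _usable(sub["R_GQPC"], sub["gqpc_flag"])
            if len(g):
                rec["median_R_GQPC"] = float(g.median())
                rec["n_GQPC"] = len(g)
        if sub["snr_efficiency"].notna().any():
            rec["median_snr_efficiency"] = float(sub["snr_efficiency"].median())
        records.append(rec)
    return pd.DataFrame(records).sort_values("W").reset_index(drop=True)
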