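"""Plain-text (TSV) readers and writers for the package's result types.

Everything round-trips through diff-able delimited text: epoched series as
``epoch, sample, X1, X2, X3`` tables with a key-value sidecar recording the
generating condition, and one long-format table per result type.  Floats are
written with 17 significant digits so that read(write(x)) == x exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fdr import SignificanceMap
from .gc_spectral import GcSpectrum
from .qpc_bispec import BqpcResult
from .signal_model import EpochedSeries
from .spectral import BicoherenceMap, Sector

__all__ = [
    "write_epoched_tsv",
    "read_epoched_tsv",
    "write_sidecar",
    "read_sidecar",
    "write_bicoherence_tsv",
    "read_bicoherence_tsv",
    "write_significance_tsv",
    "write_gc_spectrum_tsv",
    "write_bqpc_row",
]

_FLOAT_FMT = "%.17g"


def write_epoched_tsv(series: EpochedSeries, path: str | Path) -> None:
    n_ch, n_ep, n_s = series.data.shape
    epoch = np.repeat(np.arange(n_ep), n_s)
    sample = np.tile(np.arange(n_s), n_ep)
    cols = {"epoch": epoch, "sample": sample}
    for c, name in enumerate(series.channel_names):
        cols[name] = series.data[c].ravel()
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_epoched_tsv(
    path: str | Path, fs: float, channels: tuple[str, ...] = ("X1", "X2", "X3")
) -> EpochedSeries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "epoch" not in df.columns:
        raise ValueError("missing 'epoch' column")
    missing = [c for c in channels if c not in df.columns]
    if missing:
        raise ValueError(f"missing channel column(s): {', '.join(missing)}")
    counts = df.groupby("epoch").size()
    if counts.nunique() != 1:
        raise ValueError("ragged epochs: unequal epoch lengths")
    n_ep = counts.size
    n_s = int(counts.iloc[0])
    data = np.stack([df[c].to_numpy().reshape(n_ep, n_s) for c in channels])
    return EpochedSeries(data=data, fs=fs, channel_names=tuple(channels))


def write_sidecar(path: str | Path, **params) -> None:
    lines = [f"{k}\t{params[k]!r}" for k in sorted(params)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict:
    import ast

    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, raw = line.partition("\t")
        out[key] = ast.literal_eval(raw)
    return out


def _grid_long_frame(bmap: BicoherenceMap) -> pd.DataFrame:
    grid = bmap.grid
    f1, f2 = np.meshgrid(grid.freqs, grid.freqs, indexing="ij")
    return pd.DataFrame(
        {
            "f1": f1.ravel(),
            "f2": f2.ravel(),
            "sector": [Sector(s).name for s in grid.sectors.ravel()],
            "b2": bmap.b2.ravel(),
        }
    )


def write_bicoherence_tsv(bmap: BicoherenceMap, path: str | Path) -> None:
    _grid_long_frame(bmap).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_bicoherence_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_significance_tsv(sig: SignificanceMap, path: str | Path) -> None:
    grid = sig.grid
    f1, f2 = np.meshgrid(grid.freqs, grid.freqs, indexing="ij")
    pd.DataFrame(
        {
            "f1": f1.ravel(),
            "f2": f2.ravel(),
            "b2": sig.b2_significant.ravel(),
            "q": sig.q.ravel(),
            "significant": sig.significant.ravel().astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_gc_spectrum_tsv(spec: GcSpectrum, path: str | Path) -> None:
    n = len(spec.freqs)
    nanfill = np.full(n, np.nan)
    pd.DataFrame(
        {
            "f": spec.freqs,
            "BGCS_median": spec.bgcs,
            "p": spec.p if spec.p is not None else nanfill,
            "q": spec.q if spec.q is not None else nanfill,
            "significant": (
                spec.significant if spec.significant is not None else nanfill
            ),
            "theta": np.full(n, np.nan if spec.theta is None else spec.theta),
            "lag": np.full(n, spec.lag),
            "nboots": np.full(n, -1 if spec.nboots is None else spec.nboots),
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_bqpc_row(
    result: BqpcResult, path: str | Path, F1: float, F2: float, F3: float, W: float, d: float
) -> None:
    ratio = result.ratio
    pd.DataFrame(
        [
            {
                "F1": F1, "F2": F2, "F3": F3, "W": W, "d": d,
                "sector": result.sector.name if result.sector is not None else "",
                "num": result.numerator, "den": result.denominator,
                "R_BQPC": np.nan if ratio is None else ratio, "flag": result.flag,
            }
        ]
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
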