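"""Tab-separated interchange formats used by every pipeline stage.

All tables are plain TSV with headers; floats are written with 10
significant digits so repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import HemoglobinSeries

FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _channel_columns(n: int) -> list[str]:
    return [f"ch{i:02d}" for i in range(1, n + 1)]


def write_series(series: HemoglobinSeries, directory: str | Path, subject_id: str) -> dict[str, Path]:
    """One wide TSV per chromophore: a time column plus one column per channel."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = series.t0 + np.arange(series.n_samples) / series.sampling_rate
    paths = {}
    for chrom in ("HbO", "HbR"):
        data = series.chromophore(chrom)
        df = pd.DataFrame(data.T, columns=_channel_columns(series.n_channels))
        df.insert(0, "time", t)
        path = directory / f"{subject_id}_{chrom}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
        paths[chrom] = path
    return paths


def read_series(directory: str | Path, subject_id: str) -> HemoglobinSeries:
    directory = Path(directory)
    frames = {}
    for chrom in ("HbO", "HbR"):
        path = directory / f"{subject_id}_{chrom}.tsv"
        frames[chrom] = pd.read_csv(path, sep="\t")
    t = frames["HbO"]["time"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"series for {subject_id} too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    channels = [c for c in frames["HbO"].columns if c != "time"]
    return HemoglobinSeries(
        hbo=frames["HbO"][channels].to_numpy().T,
        hbr=frames["HbR"][channels].to_numpy().T,
        sampling_rate=fs,
        t0=float(t[0]),
    )


def write_matrix(mat: np.ndarray, path: str | Path) -> Path:
    """A square matrix as a headerless TSV grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, mat, delimiter="\t", fmt=FLOAT_FMT)
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t")
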