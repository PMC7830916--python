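"""In-memory containers for multi-channel optical and hemoglobin time series.

All arrays are channel-major: shape ``(n_channels, n_samples)`` for
hemoglobin / per-wavelength optical density, and
``(n_channels, n_samples, n_wavelengths)`` for raw intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Laser wavelengths of the emulated continuous-wave instrument, nm.
WAVELENGTHS_NM = (780.0, 805.0, 830.0)


@dataclass
class RawIntensitySeries:
    """Detected light intensity, arbitrary units, strictly positive."""

    data: np.ndarray  # (n_channels, n_samples, 3)
    sampling_rate: float
    wavelengths_nm: tuple[float, ...] = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.wavelengths_nm):
            raise ValueError("intensity array must be (channels, samples, wavelengths)")
        if not np.all(self.data > 0):
            raise ValueError("raw intensities must be strictly positive")


@dataclass
class OpticalDensitySeries:
    """Optical-density change relative to the temporal mean, dimensionless."""

    data: np.ndarray  # (n_channels, n_samples, 3)
    sampling_rate: float
    wavelengths_nm: tuple[float, ...] = WAVELENGTHS_NM


@dataclass
class HemoglobinSeries:
    """Oxy-/deoxy-hemoglobin concentration change (µM), channel × time."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR must have identical shape")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def chromophore(self, name: str) -> np.ndarray:
        if name == "HbO":
            return self.hbo
        if name == "HbR":
            return self.hbr
        raise KeyError(f"unknown chromophore {name!r}")

    def copy(self) -> "HemoglobinSeries":
        return replace(self, hbo=self.hbo.copy(), hbr=self.hbr.copy())


@dataclass
class ArtifactMask:
    """Boolean channel × time mask; True marks motion-contaminated samples."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def channel_fraction_percent(self) -> np.ndarray:
        """Masked percentage per channel, in [0, 100]."""
        return self.mask.mean(axis=1) * 100.0

    def union(self, other: "ArtifactMask") -> "ArtifactMask":
        return ArtifactMask(self.mask | other.mask)
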