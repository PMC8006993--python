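"""Time-series and image-stack containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError
from .optics import OpticalGeometry

__all__ = [
    "PhaseTrace",
    "ElongationTrace",
    "RERTrace",
    "SpeckleField",
    "FrameStack",
]


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {a.shape}")
    return a


@dataclass
class PhaseTrace:
    """Interference phase vs time, wrapped to (-pi, pi] or unwrapped.

    ``quality`` carries demodulation diagnostics (modulation depth, residual,
    degeneracy flag) when the trace was estimated from frames.
    """

    times_s: np.ndarray
    phi_rad: np.ndarray
    wrapped: bool
    quality: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = _as_1d(self.times_s, "times_s")
        self.phi_rad = _as_1d(self.phi_rad, "phi_rad")
        if len(self.times_s) != len(self.phi_rad):
            raise InputError(
                f"times_s and phi_rad length mismatch: "
                f"{len(self.times_s)} vs {len(self.phi_rad)}"
            )

    def __len__(self) -> int:
        return len(self.phi_rad)


@dataclass
class ElongationTrace:
    """Cumulative root elongation in nm, zero at the first sample."""

    times_s: np.ndarray
    x_nm: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = _as_1d(self.times_s, "times_s")
        self.x_nm = _as_1d(self.x_nm, "x_nm")
        if len(self.times_s) != len(self.x_nm):
            raise InputError("times_s and x_nm length mismatch")

    def __len__(self) -> int:
        return len(self.x_nm)


@dataclass
class RERTrace:
    """Normalized root elongation rate in nm s^-1 mm^-1.

    ``times_s`` are the left edges of the differencing intervals, so a trace
    derived from an elongation series of N samples has N - 1 rates.
    """

    times_s: np.ndarray
    rate: np.ndarray
    group_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.times_s = _as_1d(self.times_s, "times_s")
        self.rate = _as_1d(self.rate, "rate")
        if len(self.times_s) != len(self.rate):
            raise InputError("times_s and rate length mismatch")

    def __len__(self) -> int:
        return len(self.rate)


@dataclass
class SpeckleField:
    """Complex scattered field on a pixel grid (fully developed speckle).

    The marginal phase is uniform on [-pi, pi] and the intensity |A|^2 is
    negative-exponential with unit contrast in the fully developed limit.
    """

    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=complex)
        if self.amplitude.ndim != 2:
            raise InputError("speckle amplitude must be a 2-D grid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.amplitude)


@dataclass
class FrameStack:
    """Time-ordered stack of interference intensity frames.

    ``frames`` has shape (n_frames, height, width) with non-negative values.
    """

    frames: np.ndarray
    times_s: np.ndarray
    geom: OpticalGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_s = _as_1d(self.times_s, "times_s")
        if self.frames.ndim != 3:
            raise InputError(f"frames must be 3-D (t, y, x), got shape {self.frames.shape}")
        if len(self.times_s) != self.frames.shape[0]:
            raise InputError(
                f"frame count {self.frames.shape[0]} does not match "
                f"{len(self.times_s)} time stamps"
            )
        if np.any(self.frames < 0):
            raise InputError("intensity frames must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]
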