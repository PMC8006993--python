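"""Scalar two-beam interference model linking root elongation to speckle phase.

Two laser beams illuminate a root at points separated by the gauge length.
When the segment between the points elongates by ``dx`` the optical path
between the two scattered speckle fields changes by ``dx * sin(theta)``,
where ``theta`` is the angle between the illuminating beams and the
observing direction, and the interference phase changes by

    dphi = 2 * pi * dx * sin(theta) / lambda

with ``lambda`` the laser wavelength.  Everything downstream of the camera
reduces to this linear relation and its inverse.

Internal unit conventions: elongation in nm, phase in rad, time in s,
gauge length in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["OpticalGeometry", "elongation_to_phase", "phase_to_elongation"]


@dataclass(frozen=True)
class OpticalGeometry:
    """Bench geometry and acquisition timing of the interferometer.

    Parameters
    ----------
    wavelength_nm
        Laser wavelength in nm.  Default 633 (He-Ne).
    sin_theta
        Sine of the angle between the illuminating beams and the observing
        direction, in (0, 1].  Default 1, i.e. theta = 90 degrees, so one
        interference fringe corresponds to exactly one wavelength of
        elongation.
    gauge_length_mm
        Separation of the two illumination points in mm; the monitored root
        segment. Default 3.
    dt_s
        Frame sampling interval in s.  Default 0.5.
    """

    wavelength_nm: float = 633.0
    sin_theta: float = 1.0
    gauge_length_mm: float = 3.0
    dt_s: float = 0.5

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise GeometryError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if not 0 < self.sin_theta <= 1:
            raise GeometryError(f"sin_theta must be in (0, 1], got {self.sin_theta}")
        if not self.gauge_length_mm > 0:
            raise GeometryError(
                f"gauge_length_mm must be > 0, got {self.gauge_length_mm}"
            )
        if not self.dt_s > 0:
            raise GeometryError(f"dt_s must be > 0, got {self.dt_s}")

    @property
    def fringe_nm(self) -> float:
        """Elongation corresponding to one full 2*pi fringe, lambda/sin(theta)."""
        return self.wavelength_nm / self.sin_theta

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "sin_theta": self.sin_theta,
            "gauge_length_mm": self.gauge_length_mm,
            "dt_s": self.dt_s,
        }


def elongation_to_phase(dx_nm, geom: OpticalGeometry):
    """Interference phase change (rad) produced by an elongation ``dx_nm`` (nm).

    Linear and sign-preserving; accepts scalars or arrays.
    """
    return 2.0 * np.pi * np.asarray(dx_nm, dtype=float) * geom.sin_theta / geom.wavelength_nm


def phase_to_elongation(dphi_rad, geom: OpticalGeometry):
    """Elongation (nm) producing a phase change ``dphi_rad`` (rad).

    Exact inverse of :func:`elongation_to_phase` for the same geometry.
    """
    return np.asarray(dphi_rad, dtype=float) * geom.wavelength_nm / (2.0 * np.pi * geom.sin_theta)
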