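"""Phase-to-elongation conversion and the normalized root elongation rate.

The interference phase recovered from the speckle frames is converted to
cumulative elongation through the scalar optics relation, then differenced
into a rate normalized by the gauge length:

    rate_k = (x_{k+1} - x_k) / (dt_s * gauge_length_mm)   [nm s^-1 mm^-1]

Left-edge (forward) differencing with timestamps at interval left edges;
no smoothing is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError
from .optics import OpticalGeometry, phase_to_elongation
from .phase_recovery import estimate_phase_trace, unwrap_phase
from .traces import ElongationTrace, FrameStack, PhaseTrace, RERTrace

__all__ = [
    "phase_to_elongation_trace",
    "elongation_to_rer",
    "recover_rer_from_frames",
    "RecoveryResult",
]


def phase_to_elongation_trace(
    trace: PhaseTrace, geom: OpticalGeometry
) -> ElongationTrace:
    """Convert an unwrapped phase trace into cumulative elongation (nm).

    The arbitrary global phase offset is removed by referencing every sample
    to the first, so the elongation starts at exactly zero.
    """
    if trace.wrapped:
        raise InputError("phase trace must be unwrapped before conversion")
    x = phase_to_elongation(trace.phi_rad - trace.phi_rad[0], geom)
    return ElongationTrace(times_s=trace.times_s.copy(), x_nm=x)


def elongation_to_rer(
    elong: ElongationTrace,
    geom: OpticalGeometry,
    group_label: Optional[str] = None,
) -> RERTrace:
    """Differentiate elongation into the normalized rate (nm s^-1 mm^-1)."""
    if len(elong) < 2:
        raise InputError("need at least 2 elongation samples to form a rate")
    dt = np.diff(elong.times_s)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise InputError("elongation trace must be uniformly sampled")
    rate = np.diff(elong.x_nm) / (geom.dt_s * geom.gauge_length_mm)
    return RERTrace(times_s=elong.times_s[:-1].copy(), rate=rate, group_label=group_label)


@dataclass
class RecoveryResult:
    """Full output of the frames-to-rate pipeline with per-stage diagnostics."""

    rer: RERTrace
    elongation: ElongationTrace
    phase: PhaseTrace  # unwrapped, sign-resolved
    quality: dict


def recover_rer_from_frames(
    stack: FrameStack,
    geom: Optional[OpticalGeometry] = None,
    expected_drift_sign: Optional[float] = None,
    mask_quantile: float = 0.2,
    group_label: Optional[str] = None,
) -> RecoveryResult:
    """Demodulate a frame stack all the way to a rate trace.

    Composition of phase estimation, temporal unwrapping, the optics
    inversion and rate differencing.  The recovered phase sign is ambiguous;
    if ``expected_drift_sign`` (+1 or -1) is given, the unwrapped trace is
    flipped so its net drift matches that direction, otherwise the sign is
    left as estimated.
    """
    if geom is None:
        geom = stack.geom
    wrapped = estimate_phase_trace(stack, mask_quantile=mask_quantile)
    phase = unwrap_phase(wrapped)
    if expected_drift_sign is not None:
        drift = phase.phi_rad[-1] - phase.phi_rad[0]
        if drift * expected_drift_sign < 0:
            phase = PhaseTrace(
                times_s=phase.times_s,
                phi_rad=-phase.phi_rad,
                wrapped=False,
                quality={**phase.quality, "sign_flipped": True},
            )
    elong = phase_to_elongation_trace(phase, geom)
    rer = elongation_to_rer(elong, geom, group_label=group_label)
    quality = {
        "demodulation": dict(wrapped.quality),
        "expected_drift_sign": expected_drift_sign,
        "n_frames": stack.n_frames,
        "geometry": geom.to_dict(),
    }
    return RecoveryResult(rer=rer, elongation=elong, phase=phase, quality=quality)
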