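"""Synthetic data generation: growth traces and speckle interference frames.

Two layers are simulated:

1. Root-growth kinematics.  A root elongation rate (RER) trace is modeled as
   a sinusoidal oscillation (default period 10 s) plus white Gaussian noise,
   with the oscillation carrying a configurable fraction of the total
   variance.  The packaged ``wet`` and ``dry`` presets are calibrated so the
   pooled moments match the reference groups of well-watered and
   water-stressed pine seedlings (wet: mean -0.10, sd 3.41; dry:
   mean -23.44, sd 52.63, all in nm s^-1 mm^-1).

2. Speckle optics.  Two fully developed speckle fields (complex circular
   Gaussian) are superposed with a time-varying relative phase driven by the
   elongation trace, giving the intensity frame stack a camera would record.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage
import yaml

from .errors import InputError
from .optics import OpticalGeometry, elongation_to_phase
from .traces import ElongationTrace, FrameStack, RERTrace, SpeckleField

__all__ = [
    "GrowthPreset",
    "load_presets",
    "generate_rer_trace",
    "rer_to_elongation",
    "generate_speckle_field",
    "render_frame_stack",
    "generate_group_dataset",
    "GroupDataset",
]


@dataclass(frozen=True)
class GrowthPreset:
    """Parameters of the oscillation-plus-noise RER model.

    The generated rate is

        r(t) = mu + A sin(2 pi t / period_s + phi0) + sigma_n eps(t)

    with A = sigma_total * sqrt(2 * osc_fraction) and
    sigma_n = sigma_total * sqrt(1 - osc_fraction), so that the total
    variance A^2/2 + sigma_n^2 equals sigma_total^2 for any split.
    phi0 is drawn uniformly per trace; eps is iid standard normal.
    """

    label: str
    mu: float
    sigma_total: float
    period_s: float = 10.0
    osc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_total < 0:
            raise InputError(f"sigma_total must be >= 0, got {self.sigma_total}")
        if self.period_s <= 0:
            raise InputError(f"period_s must be > 0, got {self.period_s}")
        if not 0 <= self.osc_fraction <= 1:
            raise InputError(f"osc_fraction must be in [0, 1], got {self.osc_fraction}")

    @property
    def osc_amplitude(self) -> float:
        """Sinusoid amplitude A carrying osc_fraction of the variance."""
        return self.sigma_total * np.sqrt(2.0 * self.osc_fraction)

    @property
    def noise_sd(self) -> float:
        """White-noise standard deviation carrying the rest of the variance."""
        return self.sigma_total * np.sqrt(1.0 - self.osc_fraction)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mu": self.mu,
            "sigma_total": self.sigma_total,
            "period_s": self.period_s,
            "osc_fraction": self.osc_fraction,
        }


def load_presets() -> dict[str, GrowthPreset]:
    """Load the packaged calibration presets (``wet`` and ``dry``)."""
    text = (
        importlib.resources.files("rootspeckle").joinpath("data/presets.yaml").read_text()
    )
    raw = yaml.safe_load(text)["presets"]
    return {name: GrowthPreset(**params) for name, params in raw.items()}


def generate_rer_trace(
    preset: GrowthPreset,
    duration_s: float,
    geom: OpticalGeometry,
    seed,
) -> RERTrace:
    """Generate one RER trace sampled at ``geom.dt_s`` for ``duration_s`` seconds.

    The trace has ``round(duration_s / dt_s)`` samples at times k * dt_s.
    Reproducible for a fixed seed; the per-trace oscillation phase offset is
    part of the seeded randomness.
    """
    if duration_s < 2 * geom.dt_s:
        raise InputError(
            f"duration_s must cover at least two samples ({2 * geom.dt_s} s), "
            f"got {duration_s}"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / geom.dt_s))
    t = np.arange(n) * geom.dt_s
    phi0 = rng.uniform(-np.pi, np.pi)
    rate = (
        preset.mu
        + preset.osc_amplitude * np.sin(2.0 * np.pi * t / preset.period_s + phi0)
        + preset.noise_sd * rng.standard_normal(n)
    )
    return RERTrace(times_s=t, rate=rate, group_label=preset.label)


def rer_to_elongation(trace: RERTrace, geom: OpticalGeometry) -> ElongationTrace:
    """Integrate a rate trace into cumulative elongation (nm), starting at 0.

    Each rate sample r_k contributes r_k * gauge_length_mm * dt_s nm over its
    interval, so the elongation series has one more sample than the rate
    series; this is the exact inverse of the left-edge differencing used to
    compute RER from elongation.
    """
    increments = trace.rate * geom.gauge_length_mm * geom.dt_s
    x = np.concatenate([[0.0], np.cumsum(increments)])
    t = np.concatenate([trace.times_s, [trace.times_s[-1] + geom.dt_s]])
    return ElongationTrace(times_s=t, x_nm=x)


def generate_speckle_field(
    grid_shape: tuple[int, int],
    speckle_size_px: float = 1.0,
    seed=None,
) -> SpeckleField:
    """Draw a fully developed speckle field on a pixel grid.

    Each pixel of the underlying field is iid complex circular Gaussian; for
    ``speckle_size_px > 1`` the field is low-pass filtered with a Gaussian of
    that correlation length and renormalized to unit mean intensity.  The
    filtered field remains complex Gaussian, so the marginal phase stays
    uniform on [-pi, pi] and the pointwise intensity contrast stays ~1.
    """
    h, w = grid_shape
    if speckle_size_px < 1:
        raise InputError(f"speckle_size_px must be >= 1, got {speckle_size_px}")
    if min(h, w) < 8 * speckle_size_px:
        raise InputError(
            f"grid {grid_shape} too small for speckle size {speckle_size_px} px; "
            "need at least 8 speckles across each dimension"
        )
    rng = np.random.default_rng(seed)
    field = (rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))) / np.sqrt(2)
    if speckle_size_px > 1:
        sigma = speckle_size_px / 2.0
        field = scipy.ndimage.gaussian_filter(field.real, sigma, mode="wrap") + 1j * (
            scipy.ndimage.gaussian_filter(field.imag, sigma, mode="wrap")
        )
        field /= np.sqrt(np.mean(np.abs(field) ** 2))
    return SpeckleField(amplitude=field)


def render_frame_stack(
    elong: ElongationTrace,
    field_a: SpeckleField,
    field_b: SpeckleField,
    geom: OpticalGeometry,
    noise_sd: float = 0.01,
    seed=None,
) -> FrameStack:
    """Render the interference intensity stack for an elongation trajectory.

    Frame k is ``|A_a + A_b exp(i dphi_k)|^2`` per pixel, where dphi_k is the
    interference phase of the elongation at sample k, plus additive Gaussian
    detector noise with standard deviation ``noise_sd`` times the mean clean
    intensity.  Intensities are clipped at zero.
    """
    if field_a.grid_shape != field_b.grid_shape:
        raise InputError(
            f"speckle fields must share a grid shape: "
            f"{field_a.grid_shape} vs {field_b.grid_shape}"
        )
    dphi = elongation_to_phase(elong.x_nm, geom)  # (N,)
    a = field_a.amplitude[None, :, :]
    b = field_b.amplitude[None, :, :]
    rot = np.exp(1j * dphi)[:, None, None]
    frames = np.abs(a + b * rot) ** 2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + noise_sd * frames.mean() * rng.standard_normal(frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return FrameStack(frames=frames, times_s=elong.times_s.copy(), geom=geom)


@dataclass
class GroupDataset:
    """A group of independently generated traces plus a generation manifest."""

    traces: list
    manifest: dict
    stacks: Optional[list] = None


def generate_group_dataset(
    preset: GrowthPreset,
    n_traces: int,
    duration_s: float,
    geom: OpticalGeometry,
    seed: int,
    with_frames: bool = False,
    grid_shape: tuple[int, int] = (64, 64),
    speckle_size_px: float = 2.0,
    noise_sd: float = 0.01,
) -> GroupDataset:
    """Generate ``n_traces`` independent RER traces (optionally with frames).

    Per-trace seeds are derived deterministically from the group seed, and
    the manifest records the preset, geometry and every derived seed so a
    run can be reproduced exactly.
    """
    if n_traces < 1:
        raise InputError(f"n_traces must be >= 1, got {n_traces}")
    traces = []
    stacks = [] if with_frames else None
    trace_seeds = []
    for i in range(n_traces):
        trace_seed = [int(seed), i]
        trace_seeds.append(trace_seed)
        trace = generate_rer_trace(preset, duration_s, geom, seed=trace_seed)
        traces.append(trace)
        if with_frames:
            elong = rer_to_elongation(trace, geom)
            fa = generate_speckle_field(grid_shape, speckle_size_px, seed=[int(seed), i, 1])
            fb = generate_speckle_field(grid_shape, speckle_size_px, seed=[int(seed), i, 2])
            stacks.append(
                render_frame_stack(
                    elong, fa, fb, geom, noise_sd=noise_sd, seed=[int(seed), i, 3]
                )
            )
    manifest = {
        "preset": preset.to_dict(),
        "geometry": geom.to_dict(),
        "n_traces": n_traces,
        "duration_s": duration_s,
        "seed": int(seed),
        "trace_seeds": trace_seeds,
        "with_frames": with_frames,
    }
    if with_frames:
        manifest["frames"] = {
            "grid_shape": list(grid_shape),
            "speckle_size_px": speckle_size_px,
            "noise_sd": noise_sd,
        }
    return GroupDataset(traces=traces, manifest=manifest, stacks=stacks)
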