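"""Temporal phase demodulation of speckle interference frame stacks.

Every pixel of a two-beam speckle interferogram follows

    I_k(p) = a(p) + b(p) * cos(psi(p) + dphi_k)

where psi(p) is the static random speckle phase at pixel p (uniform over
the field) and dphi_k is the object phase common to all pixels at frame k.
Because psi(p) is spread uniformly over [-pi, pi], the ensemble of pixel
time series jointly carries both quadratures of dphi: after per-pixel mean
removal the stack is (up to noise) a rank-2 matrix whose two temporal
components are linear mixtures of cos(dphi_k) and sin(dphi_k).

The estimator here proceeds in two stages:

1. Spectral initialization: extract the two leading joint temporal
   components (eigenvectors of the frame-by-frame Gram matrix), whiten
   their amplitude ellipse to a circle, and take the two-argument
   arctangent of the whitened pair as a first phase estimate.
2. Alternating least-squares refinement on the explicit per-pixel cosine
   model: given the phase, fit (a, b cos psi, b sin psi) per pixel by
   linear least squares; given the pixel coefficients, re-estimate each
   frame's phase from the 2x2 normal equations over all pixels.  A few
   iterations converge to machine-level consistency on clean data.

The recovered trace is defined only up to a global offset and a global
sign (the bench geometry fixes the physical sign; simulations resolve it
against ground truth, production against a configured drift direction).
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .traces import FrameStack, PhaseTrace

__all__ = [
    "estimate_phase_trace",
    "unwrap_phase",
    "wrap_phase",
    "align_to_reference",
]

# Temporal variance (relative to mean intensity) below which a stack is
# considered to carry no phase modulation at all.
_DEGENERATE_REL_VAR = 1e-12


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values to the interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = np.mod(-phi + np.pi, 2.0 * np.pi)
    return -(wrapped - np.pi)


def _init_phase_svd(X: np.ndarray) -> np.ndarray:
    """Initial phase estimate from the two leading temporal components.

    X is the mean-removed (n_frames, n_pixels) data matrix.  The Gram matrix
    X X^T is cheap for typical stacks (hundreds of frames) regardless of
    pixel count.
    """
    gram = X @ X.T
    evals, evecs = np.linalg.eigh(gram)
    # top-2 components; eigh returns ascending order
    scores = evecs[:, -2:] * np.sqrt(np.maximum(evals[-2:], 0.0))
    # whiten the score ellipse to a circle
    cov = scores.T @ scores / scores.shape[0]
    ev, U = np.linalg.eigh(cov)
    ev = np.maximum(ev, 1e-30)
    white = scores @ U / np.sqrt(ev)
    return np.arctan2(white[:, 1], white[:, 0])


def estimate_phase_trace(
    stack: FrameStack,
    mask_quantile: float = 0.2,
    n_refine: int = 200,
    refine_tol: float = 1e-9,
) -> PhaseTrace:
    """Estimate the wrapped object phase dphi_k from an intensity stack.

    Parameters
    ----------
    stack
        Interference frame stack (>= 3 frames).
    mask_quantile
        Pixels whose temporal modulation amplitude falls in this bottom
        quantile are excluded from demodulation; dark speckles contribute
        mostly noise.
    n_refine
        Maximum alternating least-squares refinement sweeps after the
        spectral initialization.  Convergence is linear, and slow when the
        phase excursion covers only part of a fringe, so the ceiling is
        generous; iteration stops early once the phase update falls below
        ``refine_tol``.
    refine_tol
        Early-stopping threshold on the maximum absolute phase change (rad)
        between successive refinement sweeps.

    Returns
    -------
    PhaseTrace
        Wrapped trace, defined up to a global offset and sign.  ``quality``
        reports the mean relative modulation depth, the relative residual of
        the cosine-model fit, the masked-pixel fraction, and a
        ``degenerate`` flag set when the stack shows no temporal modulation
        (in which case the phase is all zeros rather than an exception).
    """
    if stack.n_frames < 3:
        raise InputError(f"need at least 3 frames, got {stack.n_frames}")
    n = stack.n_frames
    X = stack.frames.reshape(n, -1)
    pixel_mean = X.mean(axis=0)
    Xc = X - pixel_mean

    mean_intensity = float(pixel_mean.mean())
    rel_var = float(np.mean(Xc**2)) / max(mean_intensity**2, 1e-300)
    if rel_var < _DEGENERATE_REL_VAR:
        return PhaseTrace(
            times_s=stack.times_s.copy(),
            phi_rad=np.zeros(n),
            wrapped=True,
            quality={
                "degenerate": True,
                "modulation_depth": 0.0,
                "relative_residual": 0.0,
                "masked_fraction": 0.0,
            },
        )

    # keep the brighter-modulation pixels
    mod_amp = Xc.std(axis=0)
    threshold = np.quantile(mod_amp, mask_quantile)
    keep = mod_amp > threshold
    if keep.sum() < 8:  # tiny stacks: keep everything
        keep = np.ones_like(keep, dtype=bool)
    Xk = Xc[:, keep]

    phi = _init_phase_svd(Xk)

    # alternating least-squares refinement of I = a + c cos(phi) + d sin(phi)
    Xs = X[:, keep]
    design = None
    coef = None
    for _ in range(max(n_refine, 1)):
        design = np.column_stack([np.ones(n), np.cos(phi), np.sin(phi)])
        # normal equations of the 3-parameter per-pixel fit (well conditioned:
        # the columns are 1, cos, sin of a spread of phases)
        gram3 = design.T @ design
        coef = np.linalg.solve(gram3, design.T @ Xs)
        a, c, d = coef
        # per-frame 2x2 normal equations over pixels
        Scc, Sdd, Scd = np.dot(c, c), np.dot(d, d), np.dot(c, d)
        rhs_c = Xs @ c - np.dot(a, c)
        rhs_d = Xs @ d - np.dot(a, d)
        det = Scc * Sdd - Scd**2
        if det <= 0:
            break
        u = (Sdd * rhs_c - Scd * rhs_d) / det
        v = (Scc * rhs_d - Scd * rhs_c) / det
        phi_new = np.arctan2(v, u)
        step = np.max(np.abs(wrap_phase(phi_new - phi)))
        phi = phi_new
        if step < refine_tol:
            break
    resid = Xs - design @ coef
    resid_rms = float(np.sqrt(np.mean(resid**2)))

    modulation = float(np.mean(np.hypot(c, d)) / max(mean_intensity, 1e-300))
    quality = {
        "degenerate": False,
        "modulation_depth": modulation,
        "relative_residual": resid_rms / max(mean_intensity, 1e-300),
        "masked_fraction": float(1.0 - keep.mean()),
    }
    return PhaseTrace(
        times_s=stack.times_s.copy(),
        phi_rad=wrap_phase(phi),
        wrapped=True,
        quality=quality,
    )


def unwrap_phase(trace: PhaseTrace) -> PhaseTrace:
    """Temporal phase unwrapping of a wrapped trace.

    Whenever the difference between successive samples exceeds pi in
    magnitude, the appropriate multiple of 2*pi is added to restore
    continuity; the first sample is unchanged.  Valid under the physical
    assumption that true per-sample phase steps stay below pi (violations
    are undetectable from the wrapped data and silently aliased).
    """
    if not trace.wrapped:
        raise InputError("trace is already unwrapped")
    return PhaseTrace(
        times_s=trace.times_s.copy(),
        phi_rad=np.unwrap(trace.phi_rad),
        wrapped=False,
        quality=dict(trace.quality),
    )


def align_to_reference(trace: PhaseTrace, reference: PhaseTrace) -> PhaseTrace:
    """Resolve the global sign and offset of a trace against a reference.

    Returns ``s * trace + c`` with sign s in {+1, -1} and offset c chosen to
    minimize the sum of squared deviations from the reference.
    """
    if len(trace) != len(reference):
        raise InputError(
            f"length mismatch: trace {len(trace)} vs reference {len(reference)}"
        )
    best = None
    for s in (1.0, -1.0):
        c = float(np.mean(reference.phi_rad - s * trace.phi_rad))
        aligned = s * trace.phi_rad + c
        sse = float(np.sum((aligned - reference.phi_rad) ** 2))
        if best is None or sse < best[0]:
            best = (sse, aligned, s, c)
    _, aligned, s, c = best
    quality = dict(trace.quality)
    quality.update({"align_sign": s, "align_offset": c})
    return PhaseTrace(
        times_s=trace.times_s.copy(),
        phi_rad=aligned,
        wrapped=trace.wrapped,
        quality=quality,
    )
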