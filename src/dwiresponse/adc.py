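"""Trace-image formation and voxelwise monoexponential ADC estimation.

Each voxel's signal across b-values is fit to S(b) = S0 * exp(-b * ADC),
with ADC expressed in 1e-3 mm^2/s and constrained to [0, adc_max], S0 > 0.
There is no b=0 image (the lowest acquired weighting is 10 s/mm^2), so S0
is a free parameter of the fit.

The least-squares problem is solved by variable projection: for any fixed
ADC the optimal S0 has a closed form, reducing the fit to a 1-D profiled
objective in ADC.  That profile is minimized by a dense bracketing scan
followed by golden-section refinement — deterministic, derivative-free and
immune to the local minima a descent method can fall into on noisy decay
curves.  The objective is unweighted and no Rician bias correction is
applied (a documented limitation at low SNR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_model import ADCMap, DWIStudy, VOIMask

#: Upper ADC bound, 1e-3 mm^2/s.  Free water is ~3; the cap only rejects
#: pathological fits.  Hitting a bound leaves the fit converged.
DEFAULT_ADC_MAX = 10.0

_GRID_POINTS = 257
_GOLDEN_ITERS = 35
_SECANT_ITERS = 30
_INVGOLD = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class FitResult:
    """One voxel's monoexponential fit: ADC (1e-3 mm^2/s), S0 (signal units),
    RMS residual and a convergence flag."""

    adc: float
    s0: float
    residual_norm: float
    converged: bool


def trace_average(direction_images: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Average diffusion-weighted images acquired with gradients along three
    orthogonal directions into a direction-independent trace image."""
    if len(direction_images) != 3:
        raise ValidationError("trace averaging expects exactly 3 direction images")
    arrays = [np.asarray(a, dtype=float) for a in direction_images]
    if not (arrays[0].shape == arrays[1].shape == arrays[2].shape):
        raise ValidationError("direction images must share dimensions")
    return (arrays[0] + arrays[1] + arrays[2]) / 3.0


def _profile(signals: np.ndarray, bvalues: np.ndarray, adc: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Profiled objective: for each row of ``signals`` and the matching entry
    of ``adc``, the optimal S0 (clipped to >= 0) and the residual sum of
    squares at that S0."""
    decay = np.exp(-np.multiply.outer(adc * 1e-3, bvalues))
    num = np.sum(signals * decay, axis=-1)
    den = np.sum(decay * decay, axis=-1)
    s0 = np.clip(num / den, 0.0, None)
    # residuals formed directly: the expanded quadratic form cancels
    # catastrophically near a zero-residual optimum
    resid = signals - s0[..., None] * decay
    rss = np.sum(resid * resid, axis=-1)
    return s0, rss


def _fit_batch(signals: np.ndarray, bvalues: np.ndarray, adc_max: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized fit of many voxels.  Returns (adc, s0, rss)."""
    n = signals.shape[0]
    grid = np.linspace(0.0, adc_max, _GRID_POINTS)
    # shared decay matrix across voxels for the bracketing scan
    decay = np.exp(-np.multiply.outer(grid, bvalues * 1e-3))  # (grid, nb)
    num = signals @ decay.T  # (n, grid)
    den = np.sum(decay * decay, axis=1)  # (grid,)
    s0g = np.clip(num / den, 0.0, None)
    rss_grid = np.sum(signals * signals, axis=1)[:, None] - 2.0 * s0g * num + s0g**2 * den
    best = np.argmin(rss_grid, axis=1)
    step = grid[1] - grid[0]
    lo = np.clip(grid[best] - step, 0.0, adc_max)
    hi = np.clip(grid[best] + step, 0.0, adc_max)

    lo0, hi0 = lo.copy(), hi.copy()

    # golden-section refinement inside the bracket, all voxels in lockstep
    x1 = hi - _INVGOLD * (hi - lo)
    x2 = lo + _INVGOLD * (hi - lo)
    _, f1 = _profile(signals, bvalues, x1)
    _, f2 = _profile(signals, bvalues, x2)
    for _ in range(_GOLDEN_ITERS):
        take_left = f1 < f2
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
        x1 = hi - _INVGOLD * (hi - lo)
        x2 = lo + _INVGOLD * (hi - lo)
        _, f1 = _profile(signals, bvalues, x1)
        _, f2 = _profile(signals, bvalues, x2)
    adc = np.clip(np.where(f1 < f2, x1, x2), 0.0, adc_max)
    s0, rss = _profile(signals, bvalues, adc)

    # Secant polish of the stationarity condition.  The golden search can
    # only localize the argmin to ~sqrt(machine eps) because the objective is
    # numerically flat there; the gradient (by the envelope theorem
    # proportional to sum_i r_i b_i e_i at the profiled S0) is free of that
    # cancellation and pins the optimum to machine precision.
    def gradient(a):
        decay = np.exp(-np.multiply.outer(a * 1e-3, bvalues))
        num = np.sum(signals * decay, axis=-1)
        den = np.sum(decay * decay, axis=-1)
        s0_ = np.clip(num / den, 0.0, None)
        resid = signals - s0_[..., None] * decay
        return np.sum(resid * bvalues * decay, axis=-1)

    a0, a1 = lo, hi
    g0, g1 = gradient(a0), gradient(a1)
    for _ in range(_SECANT_ITERS):
        denom = g1 - g0
        step_s = np.where(denom != 0, g1 * (a1 - a0) / np.where(denom == 0, 1.0, denom), 0.0)
        a_next = np.clip(a1 - step_s, lo0, hi0)
        a0, g0 = a1, g1
        a1 = a_next
        g1 = gradient(a1)
    s0_p, rss_p = _profile(signals, bvalues, a1)
    # the polish improvement near the optimum is below one ulp of the RSS, so
    # a strict comparison is a coin flip; a relative slack keeps the polished
    # location whenever the secant stayed in the basin
    polish_better = rss_p <= rss * (1.0 + 1e-9) + 1e-300
    adc = np.where(polish_better, a1, adc)
    s0 = np.where(polish_better, s0_p, s0)
    rss = np.where(polish_better, rss_p, rss)

    # a boundary candidate can beat the interior bracket on flat profiles
    s0_lo, rss_lo = _profile(signals, bvalues, np.zeros(n))
    better = rss_lo < rss
    adc = np.where(better, 0.0, adc)
    s0 = np.where(better, s0_lo, s0)
    rss = np.where(better, rss_lo, rss)
    return adc, s0, np.maximum(rss, 0.0)


def fit_voxel(signal: np.ndarray, bvalues: np.ndarray,
              adc_max: float = DEFAULT_ADC_MAX) -> FitResult:
    """Fit one voxel's decay curve.

    The fit is flagged unconverged (rather than raising) when at least half
    the signals are non-positive or the optimal S0 is not positive; fewer
    than two b-values is a validation error.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    bvalues = np.asarray(bvalues, dtype=float).ravel()
    if bvalues.size < 2:
        raise ValidationError("at least 2 b-values required")
    if signal.size != bvalues.size:
        raise ValidationError("signal and bvalues must have equal length")
    if not np.all(np.isfinite(signal)):
        raise ValidationError("signal must be finite")
    if np.count_nonzero(signal <= 0) * 2 >= signal.size:
        return FitResult(adc=np.nan, s0=np.nan, residual_norm=np.nan, converged=False)
    adc, s0, rss = _fit_batch(signal[None, :], bvalues, adc_max)
    if not s0[0] > 0:
        return FitResult(adc=np.nan, s0=np.nan, residual_norm=np.nan, converged=False)
    return FitResult(
        adc=float(adc[0]),
        s0=float(s0[0]),
        residual_norm=float(np.sqrt(rss[0] / signal.size)),
        converged=True,
    )


def compute_adc_map(study: DWIStudy, mask: VOIMask | None = None,
                    adc_max: float = DEFAULT_ADC_MAX) -> ADCMap:
    """Voxelwise ADC map over the study (restricted to ``mask`` when given).

    Voxels outside the mask, with mostly non-positive signal, or with a
    non-positive fitted S0 are flagged invalid and carry NaN.
    """
    shape = study.shape
    if mask is not None and mask.mask.shape != shape:
        raise ValidationError("mask geometry does not match the study")
    data = study.stacked()  # (x, y, z, b)
    select = mask.mask if mask is not None else np.ones(shape, dtype=bool)
    signals = data[select]  # (n, nb)
    bvalues = np.asarray(study.bvalues, dtype=float)

    finite = np.all(np.isfinite(signals), axis=1)
    enough_signal = np.count_nonzero(signals <= 0, axis=1) * 2 < bvalues.size
    fittable = finite & enough_signal

    adc_flat = np.full(signals.shape[0], np.nan)
    s0_flat = np.full(signals.shape[0], np.nan)
    ok = np.zeros(signals.shape[0], dtype=bool)
    if np.any(fittable):
        adc_f, s0_f, _ = _fit_batch(signals[fittable], bvalues, adc_max)
        pos = s0_f > 0
        idx = np.flatnonzero(fittable)
        adc_flat[idx[pos]] = adc_f[pos]
        s0_flat[idx[pos]] = s0_f[pos]
        ok[idx[pos]] = True

    values = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    values[select] = adc_flat
    s0[select] = s0_flat
    valid[select] = ok
    return ADCMap(
        values=values, s0=s0, valid=valid,
        voxel_size=study.voxel_size,
        slice_thickness=study.slice_thickness,
        slice_gap=study.slice_gap,
    )
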