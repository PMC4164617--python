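"""Translation-only registration of the DWI series along the b-value axis.

Bulk motion between the acquisitions at different diffusion weightings
corrupts the voxelwise decay curves, so before fitting the series is
rigidly aligned by Fourier cross-correlation: each slice of each volume is
phase-correlated with the corresponding slice of a reference volume (by
default the lowest b-value, which has the highest signal), the correlation
peak is refined to sub-voxel precision by quadratic interpolation, and the
volume is resampled onto the reference by a band-limited Fourier shift.

Boundary semantics are circular — inherent to the Fourier model; objects
should stay away from the image edge.  Rotation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import fourier_shift

from .errors import DegenerateInputError, ValidationError
from .io_model import DWIStudy

#: Regularization of the spectral whitening, relative to the peak
#: cross-power magnitude; keeps low-energy frequencies from dominating.
_WHITEN_EPS = 1e-9


@dataclass
class ShiftEstimate:
    """In-plane displacement (voxels, fractional) with the normalized
    correlation-peak height in [0, 1]."""

    dy: float
    dx: float
    peak_score: float


def _wrap(index: int, size: int) -> float:
    """Map an FFT bin index to the signed shift range (-size/2, size/2]."""
    return index - size if index > size // 2 else index


def _quadratic_offset(m1: float, m0: float, p1: float) -> float:
    """Sub-voxel offset of a parabola through three samples around a peak."""
    denom = m1 - 2.0 * m0 + p1
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    offset = float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))
    # sub-rounding offsets are numerical noise on an exact integer peak
    return 0.0 if abs(offset) < 1e-6 else offset


def estimate_shift(reference: np.ndarray, moving: np.ndarray) -> ShiftEstimate:
    """Estimate the translation (dy, dx) such that ``moving`` equals
    ``reference`` displaced by (dy, dx).

    Phase correlation: the cross-power spectrum of the pair is spectrally
    whitened and inverse-transformed; its argmax is the integer shift, and a
    quadratic fit to the three samples around the peak (per axis, with
    circular neighbors) refines it to sub-voxel precision.  Applying the
    negated estimate to ``moving`` aligns it with ``reference``.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape or reference.ndim != 2:
        raise ValidationError("reference and moving must be 2D arrays of equal shape")
    for name, img in (("reference", reference), ("moving", moving)):
        if np.ptp(img) == 0:
            raise DegenerateInputError(f"{name} image is constant")

    cross = np.fft.fft2(moving) * np.conj(np.fft.fft2(reference))
    mag = np.abs(cross)
    surface = np.fft.ifft2(cross / (mag + _WHITEN_EPS * mag.max())).real
    ny, nx = surface.shape
    iy, ix = np.unravel_index(np.argmax(surface), surface.shape)
    off_y = _quadratic_offset(
        surface[(iy - 1) % ny, ix], surface[iy, ix], surface[(iy + 1) % ny, ix]
    )
    off_x = _quadratic_offset(
        surface[iy, (ix - 1) % nx], surface[iy, ix], surface[iy, (ix + 1) % nx]
    )
    return ShiftEstimate(
        dy=float(_wrap(iy, ny) + off_y),
        dx=float(_wrap(ix, nx) + off_x),
        peak_score=float(np.clip(surface[iy, ix], 0.0, 1.0)),
    )


def shift_image(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate a 2D image by (dy, dx) voxels with circular boundaries.

    Integer displacements are exact rolls; fractional ones use band-limited
    Fourier interpolation.
    """
    image = np.asarray(image, dtype=float)
    if dy == int(dy) and dx == int(dx):
        return np.roll(image, (int(dy), int(dx)), axis=(0, 1))
    return np.fft.ifft2(fourier_shift(np.fft.fft2(image), (dy, dx))).real


def register_series(
    study: DWIStudy, reference_index: int = 0
) -> tuple[DWIStudy, list[list[ShiftEstimate]]]:
    """Align every volume of the series onto the reference volume, slice by
    slice, and return the registered study plus the per-(b-value, slice)
    shift estimates.

    The reference volume (default: the lowest b-value) passes through
    unchanged; its estimates are identically zero.  A constant slice raises
    a degenerate-input error annotated with the offending b-value.
    """
    if not 0 <= reference_index < study.n_bvalues:
        raise ValidationError(f"reference_index {reference_index} out of range")
    ref = study.volumes[reference_index]
    n_slices = study.shape[2]
    registered: list[np.ndarray] = []
    estimates: list[list[ShiftEstimate]] = []
    for i, vol in enumerate(study.volumes):
        if i == reference_index:
            registered.append(vol.copy())
            estimates.append([ShiftEstimate(0.0, 0.0, 1.0) for _ in range(n_slices)])
            continue
        out = np.empty_like(vol, dtype=float)
        per_slice = []
        for k in range(n_slices):
            if np.ptp(ref[:, :, k]) == 0 and np.ptp(vol[:, :, k]) == 0:
                # featureless on both sides (e.g. background-only slices of a
                # noiseless phantom): no motion information, zero shift exact
                est = ShiftEstimate(0.0, 0.0, 0.0)
            else:
                try:
                    est = estimate_shift(ref[:, :, k], vol[:, :, k])
                except DegenerateInputError as exc:
                    raise DegenerateInputError(
                        f"b={study.bvalues[i]:g} s/mm^2, slice {k}: {exc}"
                    ) from exc
            per_slice.append(est)
            if est.dy == 0.0 and est.dx == 0.0:
                out[:, :, k] = vol[:, :, k]
            else:
                out[:, :, k] = shift_image(vol[:, :, k], -est.dy, -est.dx)
        registered.append(out)
        estimates.append(per_slice)
    out_study = DWIStudy(
        volumes=registered,
        bvalues=list(study.bvalues),
        voxel_size=study.voxel_size,
        slice_thickness=study.slice_thickness,
        slice_gap=study.slice_gap,
        study_id=study.study_id,
    )
    return out_study, estimates


def shifts_to_rows(study: DWIStudy, estimates: list[list[ShiftEstimate]]) -> list[dict]:
    """Flatten per-(b-value, slice) estimates to rows for CSV export."""
    rows = []
    for b, per_slice in zip(study.bvalues, estimates):
        for k, est in enumerate(per_slice):
            rows.append(
                {"bvalue": b, "slice": k, "dy": est.dy, "dx": est.dx,
                 "peak_score": est.peak_score}
            )
    return rows
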