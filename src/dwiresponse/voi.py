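"""Volume-of-interest summary metrics.

The representative tumor ADC of a session is the median of the voxelwise
ADC distribution inside the VOI (valid fits only); the tumor volume is the
combined volume of all mask voxels.  Growth is expressed relative to
baseline, so tumors of different starting size are comparable.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import EmptyVOIError, ValidationError
from .io_model import ADCMap, AnimalRecord, CohortTable, VOIMask


def median_adc(adc_map: ADCMap, mask: VOIMask) -> float:
    """Median ADC (1e-3 mm^2/s) over the valid voxels inside the mask.

    An even voxel count yields the mean of the two central order statistics.
    Invalid fits are excluded rather than zero-filled (zeros would bias the
    median downward); a mask with no valid voxels is an error.
    """
    if mask.mask.shape != adc_map.values.shape:
        raise ValidationError("mask geometry does not match the ADC map")
    if mask.n_voxels == 0:
        raise EmptyVOIError("mask is empty")
    selected = mask.mask & adc_map.valid
    if not np.any(selected):
        raise EmptyVOIError("no valid ADC voxels inside the mask")
    return float(np.median(adc_map.values[selected]))


def mask_volume(mask: VOIMask) -> float:
    """Tumor volume in mm^3: voxel count times the voxel footprint times the
    effective slice spacing (thickness + gap)."""
    n = mask.n_voxels
    if n == 0:
        warnings.warn("empty mask: volume is 0", stacklevel=2)
    vx, vy = mask.voxel_size
    return n * vx * vy * (mask.slice_thickness + mask.slice_gap)


def relative_change(baseline: float, followup: float) -> float:
    """Percent change relative to baseline: 100 * (followup - baseline) / baseline."""
    if baseline <= 0:
        raise ValidationError("baseline must be > 0")
    return 100.0 * (followup - baseline) / baseline


def caliper_volume(a: float, b: float, c: float) -> float:
    """Ellipsoid-approximation tumor volume from three caliper measurements
    (mm): a * b * c * 0.5."""
    if min(a, b, c) <= 0:
        raise ValidationError("caliper dimensions must be > 0")
    return a * b * c * 0.5


def build_records(
    measurements: list[dict] | list[tuple],
    provenance: str = "",
) -> CohortTable:
    """Assemble a cohort table from per-animal session summaries.

    Each measurement is either a mapping with keys (animal_id, group, adc_b,
    adc_f, vol_b, vol_f) or a tuple in that order; both sessions must be
    present.  Deltas are recomputed: d_adc = adc_f - adc_b, d_vol_pct via
    :func:`relative_change`.  Group medians of deltas must always be taken
    over the per-animal deltas, never as a difference of group medians.
    """
    keys = ("animal_id", "group", "adc_b", "adc_f", "vol_b", "vol_f")
    records = []
    for m in measurements:
        if not isinstance(m, dict):
            m = dict(zip(keys, m))
        missing = [k for k in keys if k not in m or m[k] is None]
        if missing:
            raise ValidationError(f"measurement missing fields {missing}")
        records.append(
            AnimalRecord(
                animal_id=str(m["animal_id"]),
                group=str(m["group"]),
                adc_b=float(m["adc_b"]),
                adc_f=float(m["adc_f"]),
                vol_b=float(m["vol_b"]),
                vol_f=float(m["vol_f"]),
            )
        )
    return CohortTable(records=records, provenance=provenance)
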