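"""Recover bulk motion along the b-value dimension by phase correlation.

Injects a known in-plane shift into every volume of a noisy phantom
series, registers the series back onto the lowest-b reference and shows
that registration restores the voxelwise ADC accuracy that motion
destroyed.
"""

import numpy as np

from dwiresponse import PhantomConfig, compute_adc_map, generate_phantom, register_series

shifts = [(0, 0), (1.5, -1), (-1, 0.5), (0, 2), (1, 0), (-2, -1),
          (1, -1), (0.5, -2), (2, 1)]
cfg = PhantomConfig(dims=(48, 40, 12), semi_axes=(10, 8, 4),
                    snr=50.0, shifts=shifts, seed=7)
study, voi, truth = generate_phantom(cfg)

registered, estimates = register_series(study, reference_index=0)
errors = [abs(est.dy - dy) + abs(est.dx - dx)
          for (dy, dx), per_slice in zip(shifts, estimates)
          for est in per_slice]
print(f"median shift recovery error: {np.median(errors):.3f} voxels")


def median_adc_error(st):
    amap = compute_adc_map(st, mask=voi)
    sel = voi.mask & amap.valid
    return np.median(np.abs(amap.values[sel] - truth.values[sel]))


before, after = median_adc_error(study), median_adc_error(registered)
print(f"median voxel ADC error, unregistered: {before:.4f} x 1e-3 mm^2/s")
print(f"median voxel ADC error, registered:   {after:.4f} x 1e-3 mm^2/s")
# motion mixes tumor and background decay curves; undoing it recovers most
# of the lost ADC accuracy
print(f"error reduction factor:               {before / after:.1f}x")
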