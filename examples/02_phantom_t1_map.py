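"""Generate a mid-calf phantom and map its compartment T1 values.

Renders a single right leg at SNR 50 (Rician noise), fits the native T1
map over the labeled voxels and prints peak/mean/min T1 and the
cross-sectional area per muscle compartment next to the ground truth.
The peak lands on the compartment's hot-spot voxel, so its error is the
single-voxel fit uncertainty (roughly 150 ms at these long T1 values).
"""

import numpy as np

from calfmolli import (MUSCLE_COMPARTMENTS, FitOptions, PhantomConfig,
                       compartment_metrics, fit_map, generate_phantom)

cfg = PhantomConfig(grid_size=64, pixel_spacing_mm=3.0,
                    noise_sigma=20.0, noise_model="rician", seed=42)
pre, post, regions, truth = generate_phantom(cfg)

mask = np.zeros(pre.shape, dtype=bool)
for name in regions.labels:
    if name != "leg":
        mask |= regions[name]
t1map = fit_map(pre, mask)

print(f"{'region':>6} {'peak':>7} {'truth':>7} {'mean':>7} {'min':>6} {'area mm2':>9}")
for name in MUSCLE_COMPARTMENTS:
    m = compartment_metrics(t1map, regions[name], regions.pixel_spacing_mm, name)
    print(f"{name:>6} {m.peak_t1_ms:7.0f} {truth.region_t1_pre[name]:7.1f} "
          f"{m.mean_t1_ms:7.0f} {m.min_t1_ms:6.0f} {m.csa_mm2:9.0f}")
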