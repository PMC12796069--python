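"""First-pass parametric images: bolus arrival time (t_mid) and area (AUC).

Extracts the first-pass peak of every voxel's time-activity curve and prints
per-structure median arrival times — the timing ladder RA < RV < lungs <
LA < LV <= aorta that the atrial segmentation gates rely on.
"""

import numpy as np

from atriaflow.firstpass import compute_parametric_maps
from atriaflow.phantom import default_phantom_spec, generate_phantom

series, truth = generate_phantom(default_phantom_spec(grid_n=64, voxel_mm=3.0, seed=0))
maps = compute_parametric_maps(series)

print(f"peak detected in {maps.detected.sum()} of {maps.detected.size} voxels")
print("structure        median t_mid (s)   injected (s)   median raw AUC")
for name in ("right_atrium", "rv_cavity", "lungs", "left_atrium", "lv_cavity", "aorta"):
    m = truth.mask(name)
    print(f"  {name:<14} {np.nanmedian(maps.tmid[m]):10.1f}      "
          f"{truth.centroid_times_s[name]:8.1f}      {np.nanmedian(maps.auc_raw[m]):10.0f}")
# t_mid is the duration-weighted centroid of the first-pass peak; AUC (in
# kBq*s/mL) is proportional to local blood volume and is later normalised
# so the LV blood pool reads 1.
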