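"""End-to-end atrial volumetry on a synthetic scan.

Runs the complete chain — parametric maps, input-function clustering,
kinetic model fitting, short-axis reorientation, ventricular and atrial
segmentation — and prints the resulting volume report next to the phantom's
ground truth.
"""

from atriaflow.phantom import default_phantom_spec, generate_phantom
from atriaflow.pipeline import run_pipeline

series, truth = generate_phantom(default_phantom_spec(grid_n=64, voxel_mm=3.0,
                                                      noise_scale=1.0, seed=0))
result = run_pipeline(series)
rep = result.report

print(f"LAV  {rep.lav_ml:6.1f} mL   (truth {truth.volumes_ml['left_atrium']:.1f} mL)")
print(f"RAV  {rep.rav_ml:6.1f} mL   (truth {truth.volumes_ml['right_atrium']:.1f} mL)")
print(f"LAVI {rep.lavi_ml_m2:6.1f} mL/m^2, RAVI {rep.ravi_ml_m2:6.1f} mL/m^2 "
      f"(BSA {rep.bsa_m2:.2f} m^2, Du Bois)")
print(f"timing: t_RV {rep.t_rv_s:.1f} s < t_lungs {rep.t_lungs_s:.1f} s "
      f"< t_LV {rep.t_lv_s:.1f} s")
print(f"QC flags: {rep.flags or 'none'}")
# The reported volumes are mean atrial volumes over the (non-gated) scan;
# the ~10% underestimate vs truth reflects the 2/3-of-LV blood-pool
# threshold clipping the partial-volume rim of each chamber.
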