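"""Voxelwise Ki and k3 parametric maps on a digital phantom.

Simulates a 32^3 dynamic phantom (muscle body, blood pool, tumor with a 30%
hypoxic core), derives the plasma input from the early-bolus blood ROI,
and computes:
  * a whole-body Patlak Ki map and its tumor-to-muscle contrast,
  * a tumor-restricted compartmental k3 map and the fraction of the tumor
    volume the k3 map covers at 20% of its in-tumor maximum.

Runs in well under a minute on one CPU.
"""

import numpy as np

from fmisopk import (
    PhantomSpec,
    contrast_ratio,
    default_schedule,
    k3_map,
    ki_map,
    lv_input_function,
    make_input_function,
    map_positive_fraction,
    simulate_dynamic_pet,
)

schedule = default_schedule()
cp = make_input_function()
spec = PhantomSpec(hypoxic_fraction=0.30)
phantom = simulate_dynamic_pet(spec, cp, schedule)
tumor, muscle = phantom.masks["tumor"], phantom.masks["muscle"]

cp_img, lv_mask = lv_input_function(phantom.image4d, schedule)
print(f"image-derived input from {lv_mask.n_voxels} blood-pool voxels")

kmap = k3_map(phantom.image4d, cp_img, tumor, schedule)
level = 0.2 * float(kmap.masked_values(tumor).max())
frac = map_positive_fraction(kmap, tumor, level)
core = kmap.masked_values(phantom.masks["core"])
print(f"k3 map: core median {np.median(core):.4f} 1/min "
      f"(design {spec.core_params.k3:.4f})")
print(f"k3-map volume at level {level:.4f}: {frac:.1f}% of tumor "
      f"(designed hypoxic fraction 30%)")

kimap = ki_map(phantom.image4d, cp_img, phantom.masks["body"], schedule)
ki_contrast = contrast_ratio(np.nan_to_num(kimap.values), tumor, muscle,
                             valid=kimap.valid)
frame_contrast = contrast_ratio(phantom.image4d[..., -1], tumor, muscle)
print(f"tumor/muscle contrast: Ki map {ki_contrast:.1f} "
      f"vs last-frame intensity {frame_contrast:.1f}")
print()
print("The Ki map sharpens tumor contrast because trapped tracer integrates")
print("the whole 2 h while blood and muscle background clear.")
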