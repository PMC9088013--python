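"""Simulate labelled brain phantoms with exact lesion ground truth.

Builds a small dataset of ellipsoidal "brain" volumes where class 1
carries a localized intensity reduction (atrophy surrogate), and prints
which slices in each view intersect a lesion — the ground truth used to
validate slice attention and saliency.
"""

import numpy as np

from msa3d import PhantomSpec, generate_dataset, make_phantom

spec = PhantomSpec()  # (24, 28, 24) grid, effect_size 0.8, noise_sd 0.05
control = make_phantom(spec, with_lesion=False)
patient = make_phantom(spec, with_lesion=True)

print(f"phantom grid {control.shape}, brain fills "
      f"{np.count_nonzero(control.data) / control.data.size:.1%} of the box")
print(f"mean intensity: control {control.data[control.data > 0].mean():.3f}, "
      f"lesioned {patient.data[patient.data > 0].mean():.3f}")
# the lesioned mean is lower because voxels inside the lesion ellipsoid
# are scaled by (1 - effect_size)

ds = generate_dataset(n_per_class=5, spec=spec, seed=7)
print(f"\ndataset: {len(ds)} volumes, labels balanced "
      f"({sum(ds.labels)} lesioned)")
for view in ("sagittal", "coronal", "axial"):
    idx = sorted(ds.informative_slices[view])
    print(f"informative {view} slices: {idx[0]}..{idx[-1]} "
          f"({len(idx)} of {spec.shape[('sagittal', 'coronal', 'axial').index(view)]})")
# these index sets are the union of (jittered center +/- radius) over the
# lesioned samples: any attention or saliency signal should land there
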