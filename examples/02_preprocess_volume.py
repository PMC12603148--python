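"""Run the standardized CT preprocessing pipeline on one phantom.

Resamples to 1 mm isotropic, clips to the chest window [-1000, +400] HU,
min-max normalizes to [0, 1], center-crops/pads to 128^3 about the airway
centroid, and Gaussian-smooths (sigma = 1 voxel). Prints the intensity
mapping of the key tissue classes.
"""

from lucent.phantom import PhantomSpec, generate_tree, rasterize_phantom
from lucent.preprocess import PreprocessConfig, preprocess_volume

spec = PhantomSpec()
vol, mask = rasterize_phantom(generate_tree(spec), spec)
print(f"input : shape {vol.shape}, spacing {vol.spacing_mm} mm, "
      f"HU range [{vol.voxels.min():.0f}, {vol.voxels.max():.0f}]")

out, out_mask = preprocess_volume(vol, mask, PreprocessConfig())
print(f"output: shape {out.shape}, domain {out.intensity_domain}, "
      f"range [{out.voxels.min():.3f}, {out.voxels.max():.3f}]")

for name, hu in [("air/lumen", -1000), ("parenchyma", -820),
                 ("airway wall", -100), ("soft-tissue plug", 40)]:
    print(f"  {name:>16}: {hu:+5d} HU -> {(min(max(hu, -1000), 400) + 1000) / 1400:.3f}")
print("\nthe plug stays inside the window: radiolucent means soft-tissue")
print("density, not invisible to CT — it is just not a bright object.")
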