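"""Write a phantom CT volume and its ground-truth masks as NIfTI files.

The files land in ./phantom_out and can be fed back through the command
line tool:  visfat segment --input phantom_out/phantom.nii.gz --out seg
--no-rescale
"""

from pathlib import Path

import visfat
from visfat.volume import write_mask, write_volume

out = Path("phantom_out")
out.mkdir(exist_ok=True)

spec = visfat.default_specs(seed=7)[0]          # "thin"
vol, truth = visfat.generate_phantom(spec)
write_volume(vol, out / "phantom.nii.gz")
for name in ("trunk", "bone", "muscle", "air", "fat"):
    write_mask(getattr(truth.tissues, name), out / f"truth_{name}.nii.gz")
write_mask(truth.visceral_fat, out / "truth_visceral_fat.nii.gz")

print(f"wrote {spec.name} phantom ({vol.shape[0]}x{vol.shape[1]}x{vol.shape[2]} voxels, "
      f"{vol.spacing[0]:.2f}x{vol.spacing[1]:.2f}x{vol.spacing[2]:.2f} mm) to {out}/")
print(f"ground-truth visceral fat: {truth.visceral_volume_cm3:.2f} cm^3, "
      f"pubic plane at z = {truth.pubis_z}")
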