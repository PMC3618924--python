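"""Generate a density-graded synthetic dataset and look at its texture.

Builds a few synthetic mammographic images per BI-RADS density grade,
embeds masses with chain-coded boundaries, and prints per-grade texture
statistics.  Mean intensity and variance rise with the density grade —
the property that makes dense breasts harder to read.
"""

import numpy as np

from mammica import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(seed=0, n_images_per_density=8, image_side=192, mass_fraction=0.5)
ds = generate_dataset(cfg)

print("image_id         density  n_regions  label")
for row in ds.manifest.head(6).itertuples(index=False):
    print(f"{row.image_id:<18} {row.density:^7} {row.n_regions:^9} {row.label}")
print(f"... {len(ds.images)} images total\n")

print("density  mean intensity  pixel std   (20-draw averages, mass-free)")
for density in (1, 2, 3, 4):
    draws = [
        img.pixels
        for img in ds.images
        if img.density == density and not img.regions
    ]
    mean = np.mean([d.mean() for d in draws])
    std = np.mean([d.std() for d in draws])
    print(f"   {density}        {mean:.3f}         {std:.3f}")

print(
    "\nBoth statistics increase with the grade: grade-4 backgrounds carry the"
    "\nmost structured bright texture, which later masks the inserted masses."
)
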