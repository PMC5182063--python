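"""Render a PALM image of a simulated bipolar cell.

Accumulates localizations in a 2D histogram, blurs with a 15-nm Gaussian
(matching the localization uncertainty) and gamma-adjusts to 0.5 to compress
the dynamic range between the bright stalked-pole cluster and sparse
single-molecule background.  Writes a 16-bit TIFF next to this script.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from strobopalm import ClusterSpec, LocalizationTable, RenderSettings, simulate_cluster
from strobopalm.render import render_palm_image, save_image

rng = np.random.default_rng(3)

# one extended pole, one compact pole, plus diffuse background
stalked = simulate_cluster(
    ClusterSpec("annular-arc", 600, radius_nm=180.0, width_nm=80.0,
                arc_start_deg=-100, arc_end_deg=100, sigma_nm=15.0,
                center=(0.0, 0.0)),
    rng,
)
swarmer = simulate_cluster(
    ClusterSpec("disk", 250, radius_nm=70.0, sigma_nm=15.0, center=(2_500.0, 0.0)),
    rng,
)
n_bg = 150
background = LocalizationTable.from_arrays(
    frame=np.arange(n_bg),
    x_nm=rng.uniform(-500, 3_000, n_bg),
    y_nm=rng.uniform(-600, 600, n_bg),
)
table = LocalizationTable(
    pd.concat([stalked.df, swarmer.df, background.df], ignore_index=True)
)

image = render_palm_image(table, RenderSettings(pixel_size_nm=15.0,
                                                blur_sigma_nm=15.0, gamma=0.5))
out = Path.cwd() / "render_image.tif"
save_image(image, out)
print(f"rendered {image.shape[1]} x {image.shape[0]} px image "
      f"({len(table)} localizations) -> {out.name}")
print(f"intensity range [{image.min():.2f}, {image.max():.2f}] after gamma 0.5")
print("The two poles appear as one extended arc and one compact focus, the")
print("morphological difference the cluster metrics quantify.")
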