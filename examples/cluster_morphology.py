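"""Measure nanoscale cluster area/shape and test against the zero-area baseline.

Even a true point source measures a positive area because every localization
carries ~15 nm of error.  The zero-area baseline (point-source clouds with
matched localization count and precision, run through the same DBSCAN ->
rasterize -> close -> measure pipeline) quantifies that floor; Mood's median
test then says whether an observed cluster ensemble is genuinely extended.
"""

import numpy as np

from strobopalm import (
    ClusterSpec,
    density_cluster,
    measure_cluster_area,
    moods_median_test,
    simulate_cluster,
    zero_area_baseline,
)

rng = np.random.default_rng(7)

# a "large stalked-pole-like" extended cluster: 150 nm disk, 300 localizations
disk_spec = ClusterSpec("disk", 300, radius_nm=150.0, sigma_nm=15.0)
cloud = simulate_cluster(disk_spec, rng)
labelled = density_cluster(cloud, eps_nm=50.0, min_pts=25)
labels = labelled.df["cluster_label"]
print(f"DBSCAN: {int((labels >= 0).sum())}/{len(cloud)} localizations in clusters")

shape = measure_cluster_area(cloud)
print(f"disk cluster  : area {shape.area_nm2/1e4:.2f} x 10^4 nm^2, "
      f"C {shape.circularity:.2f}, S {shape.solidity:.2f}, E {shape.eccentricity:.2f}")

baseline = zero_area_baseline(ClusterSpec("point", 300, sigma_nm=15.0), 200, rng)
print(f"zero-area baseline: median {np.median(baseline)/1e4:.2f} x 10^4 nm^2 "
      f"(all {len(baseline)} replicates > 0)")

disk_areas = [
    measure_cluster_area(simulate_cluster(disk_spec, rng)).area_nm2 for _ in range(100)
]
chi2, p, _ = moods_median_test(disk_areas, baseline)
print(f"disk ensemble vs baseline: Mood's chi2 = {chi2:.1f}, p = {p:.2g}")
print("p << 0.001: the disk ensemble is a genuinely extended assembly, not")
print("a point source inflated by localization noise.")
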