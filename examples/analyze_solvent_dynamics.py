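"""Binding-site statistics from a solvent-coordinate ensemble.

Generates frames for two water-binding sites with different planted
occupancy and positional spread, renders the frame-averaged solvent
density, extracts binding-site peaks, and recovers occupancy, RMSF and
peak density (in waters/A^3 and molar units).
"""

import numpy as np

from rnaswim import (BindingSite, assign_frame_solvent, find_binding_sites,
                     generate_water_ensemble, molarity_to_number_density,
                     number_density_to_molarity, render_coordinate_density,
                     site_occupancy, site_rmsf)

sites_truth = [
    (np.array([10.0, 10.0, 10.0]), 0.9, 0.3),   # ordered: high p, low s
    (np.array([16.0, 10.0, 10.0]), 0.5, 0.9),   # diffuse: low p, high s
]
frames = generate_water_ensemble(sites_truth, n_frames=5000, seed=11)

density = render_coordinate_density(frames, "water", origin=(4, 4, 4),
                                    shape=(45, 30, 30), voxel_size=0.4)
sites = find_binding_sites(density, kind="water")
assignments = assign_frame_solvent(frames, sites)

print(f"bulk water at 55 M = "
      f"{molarity_to_number_density(55):.3f} waters/A^3\n")
print("site  planted(p, s)   occupancy   RMSF(A)   peak density")
for truth, site, asn in zip(sites_truth, sites, assignments):
    occ = site_occupancy(asn, frames)
    rmsf = site_rmsf(asn)
    molar = number_density_to_molarity(site.peak_density)
    print(f"  {truth[1]:.1f}, {truth[2]:.1f} A      "
          f"{occ:9.3f}  {rmsf:8.3f}   {site.peak_density:.3f}/A^3"
          f" ({molar:.0f} M)")

print("\nThe ordered site recovers its planted occupancy and spread and"
      "\nshows a far higher peak density than the diffuse site: both low"
      "\noccupancy and high positional spread flatten the density peak,"
      "\nwhich is why such waters elude peak-based modelling.")
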