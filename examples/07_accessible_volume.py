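"""Accessible-volume dye modelling and structure screening.

Computes dye accessible volumes around two attachment points next to a
simple obstacle, predicts the mean inter-dye distance, and screens two
candidate geometries against a measured distance.
"""

import numpy as np
import pandas as pd

from chromofret import structure as st

# a crude cylindrical obstacle between the two label sites
theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
ring = np.column_stack([np.full(24, 25.0), 8 * np.cos(theta), 8 * np.sin(theta)])
obstacles = np.vstack([ring + [0, 0, dz] for dz in range(-10, 11, 2)])
radii = np.full(len(obstacles), 2.0)

site1 = st.LabelSite((0, 0, 0), linker_length=12.0, linker_width=4.5, dye_radius=3.5)
site2 = st.LabelSite((50.0, 0, 0), linker_length=12.0, linker_width=4.5, dye_radius=3.5)
av1 = st.compute_accessible_volume(obstacles, radii, site1, grid_spacing=1.0)
av2 = st.compute_accessible_volume(obstacles, radii, site2, grid_spacing=1.0)
print(f"AV1: {len(av1.points)} grid points, volume {av1.volume:.0f} A^3, "
      f"contact fraction {av1.contact_fraction:.2f}")

mean_r, se = st.av_mean_distance(av1, av2, seed=0)
print(f"predicted <R_DA> = {mean_r:.1f} +/- {se:.2f} A "
      f"(attachment separation 50 A; linkers broaden and shift the mean)")

measured = st.DistanceSet(pd.DataFrame({
    "pair_id": ["DA1"], "species": ["A"], "r_da": [mean_r], "dr_da": [3.0],
}))
ranking = st.screen_structures(
    {"this_geometry": {"DA1": mean_r}, "alternative": {"DA1": mean_r + 15.0}}, measured
)
print(ranking[["structure", "species", "chi2", "rank"]].to_string(index=False))
# chi^2 = 0 for the generating geometry; the 15 A-off alternative pays
# ((15/3)^2 = 25) per pair
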