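"""Simulate diffusing-molecule photon bursts and compute MFD indicators.

A static E = 0.5 species with realistic crosstalk and background is
simulated, bursts are found by the sliding-window search, corrected
per-burst E and fluorescence-weighted lifetimes are computed, and the
population centroid is compared against the static FRET line.
"""

import numpy as np

from chromofret import burst as bm
from chromofret import kinetics as kin
from chromofret import synthetic as syn

pair = kin.ALEXA568_647
species = kin.FRETSpecies("stacked", pair, efficiency=0.5)
model = kin.KineticModel([species], np.zeros((1, 1)))
calib = syn.CalibrationConfig(alpha=0.05, background_donor=800, background_acceptor=600)
stream, truth = syn.simulate_bursts(
    model, syn.ConfocalSimConfig(burst_count=1500, seed=7, calibration=calib)
)
print(f"simulated {len(stream)} photons over {stream.duration:.1f} s")

bursts = bm.analyze_bursts(stream, calib, pair, window=500e-6,
                           min_photons_in_window=15, min_total_photons=60)
es = np.array([b.efficiency for b in bursts if b.mean_lifetime is not None])
taus = np.array([b.mean_lifetime for b in bursts if b.mean_lifetime is not None])
print(f"{len(bursts)} bursts; mean E = {es.mean():.3f} (truth 0.5), "
      f"mean <tau>_F = {taus.mean():.2f} ns (truth {pair.donor_lifetime * 0.5:.2f})")

line = bm.static_fret_line(pair)
offset = abs(es.mean() - line.efficiency(taus.mean()))
print(f"centroid offset from the static FRET line: {offset:.4f} in E")
# a conformationally static population sits on the static line; exchange
# during a burst would displace it toward a dynamic FRET line
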