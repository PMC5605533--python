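"""Locate dynamical-transition temperatures in an elastic-intensity scan.

The elastic intensity of a hydrated sample decreases with temperature; slope
breaks mark the onset of anharmonic surface-water dynamics (~220 K) and the
melting of interfibrillar confined water (~260 K).  Segmented regression
with information-criterion model selection recovers both breakpoints, and
the Gaussian approximation converts the Q dependence into a mean-square
displacement.
"""

import numpy as np

import fibrilwater as fw
from fibrilwater import synthetic as syn

q = np.array([0.5, 0.6, 0.7, 0.8, 0.9])
scan = syn.generate_elastic_scan(q, np.arange(10.0, 291.0, 5.0),
                                 transition_temps=(220.0, 260.0),
                                 noise=0.01, seed=7)

for temperature, unc in fw.detect_transitions(scan, max_transitions=2):
    print(f"transition at {temperature:.0f} +/- {unc:.0f} K")

msd, err = fw.msd_from_elastic(scan, temperature=250.0, q_window=(0.5, 0.9))
print(f"MSD(250 K) from ln S_el vs Q^2: {msd:.3f} +/- {err:.3f} A^2")
print("(the synthetic scan has no Q dependence, so the MSD is ~0 here;"
      " see water_populations.py for a physical MSD)")
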