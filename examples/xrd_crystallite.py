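"""Diffraction analysis: pseudo-Voigt peak fits, Bragg spacings, Scherrer
crystallite size, and the interfibrillar gap.

The four cellulose-I reflections are fitted simultaneously; the 110 peak
width gives the microfibril cross-section (~50 A), and subtracting it from
the SANS repeat distance (~67 A) leaves the ~17 A water-filled gap between
neighbouring microfibrils.
"""

import fibrilwater as fw
from fibrilwater import synthetic as syn
from fibrilwater.xrd import peak_report

pattern = syn.generate_xrd_pattern(noise=0.01, seed=14)
init = [{"hkl": p["hkl"], "center": p["center"]}
        for p in syn.CELLULOSE_XRD_PEAKS]
peaks, background = fw.fit_diffraction_peaks(pattern, init)

print(peak_report(peaks).round(3).to_string(index=False))

p110 = next(p for p in peaks if p.hkl == "110")
width = fw.scherrer_size(p110)
gap, gap_err = fw.interfibril_gap(67.0, width, 0.6, 1.0)
print(f"\ncrystallite width (110): {width:.1f} A")
print(f"interfibrillar gap: 67.0 - {width:.0f} = {gap:.1f} +/- {gap_err:.1f} A")
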