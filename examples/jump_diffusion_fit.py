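"""Extract the translational diffusion coefficient of bound water from
synthetic QENS spectra, end to end.

For each temperature: simulate spectra whose narrow line width follows the
jump-diffusion dispersion, fit the spectral model per Q, then fit
Gamma(Q) = (hbar/tau0) [1 - 1/(1 + D Q^2 tau0)] up to Q = 0.9 1/A.  The
printed D (1e-10 m^2/s), residence time tau0 (ps) and jump length
l = sqrt(6 D tau0) (nm) should recover the generating values
(D = 0.86 at 250 K, 1.77 at 265 K; l = 0.27 and 0.34 nm).
"""

import numpy as np
import pandas as pd

import fibrilwater as fw
from fibrilwater import synthetic as syn

rows = []
for temperature, seed in [(250.0, 42), (265.0, 43)]:
    truth = syn.basis_like_truth(temperature, noise=0.01, seed=seed)
    spectrum = syn.generate_qens_spectrum(
        truth, np.arange(0.3, 0.95, 0.1), np.arange(-100.0, 100.25, 0.5))
    fit = fw.fit_spectrum(spectrum, fw.ResolutionModel(fwhm=3.5))
    jd = fw.fit_jump_diffusion(fit.narrow_component(), q_max=0.9)
    rows.append(jd.to_row(temperature))

print(pd.DataFrame(rows).round(3).to_string(index=False))
print("\nD in 1e-10 m^2/s; bound water diffuses ~100x slower than bulk water.")
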