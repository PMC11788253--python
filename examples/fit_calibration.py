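"""Fit the OD-to-dose calibration curve from a nine-film dose series.

Each calibration film receives one dose level (0-50 Gy); its net optical
density is read from the time-resolved setup.  Here the (OD, dose) points
are generated from the package's reference curve so the fit can be checked
against known ground truth.
"""

import numpy as np

from trfd import REFERENCE_CALIBRATION, fit_od_to_dose, invert_calibration

dose_levels = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 50.0])
od_net = invert_calibration(dose_levels, REFERENCE_CALIBRATION)

fit = fit_od_to_dose(od_net, dose_levels)
print("dose levels [Gy]:", dose_levels)
print("net OD:          ", np.round(od_net, 4))
print(f"fit: D = {fit.a:.3e} + {fit.b:.3f}*OD + {fit.c:.3f}*OD^{fit.m:.3f}")
print(f"residual RMS: {fit.rms:.2e} Gy")
# a is the (small, negative) intercept; b the linear Gy/OD slope; the power
# term c*OD^m captures the film's saturation bend at high dose.
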