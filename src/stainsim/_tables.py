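"""Embedded standard colorimetric tables.

Published CIE values at 10 nm spacing over 400-700 nm: the relative spectral
power distribution of standard illuminant D65 (normalised to 100 at 560 nm)
and the CIE 1964 10-degree standard colorimetric observer colour-matching
functions.  Both are linearly resampled onto the working wavelength grid at
load time; the 10 nm spacing is ample for these smooth curves.
"""

import numpy as np

# wavelength_nm, D65 relative power, x10bar, y10bar, z10bar
_CIE_TABLE = np.array([
    [400.0,  82.75, 0.0191, 0.0020, 0.0860],
    [410.0,  91.49, 0.0847, 0.0088, 0.3894],
    [420.0,  93.43, 0.2045, 0.0214, 0.9725],
    [430.0,  86.68, 0.3147, 0.0387, 1.5535],
    [440.0, 104.86, 0.3837, 0.0621, 1.9673],
    [450.0, 117.01, 0.3707, 0.0895, 1.9948],
    [460.0, 117.81, 0.3023, 0.1282, 1.7454],
    [470.0, 114.86, 0.1956, 0.1852, 1.3176],
    [480.0, 115.92, 0.0805, 0.2536, 0.7721],
    [490.0, 108.81, 0.0162, 0.3391, 0.4153],
    [500.0, 109.35, 0.0038, 0.4608, 0.2185],
    [510.0, 107.80, 0.0375, 0.6067, 0.1120],
    [520.0, 104.79, 0.1177, 0.7618, 0.0607],
    [530.0, 107.69, 0.2365, 0.8752, 0.0305],
    [540.0, 104.41, 0.3768, 0.9620, 0.0137],
    [550.0, 104.05, 0.5298, 0.9918, 0.0040],
    [560.0, 100.00, 0.7052, 0.9973, 0.0000],
    [570.0,  96.33, 0.8787, 0.9556, 0.0000],
    [580.0,  95.79, 1.0142, 0.8689, 0.0000],
    [590.0,  88.69, 1.1185, 0.7774, 0.0000],
    [600.0,  90.01, 1.1240, 0.6583, 0.0000],
    [610.0,  89.60, 1.0305, 0.5280, 0.0000],
    [620.0,  87.70, 0.8563, 0.3981, 0.0000],
    [630.0,  83.29, 0.6475, 0.2835, 0.0000],
    [640.0,  83.70, 0.4316, 0.1798, 0.0000],
    [650.0,  80.03, 0.2683, 0.1076, 0.0000],
    [660.0,  80.21, 0.1526, 0.0603, 0.0000],
    [670.0,  82.28, 0.0813, 0.0318, 0.0000],
    [680.0,  78.28, 0.0409, 0.0159, 0.0000],
    [690.0,  69.72, 0.0199, 0.0077, 0.0000],
    [700.0,  71.61, 0.0096, 0.0037, 0.0000],
])

CIE_WAVELENGTHS_NM = _CIE_TABLE[:, 0]
D65_RELATIVE_POWER = _CIE_TABLE[:, 1]
CIE1964_XBAR = _CIE_TABLE[:, 2]
CIE1964_YBAR = _CIE_TABLE[:, 3]
CIE1964_ZBAR = _CIE_TABLE[:, 4]
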