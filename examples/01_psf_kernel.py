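"""Depth-dependent blur kernels of a tissue-like turbid medium.

Evaluates the closed-form point spread function for absorbers at
several depths and rasterises unit-sum convolution kernels.  The kernel
width grows steadily with depth — the physical signal that both
reconstruction techniques exploit.
"""

import numpy as np

from transillum3d import OpticalProperties, evaluate_psf, rasterize_kernel

optics = OpticalProperties(mu_s_prime=1.0, mu_a=0.01)   # 1/mm, tissue-like
print(f"effective attenuation kappa_d = {optics.kappa_d:.6f} /mm")
print(f"PSF value on the axis at depth 5 mm: "
      f"{evaluate_psf(0.0, 5.0, optics):.6f} (arbitrary units)\n")

print("depth [mm]   kernel size [px]   kernel FWHM [mm]")
for depth in [1.0, 2.0, 5.0, 10.0]:
    kernel = rasterize_kernel(depth, optics, 0.2, support_radius_mm=40.0,
                              strict=False)
    print(f"{depth:8.1f}   {kernel.values.shape[0]:14d}   "
          f"{kernel.fwhm():14.2f}")

print("\nThe FWHM roughly doubles from 2 to 5 mm depth: image blur is a"
      "\nusable depth gauge, which is the premise of this package.")
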