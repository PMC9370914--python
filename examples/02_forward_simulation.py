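"""Forward simulation: phantom -> blurred image -> sensor noise ->
background removal.

Builds the inclined-cylinder phantom (3 mm diameter, 5 degrees from the
vertical, depths 2.2 to 5.0 mm), blurs it with the depth-dependent PSF,
adds 21 dB sensor noise, and divides out a synthetic vignette the way a
real measurement divides by the absorber-free reference image.
"""

import numpy as np

from transillum3d import (ImageGrid, OpticalProperties, TransilluminationImage,
                          add_noise, blur_image, make_cylinder_phantom,
                          remove_background)

optics = OpticalProperties(1.0, 0.01)
grid = ImageGrid(360, 640, 0.1)          # 36 x 64 mm at 0.1 mm/px

phantom = make_cylinder_phantom(diameter=3.0, length=30.0, tilt_deg=5.0,
                                depth_top=2.2, depth_bottom=5.0, grid=grid)
image = blur_image(phantom, optics)
noisy = add_noise(image, snr_db=21.0, seed=1)

yy, xx = np.mgrid[0:360, 0:640]
vignette = 1.0 - 0.25 * ((yy - 180) ** 2 + (xx - 320) ** 2) / 320**2
measured = TransilluminationImage(noisy.values * vignette, grid)
reference = TransilluminationImage(vignette, grid)
flat = remove_background(measured, reference)

top = image.values[40]          # a shallow slice (depth ~2.2 mm)
bottom = image.values[320]      # a deep slice (depth ~5.0 mm)
cm = lambda row: (row.max() - row.min()) / (row.max() + row.min())
print(f"occupied pixels: {phantom.occupancy.sum()}, "
      f"true depth range: {np.nanmin(phantom.true_depth):.2f}-"
      f"{np.nanmax(phantom.true_depth):.2f} mm")
print(f"Michelson contrast, shallow end: {cm(top):.3f}")
print(f"Michelson contrast, deep end:    {cm(bottom):.3f}")
print(f"background level after removal:  "
      f"{np.median(flat.values[:, :100]):.4f} (should be ~1)")
print("\nContrast drops as the bar recedes into the medium — exactly the"
      "\ndepth cue the lookup-table estimator inverts.")
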