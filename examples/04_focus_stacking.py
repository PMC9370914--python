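"""Focus stacking: depth map + all-in-focus image from a single frame.

Simulates a 3 mm bar at 5 mm depth on a 128 mm field, deconvolves it at
31 hypothesis depths, scores every 9x9 window with the gray-level
variance focus function, and fuses the stack with selectivity-gated
weights.
"""

import numpy as np

from transillum3d import (ImageGrid, OpticalProperties, blur_image,
                          estimate_depth_map, make_cylinder_phantom)

optics = OpticalProperties(1.0, 0.01)
grid = ImageGrid(256, 256, 0.5)               # 128 x 128 mm field

phantom = make_cylinder_phantom(3.0, 140.0, 0.0, 5.0, 5.0, grid,
                                top_row_mm=-1.0)
image = blur_image(phantom, optics, max_kernel_radius_mm=127.5)

result = estimate_depth_map(image, optics)
on_bar = phantom.occupancy & result.depth_map.valid
depths = result.depth_map.depth[on_bar]
print(f"hypothesis depths: {len(result.stack.depths)} "
      f"({result.stack.depths[0]} ... {result.stack.depths[-1]} mm)")
print(f"valid windows over the absorber: {on_bar.sum()}"
      f" / {phantom.occupancy.sum()}")
print(f"median estimated depth: {np.median(depths):.2f} mm (true 5.0)")
print(f"windows within one grid step of the truth: "
      f"{np.mean(np.abs(depths - 5.0) <= 1.0):.1%}")
amp_blur = 1 - image.values[128, 128]
amp_fused = 1 - result.fused.values[128, 128]
print(f"dip amplitude, blurred input: {amp_blur:.3f}; fused: "
      f"{amp_fused:.3f}")
print("\nThe fused image restores most of the contrast the scattering"
      "\ndestroyed, and the per-window focus peak localises the bar's"
      "\ndepth to within one hypothesis step.")
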