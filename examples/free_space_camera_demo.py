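"""Tissue-to-CCD imaging demo: render four camera views of the cube phantom.

Repeats the cube bioluminescence run, converts the 300x300 per-face exit
grids into a surface flux map (weight / mm^2 per cell), and images it
through four thin-lens cameras placed at 0/90/180/270 degrees around the
phantom.  The four image totals agree within counting noise (the scene is
statistically symmetric about the camera ring), and a line profile across
one image peaks at the projection of the buried source.
"""

import numpy as np

from photonmc import (
    builtin_example,
    build_cameras,
    build_scene,
    extract_line_profile,
    normalize_profile,
    render_detector,
    run_config,
    surface_flux_map,
)

config = builtin_example("blt_cube")
result = run_config(config, n_photons=50_000)
flux = surface_flux_map(result, source="face_grid")
scene = build_scene(config).compile()

print("rendered CCD totals (flux density summed over pixels):")
images = []
for cam in build_cameras(config):
    img = render_detector(flux, cam, scene)
    images.append(img)
    print(f"  view {cam.view_angle_deg:5.1f} deg: {img.total():.4e}")

profile = normalize_profile(
    extract_line_profile(images[0].pixels, (10, 60), (110, 60), 80,
                         pitch_mm=images[0].pitch_mm)
)
peak_mm = profile.positions[np.argmax(profile.values)]
print(f"\nvertical profile through view 0: peak at {peak_mm:.2f} mm along the line")
print("(the source sits 3 mm below the +z face, so the bright spot is off-center).")
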