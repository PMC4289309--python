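# Example run configuration for the sprimage CLI.
#
# Conventions: wavelengths and layer thicknesses in nm, image coordinates
# and pixel size in μm, angles in degrees.  Circle ROIs are (cx, cy, radius)
# in μm from the image's top-left corner; pixel centers sit at
# (index + 0.5) * pixel_size.

stack:
  layers:
    - {name: glass, n: 1.78}                       # high-index coverslip
    - {name: gold, material: gold, thickness_nm: 45.0}
    - {name: water, material: water}

# Built-in dispersion tables ("gold", "water") can be replaced here, e.g.:
# dispersion_tables:
#   gold: {name: my-table, wavelength_nm: [450, 750], n: [1.4, 0.16], k: [1.9, 4.7]}

imaging:
  wavelength_nm: 620.0
  pixel_size_um: 0.1
  image_shape: [320, 320]          # (rows, columns)
  noise_sigma: 0.02                # reflectance units per frame
  frames_to_average: 4
  operating_reflectance: 0.1       # operating point, shallow of the minimum
  na: 1.65
  psf: {fwhm_x_um: 0.30, decay_y_um: 0.4543}

wavelengths_nm: [480, 515, 550, 590, 620, 670]

beads:
  - radius_um: 3.05
    refractive_index: 1.42
    center_um: [16.0, 16.0]
    material: silica
    roi_radius_um: 3.5

analysis:
  threshold_k: 3.0                 # detection threshold in background σ
  dilation_um: 10.0                # annulus: ROI diameter dilated by this

bfp:
  na: 1.65
  n_immersion: 1.78
  radius_px: 200
  center_px: [200, 200]
  max_angle_deg: 60.0

crescent:
  radial_width_deg: 2.0
  azimuthal_span_deg: 40.0
  azimuth_center_deg: 0.0
  # center_angle_deg defaults to the computed operating angle
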