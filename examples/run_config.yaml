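# Full pipeline run on a recorded TIFF stack.
#
#   spheroidquant run --config examples/run_config.yaml
#
# Calibration is mandatory for TIFF input: the analysis is in physical
# units and microscope metadata is never trusted.

out_dir: results/example_run
seed: 1

tiff_paths:
  - data/spheroid_central_slices.tif
calibration:
  xy_size: 1.0      # µm per pixel, isotropic in-plane
  z_step: 10.0      # µm between slices
depth_offset: 120.0 # µm of slice 0 below the upper spheroid border

segmentation:
  gaussian_sigma: 1.5           # µm
  phansalkar_window_radius: 15  # px
  median_radius: 3              # px
  min_area: 45.0                # µm²
  max_area: 700.0               # µm²

# zone boundaries: an ImageJ .roi/.zip or JSON polygon file with
# 'core_rim' and 'rim_invasion' entries; alternatively set zone_radii
# (circles about the image center) or leave both out for auto mode
roi_path: data/zones.json

restrict_invasion_to_quadrant: true
annotations_path: data/mitoses.csv   # optional manual mitosis table

snr_threshold: 5.0
# snr_background: [0, 86, 0, 86]    # row0, row1, col0, col1 (default: corner)
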