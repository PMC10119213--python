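# spheroidquant

Quantification of 3D tumor-spheroid invasion cultures from
nuclear-reporter (H2B-GFP-like) confocal z-stacks.

Multicellular spheroids embedded in collagen reorganize within days into
a residual cell-dense **core**, a compact concentric **rim** at the
former spheroid–matrix interface, and an **invasion zone** of
individually migrating cells. Radiotherapy-style perturbations change
these compartments differently — invading cells are depleted and die by
apoptosis while core and rim are largely spared — so image-based readouts
must be *zonal*. Deep imaging of such specimens additionally depends on
optical clearing (refractive-index matching), whose benefit is best
expressed as signal-to-noise ratio versus imaging depth.

`spheroidquant` provides, as a tested Python library plus CLI:

- **Nucleus segmentation per z-slice**: Gaussian blur (σ = 1.5 µm,
  physical units) → Phansalkar local adaptive threshold,
  t = m·(1 + p·e^(−q·m) + k·(s/r − 1)) over a disc window → binary
  median filter (radius 3 px) → watershed separation on the distance
  transform → area filter (45–700 µm²), with sub-floor objects retained
  as fragment candidates.
- **Zonal geometry**: core/rim/invasion partition from user-drawn
  boundary polygons (ImageJ `.roi`/`.zip` or JSON) straightened to
  moment-equivalent ellipses, or estimated from the radial intensity
  profile; seeded random analysis quadrant; radial migration distances.
- **Event readouts**: apoptosis as clusters (single linkage, 20 µm) of
  3–25 µm² nuclear fragments, ≥ 2 fragments per event;
  death_frequency = events/(events + intact nuclei) per zone; mitosis
  frequencies from manual annotation tables; per-zone count tables; an
  exact small-sample Mann–Whitney U test for group comparisons.
- **SNR-depth profiling**: per-slice (I_mean − B_mean)/SD_mean with
  I_mean the mean of the brightest 5% of pixels, and the greatest depth
  that stays above a segmentability threshold.
- **A synthetic spheroid generator** (core/rim/invading geometry,
  apoptotic fragment clouds, mitotic figures, Beer–Lambert depth
  attenuation, PSF, shot + read noise) with exported ground truth, so
  every stage above is validated by parameter recovery.

## Worked example

Simulate a cleared control spheroid and quantify it end to end:

```sh
spheroidquant run --simulate control --seed 1 --out results/demo
```

This writes `stack.tif`, the ground truth, `nuclei.csv`,
`zone_summary.csv`, `snr_profile.csv`, `run_metadata.json` and a
`manifest.json`. From the Python API:

```python
from spheroidquant import preset, simulate_spheroid, SegmentationParams, segment_stack

params = preset("control", seed=1)          # 1600 cells, 3 slices, cleared optics
stack, truth = simulate_spheroid(params)
nuclei, fragments = segment_stack(stack, SegmentationParams())
print(len(nuclei))                          # -> 221 segmented nuclei
```

221 nuclei from a 1600-cell scene is expected: the three central slices
(10 µm apart) only see cells within ~10 µm of a plane. Matched against
the ground truth under that visibility convention, the pipeline scores
precision 1.00 and recall 0.98 on this seed.

A two-arm comparison (`analysis/02_segment_and_quantify.py`, six
simulated spheroids per arm, the treated arm with half the invading
cells, a 100 µm shorter front and 8% invasion-zone apoptosis) prints:

```
control seed 0: zones {'core': 66, 'rim': 102, 'invasion': 32}, death 0.059, max dist 336 µm
irradiated seed 0: zones {'core': 86, 'rim': 99, 'invasion': 11}, death 0.214, max dist 211 µm
...
Mann-Whitney invasion counts control vs irradiated: U=36, p=0.0022 (exact enumeration)
```

— invasion-zone counts drop by roughly half while core and rim counts
are unchanged, and the exact rank test flags the contrast from n = 6 per
arm. The clearing analysis (`analysis/03_clearing_snr.py`) prints a
segmentable depth of 54 µm for uncleared optics (attenuation length
25 µm) versus 228 µm cleared (500 µm), a 4.2× depth gain at the same
segmentation threshold.

## Analysis drivers

Numbered scripts under `analysis/` re-run the package's canonical
experiments and write their tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_scenes.py` | export control / irradiated / uncleared / cleared scenes with ground truth |
| `02_segment_and_quantify.py` | full pipeline on both arms + Mann–Whitney comparison |
| `03_clearing_snr.py` | SNR-depth profiles and the clearing depth gain (CSV + figure) |
| `04_treatment_contrast.py` | multi-seed treated/control count ratios and death-frequency recovery |

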