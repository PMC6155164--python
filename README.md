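# nanofoci

Quantitative analysis of DNA-damage repair foci in multi-channel
single-molecule localization microscopy (SMLM/STORM) data.

When a replication fork collides with a lesion it collapses into a
single-ended double-strand break that is repaired by homologous
recombination. In super-resolution images of such cells, each repair site
appears as a nascent-DNA (naDNA) focus surrounded by clusters of repair
proteins (γH2AX, MRE11, RPA, RAD51, RAD52, BRCA1/2, ...). `nanofoci` turns
multi-channel localization tables into per-nucleus, per-protein statistics:

- **Localization** — 2D Gaussian PSF fitting of raw frame stacks, accepting
  only spots with FWHM ≤ 640 nm and signal-to-noise ratio > 3 (SNR = fitted
  amplitude / background s.d., background measured on a 2 × 2 µm window at
  each frame's minimum-intensity pixel).
- **Chromatic registration** — a degree-3 bivariate polynomial morph map
  fitted on matched fiducial-bead localizations aligns the color channels
  (typical residuals of a few nm; < 10 nm mapping error at 3 nm bead noise).
- **Rendering & segmentation** — localizations are binned onto a 20-nm pixel
  grid, restricted to a manually outlined nucleus ROI, thresholded per
  channel with Otsu's method, and labeled into 8-connected clusters.
- **Monte Carlo colocalization** — for a channel pair, the clusters of the
  protein channel are rigidly redistributed to uniform random positions
  inside the nucleus ROI; the observed overlap (count or area) is ratioed to
  the mean of 20 such randomizations:

  ```
  C = O_real / ⟨O_sim⟩,   ⟨O_sim⟩ = (1/20) Σᵢ O_simᵢ
  ```

  C = 1 means the overlap expected by chance alone; C = 2 means twice
  random. This normalizes for nuclear area and cluster density, so C is
  comparable across cells, timepoints, and treatments.
- **Focus classification & intrafoci distances** — naDNA clusters with
  associated protein clusters become focus records; a protein pair is
  classified per focus (A-only / B-only / both), and at double-positive foci
  the distance between the two proteins' centers of mass is measured. The
  distance histogram is fitted with a single Gaussian, or a double Gaussian
  whose first component is fixed at the 135 nm / 75 nm FWHM reference (the
  distribution measured for double-labeled RAD51, i.e. maximal physical
  association). A single center within 135 ± 37.5 nm is *proximal*, beyond
  180 nm *distal*, and accepted double fits are *mixed*.
- **Synthetic scenes** — a seeded generator produces nuclei with known
  ground truth (focus classes, cluster–focus links, displacement model,
  bead-field warps, raw frames), used throughout the test suite to validate
  every stage against truth.

## Worked example

```python
import numpy as np
import nanofoci as nf
from nanofoci.synthetic import SceneConfig, generate_nucleus_scene

# one synthetic nucleus: 50 naDNA foci, 50 RPA clusters, 60% colocalized
scene = generate_nucleus_scene(SceneConfig(seed=7, colocalized_fraction=0.6))
grid = scene.roi.default_grid(pixel_nm=20.0)
nadna = nf.segment_channel(nf.render(scene.locs, grid, channel="naDNA"), scene.roi)
rpa = nf.segment_channel(nf.render(scene.locs, grid, channel="RPA"), scene.roi)
res = nf.colocalization_coefficient(nadna, rpa, scene.roi, n_sims=20, seed=1)
print(f"clusters: naDNA={len(nadna)} RPA={len(rpa)}")
print(f"area coefficient = {res.coefficient_area:.2f} "
      f"(real {res.area_real_nm2:.0f} nm², sim mean {np.mean(res.sim_areas_nm2):.0f} nm²)")
```

prints

```
clusters: naDNA=80 RPA=67
area coefficient = 8.80 (real 4400 nm², sim mean 500 nm²)
```

With 60% of RPA clusters attached to naDNA foci the observed overlap is ~9×
the random expectation — strong colocalization. Rebuilding the same scene
with `colocalized_fraction=0.0` gives a coefficient near 1 (random).

The same pipeline is available from the shell:

```bash
nanofoci simulate --seed 7 --out scene/
nanofoci coloc --locs scene/localizations.csv --roi scene/roi.geojson \
    --randomize-channel RPA --n-sims 20 --mode area --out coloc.json
nanofoci foci --locs scene/localizations.csv --roi scene/roi.geojson \
    --pair RPA,RAD51 --bin-nm 10 --out foci.json
```

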