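# conemetrics

Quantitative analysis of the cone photoreceptor mosaic for high-resolution
retinal imaging, with agreement statistics for comparing graders and
imaging devices.

Adaptive-optics ophthalmoscopes resolve individual cone photoreceptors, and
newer non-AO scanning-laser modules can do so too in eyes with good optics.
Comparing the two requires a full measurement chain: deriving the image
scale from ocular biometry, registering and averaging frame stacks, marking
cone centres, computing mosaic metrics on co-localized regions of interest,
and quantifying how well two graders or two devices agree. `conemetrics`
implements that chain as a tested library plus a thin CLI, together with a
synthetic-data generator so every stage can be validated without access to
clinical images.

## The metrics

For cone coordinates in a 200 × 200 µm region of interest (ROI):

- **Bound cone density** — tessellate all points with a Voronoi diagram; a
  cell is *bound* if it is finite and lies entirely inside the ROI; density
  is `n_bound / Σ(bound cell areas)` in cones/mm². For a hexagonal mosaic
  of spacing *s* this equals `2/(√3·s²)` exactly.
- **NND** — mean nearest-neighbour distance over points in the ROI (µm).
- **ICD** — mean, over bound cells, of the mean distance to each cell's
  Voronoi neighbours (µm).

Image scale comes from the scan geometry and the eye's axial length AL,
using a retinal magnification factor of 291 µm/deg for a 24.0 mm reference
eye: `scale = (θ/I_s)·291·(AL/24)` µm/px for a scan of θ degrees over
`I_s` pixels (an analogous Ronchi-calibration form covers AO scanners).

Agreement between paired measurements uses the one-way random-effects
intraclass correlation with its F-based 95% CI, Bland–Altman bias and
limits of agreement (bias ± 1.96·SD) with confidence intervals, percent
bias relative to the grand mean, difference-vs-covariate regression, and a
t-quantile minimum-detectable-difference power computation.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from conemetrics import (ROI, GraderModel, compute_metrics, generate_mosaic,
                         simulate_grader)

# a 260x260 µm patch of mosaic at 12,375 cones/mm² with 0.5 µm jitter
mosaic = generate_mosaic(12375, (260, 260), jitter_sd=0.5, seed=42)
roi = ROI(origin=(30, 30), size=(200, 200))

m = compute_metrics(mosaic.points, roi)
print(f"density {m.bound_density:.0f} cones/mm², "
      f"NND {m.nnd_mean:.2f} µm, ICD {m.icd_mean:.2f} µm, "
      f"bound cells {m.n_cones_bound}")

# two simulated graders mark the same patch
marks = [simulate_grader(mosaic.points,
                         GraderModel(jitter_sd=0.5, miss_rate=r, seed=s),
                         field_size=mosaic.field_size)
         for r, s in ((0.02, 1), (0.05, 2))]
dens = [compute_metrics(pts, roi).bound_density for pts in marks]
print(f"grader densities: {dens[0]:.0f} vs {dens[1]:.0f} cones/mm²")
```

Output:

```
density 12366 cones/mm², NND 8.78 µm, ICD 9.69 µm, bound cells 429
grader densities: 12163 vs 11717 cones/mm²
```

The jitter-free closed form would give exactly 12,375 cones/mm² and
spacing 9.66 µm; positional jitter leaves density essentially unchanged
while pulling mean NND below the lattice spacing (jitter only ever brings
nearest neighbours closer on average). The two graders read lower than
truth in proportion to their miss rates.

The full simulated device-comparison study (mosaics at sampled
eccentricities, two modalities, two graders, ICC + Bland–Altman +
regressions) runs from the CLI:

```bash
cma run-study --seed 1 --outdir study_out
cma verify-paper          # recompute published summary arithmetic
cma scale --mode hmm --theta 8 --pixels 768 --axial-length 24.6
```

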