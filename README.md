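# nanoshape

Statistical shape-ensemble analysis for branched nanoparticles.

Syntheses of anisotropic metal nanoparticles — the "stars", "flowers" and
"urchins" of colloidal chemistry — never produce one shape; they produce a
*distribution* of individually varying shapes. Because biological responses
are sensitive to nanoscale shape, comparing such syntheses (or searching
through them for a biologically interesting one) requires treating each
batch as a statistical ensemble: measuring its typical shape, its
dispersity, and whether two batches are statistically distinguishable at
all. `nanoshape` provides that toolkit for anyone working from 2D
projected particle outlines (TEM micrographs or pre-digitized contours),
plus a parametric shape generator so every stage can be exercised without
instrument data.

## Method

1. **Contour digitization.** Particles are segmented from a bright-field
   image (global Otsu threshold, hole filling, border/area filtering) and
   their outer boundaries traced at subpixel resolution, then resampled to
   N = 1024 equally spaced points starting from a canonical point (the
   vertex farthest from the centroid).
2. **Fourier shape descriptor.** Each contour's radial signature
   r(t) — the centroid-to-boundary distance — is Fourier transformed
   (forward 1/N convention), and the particle is represented by the
   one-sided normalized amplitude spectrum
   *a*<sub>k</sub> = 2|c<sub>k</sub>|/c<sub>0</sub>, k = 1..K (K = 512).
   The vector is invariant to translation, rotation, uniform scale and
   start point; a perfect circle maps to **0**.
3. **PCA shape space.** PCA on the pooled feature matrix of the ensembles
   under comparison (centering only, deterministic sign convention) ranks
   the correlated shape features. Each particle is a point in the leading
   m = 3 components; each ensemble has a center of gravity (typical
   shape), a 95% confidence ellipse (semi-axes √(λ<sub>i</sub>
   χ²<sub>2,0.95</sub>)), and a dispersity PDF — the KDE of particle
   distances to the center of gravity.
4. **Overlap coefficient.** Two ensembles are compared by projecting both
   onto the line joining their centers of gravity and integrating the
   pointwise minimum of the two Gaussian-KDE densities:
   OVL = ∫ min(f, g) dx ∈ [0, 1], the fraction of particles common to
   both. OVL ≤ 0.05 (configurable) declares the ensembles independent
   shapes.
5. **Shape discovery.** A coordinate-ascent loop perturbs generator
   parameters step by step, backtracks (halving the step) when a jump is
   discontinuous (OVL with the previous ensemble below 0.01), and spends a
   biological readout — here a surrogate Gaussian-bump landscape over
   shape space — only when the candidate is independent of the last
   ensemble assayed. The run distills into a structure–function table of
   pairwise-independent ensembles with their readouts.

## Worked example

```bash
python examples/02_overlap_independence.py
```

```
OVL(star-1, star-2) = 0.9429  centroid distance 0.001  -> same shape population
OVL(star-1, urchin-3) = 0.0063  centroid distance 0.054  -> independent shapes
```

Two replicate star syntheses share ~94% of their shape distribution —
statistically the same population — while star vs urchin overlap by less
than 1%, far under the 0.05 independence threshold. The other examples
build the three-family shape space (`01`), run the full image pipeline on
rendered micrographs, recovering the 12-fold spike symmetry for every
particle (`03`), and run the gated discovery loop (`04`), which climbs
from readout 0.135 to 0.968 at its best assayed ensemble while spending
only 4 readouts in 15 synthesis steps.

The command line mirrors the workflow:

```bash
nanoshape simulate --preset star --n 200 --seed 7 --out sim/
nanoshape describe --contours sim/star_contours.csv --out features.csv
nanoshape space features_a.csv features_b.csv --m 3 --out space/
nanoshape overlap --a features_a.csv --b features_b.csv --out overlap.json
```

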