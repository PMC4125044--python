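# divplane

Quantitative analysis of **division-plane placement** and
**divisome / nucleoid / Ter-macrodomain co-localization** in rod-shaped
bacteria (*Escherichia coli*-like geometry), from multichannel
fluorescence micrographs — with a matched synthetic-microscopy generator
so that every estimator can be validated by parameter recovery on known
ground truth.

The package is aimed at microbiologists and image analysts who quantify
where cells divide and how the cytokinetic Z-ring is positioned relative
to chromosomal landmarks, and at methods developers who need a controlled
test bed for such pipelines.

## What it computes

Given images with a cytosolic reporter, a DAPI-like nucleoid stain, a
ZipA/FtsZ-like ring label, and a MatP-like Ter focus label:

- **Geometry** — cell segmentation, medial axis, length *L*, per-channel
  intensity line profiles along the axis, and constriction (waist)
  detection in adhered daughter pairs.
- **Localization** — axial displacements from the cell center:
  ΔX_n (nucleoid center, intensity-weighted centroid of the supra-threshold
  extent), ΔX_z (Z-ring, Gaussian peak fit), ΔX_MatP (Ter focus), plus
  compact/bilobed nucleoid and central/polar ring classification.
- **Division statistics** — daughter volume fractions
  v = V₁/(V₁+V₂) of adhered pairs by a solid-of-revolution estimator;
  maximum-likelihood decomposition of the v histogram into Gaussian peaks
  **fixed at 1/4, 1/3, 1/2, 2/3, 3/4** plus a uniform component (mirrored
  weights tied); division frequency vs mother length at 0.25 µm bins with
  a center→quarter transition length.
- **Co-localization statistics** — σ(ΔX_z − ΔX_n), σ(ΔX_z), σ(ΔX_z −
  ΔX_MatP) in nm; the goodness of fit R² = 1 − Σ(ΔX_z − ΔX_n)²/Σ(ΔX_z −
  mean)² of the fixed model ΔX_z = ΔX_n; a one-sided **Ansari-Bradley**
  rank dispersion test (exact by enumeration for pooled n ≤ 20, tie-corrected
  normal approximation otherwise) and the variance-ratio F test; and
  Z-ring occupancy of new (N, nucleoid-center) vs old (O, inter-nucleoid)
  division sites in multi-nucleoid cells with replicate SDs.
- **Time-lapse** — kymographs of one cell over its cycle, midcell arrival
  times of the Ter focus (t_MatP) and the ring (t_z) by threshold crossing
  of the rescaled midcell-window signal, the lag (t_z − t_MatP)/T_d with
  population statistics, and midcell accumulation curves with standard
  errors.

The `synthgen` subpackage renders all of the above from analytic emitter
densities (spherocylinder chords, Gaussian nucleoid blobs, transverse ring
bands, PSF-sized foci) with Poisson + read noise, and returns the ground
truth next to every image.  See `docs/methods.md` for models, defaults,
and numerical choices.

## Worked example

Generate 200 synthetic single-nucleoid cells whose ring tracks the
nucleoid center with a 45 nm placement spread, run the full imaging +
analysis chain, and summarize co-localization:

```python
import numpy as np
from divplane.synthgen import (
    PlacementModel, ScopeConfig, sample_population, render_cell,
)
from divplane import geometry, localize, colocstats

scope = ScopeConfig()
model = PlacementModel(sigma_ring_given_nucleoid=45.0, p_polar_ring=0.0)
pop = sample_population(model, 200, seed=1)
rng = np.random.default_rng(2)
records = []
for i, truth in enumerate(pop.cells):
    img = render_cell(truth, scope, rng=rng)
    rec = geometry.segment_cells(img, flag_division_pairs=False)[0]
    geometry.extract_axis(rec, image=img)
    profiles = geometry.line_profiles(img, rec)
    records.append(localize.localize_cell(profiles, cell_id=i))

summary = colocstats.coloc_summary(records)
print(f"n = {summary.n}")
print(f"sigma(dXz - dXn) = {summary.sigma_zn_nm:.1f} nm")
print(f"sigma(dXz)       = {summary.sigma_z_nm:.1f} nm")
print(f"R^2 (dXz = dXn)  = {summary.r_squared:.3f}")
```

Output:

```
n = 200
sigma(dXz - dXn) = 41.5 nm
sigma(dXz)       = 170.0 nm
R^2 (dXz = dXn)  = 0.940
```

Reading: the recovered ring-to-nucleoid placement spread (41.5 nm) matches
the generative 45 nm within sampling error and is far smaller than the
ring's spread about the cell center (170 nm, the convolution of the 150 nm
nucleoid wander with ring placement) — the signature of a ring that
follows the nucleoid center rather than the geometric midcell.  R² close
to 1 says the fixed line ΔX_z = ΔX_n explains nearly all ring variance.

## Command line

A thin CLI wraps the library:

```sh
divplane synthgen population --seed 1 --out out/         # images + truth CSV
divplane pipeline stills     --seed 1 --out out/stills   # end-to-end run
divplane pipeline divisions  --seed 1 --out out/div
divplane pipeline timelapse  --seed 1 --out out/tl
divplane divstats --events out/div/division_events.csv --out fit.json
```

Every run writes a YAML snapshot of its configuration and a log of
per-cell exclusions, and identically seeded runs produce byte-identical
outputs.

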