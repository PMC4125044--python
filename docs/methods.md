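# Methods

`divplane` quantifies where rod-shaped bacteria place their division
machinery: how the daughter volume fraction distributes over the canonical
sites 1/4, 1/3, 1/2, 2/3, 3/4 of the mother; how tightly the Z-ring tracks
the nucleoid center and the MatP-labelled Ter macrodomain along the cell
axis; and when, within the cell cycle, the Ter focus and the ring arrive at
midcell.  Because public micrograph sets with per-cell ground truth for
these quantities do not exist, the package ships a synthetic-microscopy
generator whose draws are the reference against which every estimator is
validated.  This note records the models, the defaults, and the numerical
choices.

## Synthetic microscopy model

A cell is a spherocylinder of radius r = 0.45 µm whose centerline may be a
gentle circular arc (curvature in 1/µm; 0 = straight rod).  Emitter
densities on the pixel grid are analytic:

- **cytosolic reporter** — the projected chord `2·sqrt(h(s)² − d²)` of the
  uniformly filled body, where `h(s)` is the half-width profile (flat body,
  hemispherical caps, optionally a Gaussian waist notch for an adhered
  daughter pair) and `d` the distance to the centerline;
- **nucleoid stain** — axial Gaussian blobs (σ = 0.45 µm compact; two lobes
  of σ = 0.30 µm for a bilobed nucleoid, separation set by the requested
  relative dip depth) times the chord of a nucleoid of radius 0.8·r;
- **ring label** — a transverse band of 0.25 µm FWHM at each ring offset,
  weighted by the chord so the band spans the cell width;
- **focus label** — an isotropic Gaussian spot of σ = 80 nm per MatP focus;
- **pseudo-phase** — the inverted PSF-blurred body mask (no phase optics).

All channels are blurred with a Gaussian PSF (σ = 0.10 µm), scaled to
expected counts (`photon_scale`, default 600 counts per unit emitter
density), Poisson-sampled, and read out with additive Gaussian noise
(σ = 2 counts) over a constant background (10 counts) at 0.16 µm/px
(16 µm camera pixels at 100×).  EM-gain excess noise is not modelled; it
would roughly double the shot variance without changing any estimator.
The canvas leaves a ≥ 4 σ PSF margin, so the blurred photon count of a
noiseless channel matches the emitted density integral to better than 0.1 %.
The photon budget was fixed so that single-structure localization error
stays below ~20 nm, comfortably under the smallest placement spread
(40 nm) the statistics must resolve; at the defaults the per-structure
error is 10–20 nm and the error on per-cell displacement *differences* is
~12 nm, because the shared cell-center estimate cancels.

Placement statistics (`PlacementModel`) default to the slow-growth
double-deletion regime the analysis targets: nucleoid center
~ N(0, 150 nm) about the cell center, ring offset = nucleoid offset +
N(0, 45 nm), MatP offset = ring offset + N(0, 56 nm), an optional extra
polar ring with probability 0.05 placed uniformly at |x|/L ∈ (0.33, 0.45),
and division fractions drawn from Gaussians (σ = 0.02) at the five sites
with weights 0.75 at 1/2 and 0.065 at each quarter, the remaining 12 %
uniform.  Out-of-cell draws are resampled, not clipped — clipping would
pile mass on the poles and mimic spurious polar structures.  Division
pairs mirror v ↔ 1 − v with probability 1/2 so that, as when both
daughters are counted, the histogram is symmetric about 1/2 in
expectation.  An optional `transition_length` switches mothers longer than
the threshold to quarter-dominant site weights, emulating the shift of the
division plane to 1/4 positions in long cells.

The waist of a division pair is placed so that the *unconstricted*
cumulative solid-of-revolution volume on the pole-a side equals the drawn
fraction; the notch (depth 0.45, σ = 0.25 µm) is volume-symmetric to first
order.  The generative daughter volumes used as truth integrate the actual
constricted profile, and the 3-D voxel oracle used in tests integrates the
same analytic shape, so the two references agree to < 0.003.

### Time-lapse model

A cycle spans `T_d` frames (default 48 at 2.5 min/frame ≈ 120 min) with
exponential growth from a 2.4 µm birth length.  The generative timing
convention: `t_matp` and `t_z` are the half-rise times of the *noise-free*
midcell-window signal of the respective channel.  The ring sits at midcell
with a logistic amplitude (time constant 0.02·T_d, baseline 5 % for
diffuse unassembled label) whose half-rise is `t_z` by construction.  The
MatP focus physically travels from the old pole to midcell; its trajectory
is obtained by inverting the analytic window response so that the window
signal follows a logistic with half-rise exactly at `t_matp`.  Expressed
in units of T_d the construction is independent of the frame interval.

What the generator does **not** emulate: 3-D structure and focal drift,
photobleaching, uneven illumination, cell crowding and overlap, membrane
invagination optics at the septum, EM-gain noise statistics, and
biological heterogeneity beyond the stated Gaussians.  Passing tests
therefore demonstrate correctness of the estimators under the stated
imaging model, not robustness to every artifact of real microscopy.

## Geometry

Segmentation thresholds the cytosolic channel: Otsu's criterion seeds the
foreground, and the final outline is the level
`background + 0.15·(90th-percentile foreground − background)` — a rod's
projected intensity falls toward the membrane, and Otsu alone clips the
dim rim (the 0.15 level reproduces ground-truth mask areas within ~1 %).
Holes are filled, border-touching regions dropped, regions < 0.5 µm²
removed.  A blank image yields an empty list.  An adhered pair segments as
one region and is flagged as a division candidate when its width profile
shows a sufficiently deep waist.

The medial axis is the longest geodesic path through the skeleton,
smoothed with a Savitzky-Golay filter (window 7, quadratic — a plain
moving average measurably shortens bent cells), re-centered once by
moving each point to the midpoint of the two outline crossings along its
perpendicular (this removes the lateral pixel-quantization of the
skeleton), and extended to the poles along the end tangents up to the
outline crossing.  Where the image is available the outline used for
re-centering, pole extension, and width measurement is the sub-pixel
crossing of the smooth intensity surface rather than the binary mask edge;
the pole/width level is 0.30 of the bright-cell intensity, calibrated on
noiseless renders so that rod length and width are recovered without bias
(the binary-mask edge is quantized to the grid phase and biases lengths by
up to ±1 %).  Axis orientation is canonicalized (pole with smaller x
first) so displacement signs are deterministic.  Blob-like regions with no
usable path (e.g. disks) raise a shape error and are excluded with a log
entry.

Line profiles sample every 1 px along the axis; each value is the mean of
bilinearly interpolated pixels within `half_width` (default 0.35 µm) of
the axis point, perpendicular to it and inside the mask.  One background
per image and channel — the histogram mode of pixels outside all dilated
cell masks — is subtracted.  Width profiles use the perpendicular outline
crossings described above.  A constriction is the deepest local width
minimum outside the pole caps whose relative depth (against the higher
flanking maximum, so near-polar minicell waists are still scored against
the body width) reaches 0.15; its position is refined by a symmetric
Gaussian-notch fit, because the raw argmin is pulled sideways when the two
daughters differ in size.

## Localization

The nucleoid extent is the contiguous profile run above 20 % of the
maximum; ΔX_n is the intensity-weighted centroid minus L/2, one center per
well-separated run.  A single-nucleoid profile is **bilobed** when the
3-sample-smoothed profile has a local minimum in the central 40 % of the
extent whose relative depth against the lower flanking maximum reaches
`d_min = 0.10`; otherwise compact.  Ring and focus centers are local
maxima (prominence ≥ 0.15 and height ≥ 0.10 of the profile maximum)
refined by a single-Gaussian fit in a ±0.5 µm window, with a windowed
centroid fallback (flagged) if the fit fails.  A ring is **polar** when
|ΔX_z|/L > c_polar = 0.30, i.e. within 0.2·L of a pole; the cutoff is a
package choice exposed in the configuration.  In multi-structure cells the
principal ring is the brightest, the principal nucleoid the one nearest
that ring (ties toward lower s).

## Division statistics

The geometric volume estimator treats each daughter as a solid of
revolution about the axis, `V_i = Σ π (w/2)² ds` on its side of the waist;
the intensity estimator integrates background-subtracted cytosolic signal.
Both are reported; the geometric one is primary and agrees with 3-D voxel
integration of the generative shapes within 0.01 absolute for daughter
fractions in [0.1, 0.9].

Division classes use mirrored windows with precedence
minicell > central > quarter > third > other: central = 0.50 ± 0.10,
quarter = 0.25 ± 0.05, third = 1/3 ± 0.05 (quarter wins on overlap), and
min(v, 1−v) < 0.10 defines a minicell — the tails of the fraction
histogram motivate the small-fraction cutoff, which is exposed in the
configuration.

The site mixture is fitted by maximum likelihood (EM) with Gaussian means
fixed at the five sites plus a uniform component on (0, 1), mirrored
weights (1/4 = 3/4, 1/3 = 2/3) tied, a common width by default, 10
restarts from Dirichlet-jittered weights with a fixed seed.  Widths are
floored at 0.008 (≈ one histogram bin; hitting the floor sets a flag) and
capped at 0.06 so a "peak" cannot widen into a surrogate for the uniform
background.  ML on raw fractions avoids the bin-width dependence of a
least-squares histogram fit; window-count fractions are reported alongside
because peak-area and window-count summaries of the same data differ
slightly and both are in common use.

Frequency-vs-length curves bin mothers at 0.25 µm, mask bins with < 5
events, attach Wilson 95 % intervals, and report as the transition length
the left edge of the first bin where the quarter frequency exceeds the
central frequency with non-overlapping intervals.

## Co-localization statistics

σ values are plain sample SDs of per-cell displacement differences
(a robust variant is a one-line change; plain SD is the default).  R² is
computed against the fixed line ΔX_z = ΔX_n — no fitted slope — as
`1 − Σ(ΔX_z − ΔX_n)² / Σ(ΔX_z − mean)²`; it reaches 1 under perfect
co-localization and is negative when the fixed model fits worse than the
mean.  An OLS slope is reported for description only.  Subsets: all
single-nucleoid cells, compact-nucleoid only, central-ring only; n < 10
flags low power.  No multiple-comparison correction is applied; tests are
reported individually.

The Ansari-Bradley test scores the pooled sample 1, 2, … from both
extremes inward (midrank ties), so a compact sample collects large scores;
the one-sided alternative "a less dispersed than b" rejects for large
score sums.  Samples are median-aligned first (configurable).  For pooled
size ≤ 20 the p-value enumerates all assignments exactly; otherwise a
normal approximation with tie-corrected permutation moments and a 0.5
continuity correction is used.  Under a median-centered normal null at
n = 50 + 50 the empirical size is ≈ 0.047 at α = 0.05 (the centering makes
the test slightly conservative).  The F test is the classical variance
ratio with one- or two-sided p from the F distribution; a zero denominator
variance returns F = ∞, p = 0, flagged degenerate.

Site occupancy in multi-nucleoid cells: N sites are nucleoid centers, O
sites the midpoints between adjacent centers; a site is occupied when a
detected ring lies within w = 0.25 µm (one ring-image width, exposed in
config).  Cells with adjacent nucleoids closer than 1 µm have no definable
O site and are excluded with a log entry.  Replicate SDs come from
splitting cells into three contiguous groups of ~equal size, mirroring
repeated measurements of ~50 cells.

## Time-lapse analysis

Kymographs resample each frame's profile onto a common axial grid,
anchored at the cell center in µm (absolute mode) or normalized by L.
Frames are matched by nearest centroid; a lost track truncates the
kymograph and sets a flag.  The midcell signal is the window integral
minus the flanking level (median per unit length between 1.5 and 3
half-widths on each side) times the window size; the window half-width is
0.05·L capped at 0.15 µm absolute.  The flank correction and the cap keep
the trace of a fixed-width structure flat while the cell grows — with a
plain fractional window the plateau drifts as the window sweeps more of
the band, which biases threshold timing.  Arrival is the first time the
trace, rescaled between its 10th (baseline) and 90th (plateau)
percentiles, stays at or above θ = 0.5 for k = 2 consecutive frames, with
sub-frame linear interpolation of the crossing.  Deciles rather than
quintiles leave room for arrivals as early as ~0.1 of the observed span;
with an arrival at 0.2·T_d a quintile baseline already overlaps the rise.
These detector constants were calibrated on synthetic data (they are a
package design, not a published rule); at the defaults the recovered lag
carries a bias of about +0.017·T_d with cell-to-cell SD ≈ 0.004·T_d,
inside the ±0.03·T_d recovery target for both the 0.12·T_d and 0.02·T_d
regimes, and the two regimes separate cleanly at 15 cells each.  Lags are
reported per cell as (t_z − t_MatP)/T_d, histogrammed at 0.05·T_d.  T_d is
the birth-to-division span when the full cycle is observed, else supplied
by configuration (≈ 120 min in the emulated growth condition).
Accumulation curves rescale each cell's trace to [0, 1], normalize time by
the cell's own T_d, and average across cells with standard errors (SE
undefined and omitted for a single cell).

## Pipeline and reproducibility

`run_pipeline` executes generate → segment → localize → statistics for
three modes (stills, divisions, timelapse), writes plain CSV/JSON plus a
YAML snapshot of the full configuration and a log of per-cell exclusion
reasons; per-cell failures are logged, never fatal.  All randomness flows
from one integer seed through `numpy.random.default_rng`; identically
seeded runs are byte-identical.  Thresholds are validated against their
documented ranges before any computation.

`scripts/acceptance.py` re-runs every stage at the following problem
sizes, chosen as the package's standard desk-scale workload: 500 rendered
cells per dispersion regime (σ ∈ {40, 56, 150, 344} nm), 9 division-pair
geometries spanning v ∈ [0.1, 0.9] against a 0.02 µm voxel oracle, 2000
division events for the mixture fit, 15 time-lapse cells per lag regime,
10⁴ null simulations for the test size, 600 multi-nucleoid cells for site
occupancy, and a doubled small pipeline run for the determinism check.

## Known limitations

- Estimator validation is bounded by the generator's realism (see above);
  segmentation in particular assumes high-contrast, non-touching cells.
- Rings and foci lying within ~0.1 µm of a pole cap can evade the peak
  detector (the projected band is dim and truncated there); polar-ring
  counts are accordingly conservative by a few percent.
- The waist of very asymmetric pairs (v outside ≈ [0.05, 0.95]) merges
  with the pole cap and is not detected as a division event.
- The dip classifier operates on the smoothed profile, so its decision
  boundary in *generative* dip depth sits above the nominal 0.10; the
  boundary in observed (post-smoothing) depth is at 0.10.
- The Ansari-Bradley normal approximation is slightly conservative under
  median centering; exact enumeration is used automatically only up to a
  pooled size of 20.
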