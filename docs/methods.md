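# Methods

`meshmx` models the computational core of a serial multi-crystal data
collection strategy for macromolecular crystallography (MX): many small
crystals sit on one cryocooled sample holder; a low-dose mesh scan
locates them, a per-frame diffraction score ranks them, a small rotation
wedge ("partial dataset") is collected at each good position, and a
correlation-based cluster analysis decides which partial datasets are
isomorphous enough to be scaled and merged into one final dataset.

This note records the models, the defaults and why, and what the
simulations do and do not establish.

## Detector model and resolution shells

A flat, orthogonal detector with square pixels; pixel `(px, py)` at
radial distance `r` mm from the beam centre diffracts at
`2θ = atan(r/D)` and maps to the diffraction vector length
`h = 2 sin θ / λ` (Å⁻¹), with `d = 1/h` the resolution and `s = h/2 =
sin θ / λ`. No tilt, parallax, polarization/Lorentz corrections or panel
gaps are modelled; none of the downstream statistics depend on them.

Resolution shells partition `(0, 1/d_min]`. The default policy is equal
reciprocal volume per shell (equal increments of `h³`), so the per-shell
volume weights `V(h) = (4π/3)(h_out³ − h_in³)` entering the score are
uniform and the score sum is well conditioned; an equal-`h` policy is
available. Requesting a `d_min` beyond the detector corner is an error
that names the maximum attainable resolution.

## Average-protein Wilson curve

The mean diffracted intensity of a protein crystal versus resolution
follows a near-universal curve `Σ_p(h)` — strong at low resolution, a
minimum near 6 Å, a secondary maximum near 4.5 Å, then smooth decay —
attenuated by the crystal's overall Debye–Waller factor
`exp(−2 B s²)`. The curve shipped in `meshmx.wilson` is the package's
own tabulation of that canonical shape (17 knots, piecewise-linear in
`h²`, normalised to 1 at `h = 0`, clamped outside the table). Its exact
values are a modelling choice, not a fitted constant: the simulator
draws intensities from it and the scoring fit refers back to the same
table, so simulation and analysis are self-consistent by construction.

## Frame simulation

A frame is `Poisson(background) + spots`:

* background mean `b₀ · exp(−f·h²)` with defaults `b₀ = 20–50`
  counts/pixel and `f = 8` (falls to ~40% of b₀ at 3 Å on the test
  geometry) — typical of low-dose cryo frames;
* each Bragg spot is a 2-D Gaussian (default σ = 1–1.5 px) at a uniform
  random pixel; its integrated intensity is
  `spot_scale · Σ_p(h) · exp(−2·wilson_B·s²) · E`, `E ~ Exponential(1)`
  (acentric Wilson statistics);
* optional sharp ice rings (default hexagonal-ice d-spacings 3.90, 3.67,
  3.44, 2.67, 2.25 Å; ~2 px wide Gaussian annuli of excess mean counts,
  Poisson-sampled with the background) and optional "salt" spots —
  sharp, very strong, with no resolution falloff;
* counts stay float internally; quantisation to 16-bit happens only when
  frames are written to TIFF.

The Poisson stream and the spot-placement stream are independent
children of the recipe seed, so rescaling `spot_scale` rescales the spot
flux exactly without re-rolling positions or deviates — this is what
makes the linearity properties exactly testable.

Deliberately absent: Ewald-sphere geometry (spots are not on a lattice —
the scorer never indexes), mosaicity, detector gaps, radiation damage.
Passing tests therefore show that the scorer ranks *this* class of
images correctly; they cannot certify behaviour on artefacts the
generator does not produce (e.g. module edges, blooming).

## Frame scoring

1. **Background curve** `B(h)`: per shell, iterative sigma-clipping
   (reject pixels above `mean + 3·sd`, recompute, until the rejection
   set is stable or 10 iterations; shells with < 50 pixels are
   unusable). The clip constant 3 and iteration cap are conventional
   robust-mean choices.
2. **Sharp-ring rejection**: shells where `B(h)` exceeds 1.5× a 5-shell
   moving median are flagged as ice/salt rings and excluded from spot
   acceptance, the fit and the score.
3. **Spot detection**: pixels above `B(h) + 4·sqrt(max(B(h), 1))`
   (Poisson noise model with a unit floor), 8-connected components,
   accepted when 2 ≤ size ≤ 100 px, eccentricity ≤ 0.95 (second-moment
   ellipse; rejects streaks), centroid on an unflagged shell. All
   thresholds are `ScoringParams` fields; on densely spotted simulated
   frames where Gaussian spots overlap into large blobs the size cap is
   raised (the test suite uses 2000 px).
4. **Mean Bragg intensity** `Ī(h)`: background-subtracted flux of the
   spot pixels (mask dilated 3 px to capture sub-threshold tails)
   divided by the number of pixels in the shell. Dividing by *shell*
   pixels rather than spot pixels matters: the above-threshold area of
   a Gaussian spot grows with the logarithm of its total, so a
   spot-pixel denominator flattens the apparent resolution falloff and
   systematically underestimates B.
5. **Wilson fit**: weighted none, linear least squares of
   `log Ī = log k − 2 B s² + log Σ_p(h)` over shells with positive `Ī`
   (≥ 4 required), abscissa = flux-weighted mean `h` of the shell's spot
   pixels (narrower Jensen bias than the shell centre). `CC_powder` is
   the Pearson correlation between observed `log Ī` and the fitted
   model; it gates the score, suppressing resolution-flat (salt-like)
   signal even when no ring is flagged.
6. **Score** = `max(CC_powder, 0) × Σ Ī(h)·V(h)` over unflagged,
   spot-bearing shells; exactly 0 when no spots are accepted or the fit
   is absent. Negative correlations are clamped so the score remains a
   ranking quantity.

Open conventions fixed here (the method description leaves them open):
CC on the log scale; the sum over spot-bearing shells only; `s = h/2`.

**B recovery.** With the dense test-bed recipe (256² px detector, 1000
spots, `spot_scale 2·10⁵`, background 20, 20 shells to 3 Å) the median
fitted B over 10 seeds lands within a few percent of the planted value;
the ±15% band in the tests absorbs the Wilson sampling noise of a
single frame (tens of spots per shell, exponential deviates).

## Mesh workflow

Grid dimensions are `ceil(area/beam)` per axis. Scores fill the heat
map in row-major raster order (x = horizontal translation; serpentine
scanning is off). Selection is a numeric contrast threshold plus an
optional top-N cap — the headless counterpart of interactive contrast
adjustment. Each selected position is assigned the default wedge: 10°
total rotation (±5°), 100 images, hence 0.1°/image.

`run_pipeline` chains everything: plant crystals → render mesh → score →
heat map → select → simulate one partial dataset per position → resolve
indexing → cluster → merge the main cluster → report. All randomness
derives from one seed through named `SeedSequence` children, so the
report JSON is byte-stable. Default study conditions: 6×5 grid, 8
crystals of which 2 form a non-isomorphous minority class
(`class_shift = 0.35`, giving between-class distances ≈ 0.3 versus
within-class ≈ 0.08), wedge fraction 0.35, noise 5%, per-crystal scale
spread ±20% in log, relative B up to 4 Å². Sizes are chosen so a full
run takes about a second on one core.

## Reflection data and the wedge simulator

Symmetry is handled by explicit point-group operator lists for the
families the workflow actually meets — P1, monoclinic 2, tetragonal 4,
trigonal H3, hexagonal 6 — the last three carrying the merohedral
indexing-ambiguity twofold `(h,k,l) → (k,h,−l)`. The constructor checks
closure and identity; there is deliberately no general space-group
engine. The reciprocal-ASU representative is the lexicographically
greatest orbit image (Friedel mates included when Friedel symmetry is
on), which makes reduction idempotent and orbit-invariant by
construction. d-spacings come from the general triclinic reciprocal
metric.

Ground truth: all unique reflections to `d_min` with intensities
`I ~ Exponential(mean ∝ Σ_p(h)·exp(−2 B_true s²))`. A simulated wedge
draws a random fraction of the uniques (index-random, not
rotation-geometric — only the overlap structure matters downstream) and
reports

    I_obs = k · exp(−2 b_rel s²) · I_true·(1 + c·δ_hkl) + ε,

with `δ_hkl` a fixed unit-variance per-class field (so crystals of one
class share the same perturbation — that is what makes them cluster),
`ε ~ N(0, (noise_frac·I_true)²)`, `σ = noise_frac·I_true` floored at 1%
of the median true intensity (division safety), negative observations
kept. The factor `(1 + c·δ)` is clamped at 0.01 to keep true intensities
positive. An optional reindexing operator maps the indices before
output, planting an indexing ambiguity.

Files use a plain-text XDS-ASCII-style dialect: `!`-prefixed header
(space-group number, cell, wavelength, column declarations) then
`H K L IOBS SIGMA(IOBS)` rows; the parser reports the offending line
number for malformed rows and non-positive sigmas.

## Clustering and indexing resolution

Pairwise `CC_I(i,j)` is the Pearson correlation of intensities over the
ASU-common uniques of each pair, after each set's own duplicates are
merged by inverse-variance weighted mean; pairs with fewer than 30
commons are "missing". Distance is `sqrt(1 − CC²)`; missing pairs get
the maximal distance 1 rather than an imputation (a low-overlap set
should not ride into a cluster on no evidence). Agglomeration is
average linkage by default (complete/single/ward configurable); the
dendrogram is cut at height 0.15 — the conventional isomorphism cutoff
for this distance — by connected components of merges strictly below
the cut, so a cut at 0 yields singletons. The main cluster is the
largest, ties broken by lower mean intra-cluster distance.

Indexing ambiguities are resolved *before* correlation: each set is
remapped through whichever ambiguity operator (identity included)
maximises its CC against the first set, the indexing reference. Sets
that never reach the common-reflection minimum under any operator are
left unchanged and flagged.

## Scaling, merging, statistics

Relative scaling fits, per set against the reference over positive
common intensities, `log I_set = log k − 2 b_rel s² + log I_ref` with
weights `(I/σ)²` — a linear scale plus isotropic relative B, exactly
the simulator's generative model (full scaling programs do more; this
is sufficient here and keeps the round-trip exact). Observations are
divided by `k·exp(−2 b_rel s²)` and merged per unique by
inverse-variance weighted mean with `σ_merged = (Σw)^{-1/2}`. Negative
merged intensities are retained.

Statistics (per merged dataset, against the count of all uniques to
`d_min`): completeness (%), multiplicity, `R_merge`,
`R_pim = Σ_h sqrt(1/(n_h−1)) Σ_i |I_i − Ī_h| / Σ_h Σ_i I_i` over
multiply-observed uniques, `CC_1/2` as the Pearson correlation of two
random half-averages per unique — averaged over 10 seeded splits for
stability, since the split convention is otherwise arbitrary — and
mean I/σ of the merged values.

**H-test.** Over pairs related by a (candidate) twin operator with both
intensities positive, `H = |I₁−I₂|/(I₁+I₂)`; for iid exponential
(untwinned acentric) pairs `E[H] = 1/2`, and for twin fraction α,
`E[H] = (1−2α)/2`, so `α̂ = clamp(1/2 − mean H, 0, 0.5)` (≥ 50 pairs
required). Merging mis-indexed wedges without resolution mixes the two
indexings per unique: with finite multiplicity the per-reflection
mixing fraction scatters around ½, so α̂ approaches 0.5 only as
multiplicity grows (≈ 0.4 at ~6 observations per side in the tests);
the resolved merge sits at ≈ 0.

**Anomalous diffraction ratio.** Feasibility of anomalous phasing is
judged by the classic heavy-atom estimate
`⟨ΔF/F⟩ ≈ √2 · sqrt(Σ N_i f''_i²) / (Z_eff · sqrt(N_atoms))`, with
`Z_eff = 6.7` the effective normal scatterer and 7.7 non-H atoms per
average residue; callers supply `f''` at their wavelength. For a
316-residue chain with 1 Zn (f'' = 3.9 e) and 3 Ca (f'' = 1.4 e) at the
Zn K edge this gives 1.96% ≈ 2%.

## Numerical and degenerate-input policy

* Sigma-clip convergence = stable rejection set; shells that clip below
  50 pixels become unusable.
* Wilson fit absent (< 4 usable shells) ⇒ score 0.
* `pairwise_cc` leaves CC undefined when either side has zero variance.
* Distance matrices are symmetrised (`(D+Dᵀ)/2`) before linkage to
  absorb float asymmetry.
* All seeds pass through `numpy.random.SeedSequence` with fixed integer
  tags; derived seeds are reduced mod 2³¹.

## Known limitations

* Spots are geometry-free; nothing here validates indexing or
  integration software.
* Wedge overlap is index-random, so completeness-versus-rotation-range
  trade-offs of real wedges are not reproduced.
* The shipped Wilson tabulation is an idealisation; fitted `k` has
  meaning only relative to it.
* Merging statistics follow the fixed definitions above, which differ
  in detail (binning, split conventions) from any particular standard
  scaling program.
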