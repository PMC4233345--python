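# Methods

This note records the models implemented in `saskit`, the parameter choices
that matter, and what the synthetic-data tests do and do not demonstrate.

## Data model and units

A `ScatteringCurve` holds a strictly increasing momentum-transfer grid
(s = 4π sinθ/λ), intensities and optional 1-σ errors.  s is unit-agnostic
internally; only the Porod/molecular-mass code needs absolute units (Å⁻¹)
and converts curves tagged `unit="nm"` by dividing s by 10.  Negative
intensities are accepted everywhere except inside a Guinier fit (buffer
subtraction legitimately produces them); rows with s < 0 or σ ≤ 0 are
dropped at parse time.  `BeadModel` is an ordered point set with per-point
scattering weights and a single bead radius — atoms, Cα dummy residues and
density-derived beads all use it.

## Automatic Guinier analysis (`curves.autorg`)

The Guinier law I(s) ≈ I(0)·exp(−s²Rg²/3) holds only for s·Rg below ≈1.3
(the default admissibility limit).  `autorg` scans every contiguous window
of at least 5 points in the low-angle region (prefix sums make each
weighted fit of ln I vs s² O(1)), rejects windows with non-negative slope,
s·Rg beyond the limit at the window end or — when σ is available — a
goodness-of-fit p-value below 10⁻⁶, and ranks the survivors by

    quality = 0.4·(window length fraction) + 0.3·(1 − start fraction) + 0.3·R².

The weights express the behavioural contract (prefer long windows that
start near the origin and fit well); they are exposed as module constants.
The chosen window's start index is the "first good point" passed to the
Porod stage.  The p-value screen is only applied when real errors exist: a
χ² test against unit weights would be meaningless.

Known bias: for compact globular bodies the single-exponential fit over
s·Rg ≤ 1.3 overestimates a sphere's Rg by ~1.7% (23.6 vs 23.24 Å for
R = 30 Å).  This is a property of the Guinier approximation itself, not of
the window search, and is why the sphere tests compare at percent-level
tolerances.

## Curve comparison and merging

`compare` finds the scale c minimising Σ(I_a − c·I_b)²/(σ_a² + c²σ_b²) —
iteratively reweighted least squares polished by a bounded scalar
minimisation, which restores the exact a↔b symmetry (the IRLS fixed point
alone neglects the c-dependence of the weights).  The reduced χ² with
N − 1 degrees of freedom and its survival p-value follow; curves are
"similar" at p ≥ 0.01.  `merge` scales the high-angle curve onto the
low-angle one inside an overlap window, takes the low curve below the
window midpoint and the scaled high curve above, and blends coincident
grid points with inverse-variance weights.

## Infinite-dilution extrapolation (`dilution`)

The measured profile at concentration c is modelled as linear in c,
I(s, c) = I(s, 0)·(1 − c·B̃(s)), with the interference term concentrated at
low angles.  The pipeline:

1. **Fit range.** Candidate windows run from a scanned lower edge (30–85%
   of the common range by index) to the end of the data.  In each, all
   curves are scaled onto the most concentrated one and every pair is
   χ²-compared; the widest window where all pairs reach p ≥ 0.01 wins.
   The final scales are re-estimated over the *upper half* of that window:
   the concentration effect decays with s, so this minimises its leakage
   into the scales (and makes recovery on noiseless synthetic series exact
   to machine precision).
2. **Pointwise regression.** At each grid point, weighted linear regression
   of scaled intensity against c gives the intercept I(s, 0) with its
   standard error and the slope B(s).
3. **Diagnostics.** The Rg of the extrapolated curve is compared with the
   straight-line extrapolation of the per-curve Rg² values to c = 0
   (Rg² is the Guinier-additive quantity; a flag switches to plain Rg);
   agreement within 5% sets `rg_consistent`.  Intercept errors must stay
   within 5× the best input error (`error_ok`), and points where the
   extrapolated value differs from *every* input by more than 3× the
   intercept error are flagged as information gain.
4. **Merge.** Below the point of least |I_extrap − I_avg|/σ inside the fit
   range the extrapolated curve is used, above it the inverse-variance
   average of the scaled inputs.

The 5%/5×/3σ thresholds are package choices; no published values exist.

## Porod volume and molecular mass (`porod`)

For a homogeneous particle, I(s) → A + K/s⁴ at higher angles.  The
invariant Q = ∫s²[I(s) − A] ds and the forward scattering give the excluded
volume V_P = 2π²·I(0)/Q without absolute calibration, and the protein-
average ratio 0.625 kDa per nm³ of V_P converts to molecular mass
(configurable via `--ratio`).

Choices that matter:

- **Working range.** From the Guinier first good point to 8/Rg (about the
  second minimum of the Porod plot s⁴I(s); a second-minimum detector is
  available, and the cutoff is configurable).
- **Background fit.** A and K come from a linear regression carried out in
  Porod-plot coordinates, s⁴I against s⁴, over the upper half of the
  working range with equal weights.  This is the same linear model as
  regressing I on s⁻⁴ but under a weighting with two virtues on real and
  analytic curves alike: form-factor oscillations around the asymptote
  average out over the several periods the longer tail contains, and for
  relative-error data the noise of s⁴I is roughly uniform, so equal
  weights are close to inverse-variance optimal.  (A 1/σ² weighting in I
  coordinates lets near-zero form-factor minima dominate and biases A;
  a short 25% tail spans less than one oscillation period of a sphere and
  makes the fitted constant unstable by ~0.2% of I(0), i.e. several times
  the invariant's tolerance.)  A is clamped so I − A stays positive over
  the tail, and a negative K raises an error (no Porod regime).
- **Integration.** Guinier-model continuation on [0, s_min] + trapezoid on
  the data + the analytic tail K/s_max beyond the cutoff.  The
  limited-range correction factor of the classical literature is not
  implemented; the analytic tail serves that purpose.

Measured on analytic oracles: sphere volume −1.0%, ellipsoid (20,20,60)
+2.5%, shift under an added constant ≈1.4%, exact scale invariance.

## Debye intensities and fitting (`formfit`)

I(s) = Σᵢⱼ fᵢfⱼ·sinc(s·rᵢⱼ) with per-model form-factor kinds: `point`
(constant weight), `gaussian_sphere` (w·exp(−(sR)²/α), α = 3, the smooth
dummy-residue profile; R defaults to 1.9 Å), `hard_sphere_amplitude`.  The
exact double sum runs to 2000 beads; beyond, pair distances are histogram-
binned at 0.025 Å, which keeps the result within ~10⁻³ relative of the
exact sum even at deep form-factor minima (the error concentrates where
I(s) is small).

Fitting minimises χ² over the scale c ≥ 0 and a background constant b
bounded (default ±10% of the maximum intensity) — a bounded-variable
linear least-squares problem.  The parameter search runs on a block-
averaged copy of the data (≤256 blocks uniform in s, inverse-variance
means); the model curve is averaged over the *same* blocks with the same
weights rather than interpolated at block centres, because curvature
within a block otherwise biases the additive constant by a few percent.
The final χ² is always recomputed on the original grid.

## Mixture decomposition (`mixtures`)

Non-negative least squares (Lawson–Hanson, via scipy) on the error-
weighted design of component intensities; reported fractions are the
normalised weights and the overall scale is their sum — whether those are
volume or mass fractions depends on the normalisation of the supplied
intensities, which the package deliberately does not alter.  Fixed
fractions are handled by folding the fixed block into a single column tied
to the free weights, keeping the problem linear.  The two-state wrapper
computes Debye curves of a full assembly and a chosen subcomplex and warns
when the estimated minor fraction leaves the reliable window (0.15–0.90
for a dissociated species, 0.2–0.8 monomer-vs-multimer).  With exact form
factors and a two-component NNLS the recovery error does *not* blow up
outside the window — the window reflects the realistic modelling setting
where component curves are themselves refined — so the package enforces it
as a warning, not an error, and the tests check the warning contract plus
recovery accuracy inside the window (measured: ~0.5% mean absolute
fraction error at 2% noise, far inside the 15% bound quoted for full
shape-reconstruction pipelines).

## Ensemble selection (`ensembles`)

The chromosome is a variable-size multiset of pool indices (bounds 5–50);
its fitness is the χ² of the unweighted average of the member curves after
optimal scaling, so repeats encode weights.  Operators: uniform crossover
of merged multisets, per-gene replacement mutation (rate 0.1), insert/
delete size mutation, elitism 2, population 50, ≤200 generations with a
50-generation plateau stop.  Two exploitation devices are layered on the
GA, both package design choices: the initial population contains one
chromosome obtained by largest-remainder rounding of the non-negative
least-squares weights over the whole pool (the averaging model is linear
in member weights, so NNLS is the natural exploiter), and the elite is
polished each generation by vectorised single-gene steepest descent
(replace/insert/delete).  Without them the plain GA stalls at χ² ~ 1–10 on
planted noiseless ensembles; with them planted 3-member ensembles are
recovered exactly from 50-member pools on every tested seed.  Fixed seeds
give bit-identical solutions.

The flexibility verdict compares Rg distributions: selected/pool variance
ratio ≥ 0.8 → flexible, ≤ 0.3 → rigid, else indeterminate; the mean shift
reports compaction vs extension.  The cutoffs are package conventions.

## Loop libraries (`loops`)

Traces are grown by sequential addition of Cα points at exactly 3.8 Å,
rejecting candidates that violate the > 4 Å non-neighbour clash rule or
fall outside the allowed pseudo-angle region; dead ends backtrack one
point (budget 100 tries/step, 50 restarts).  The quasi-Ramachandran mask —
pseudo-bond angle θ ∈ [75°, 150°] with a rectangular forbidden zone
θ ∈ [75°, 100°] × γ ∈ [−40°, 40°] — is a configurable stand-in for the
published plot, whose coordinates are not reproduced anywhere; users can
tighten it via `QuasiRamachandranMask`.  Libraries bin traces by length
(5–100) and end-to-end distance (2 Å bins centred at odd multiples of
1 Å), 20 distinct traces per bin (pairwise r.m.s.d. > 0.5 Å after
superposition).  Queries rigidly place a stored trace between two anchors
and return `None` — a rejection signal, not an error — when no bin covers
the anchor separation.  Serialisation writes PDB files for inspection but
stores coordinates at full precision in the JSON index, since PDB's
1 mÅ columns would break the 10⁻⁶ bond-length invariant on reload.

## Shape comparison and clustering (`shapes`)

NSD² = ½[Σ_a min_b r²/(N_a d_b²) + Σ_b min_a r²/(N_b d_a²)] with d_x the
median nearest-neighbour distance (median rather than mean: robust to
stray beads).  Superposition: P1 searches a deterministic 432-orientation
quaternion covering followed by Nelder–Mead refinement of the three best
starts, optionally testing the mirror image; Pn restricts to rotation
about and translation along the shared z axis (24 angular starts); Pn2
aligns the symmetry axes only.  Clustering: average-linkage on the
pairwise matrix; for each candidate k the mean intra-cluster distance over
clusters of ≥2 members is normalised linearly onto [1, N−1] across k, and
penalty(k) = normalised spread + k is minimised (ties toward smaller k).
The criterion needs the true k to sit strictly inside the scanned range to
form an elbow; for two planted groups of jittered copies (k_true at the
scan boundary) the spread profile is flat and the choice is noise-driven —
the tests therefore probe the boundary case with exact copies and the
interior cases (3 planted groups) with jitter.  `density_to_beads`
thresholds a map, places beads at voxel centres (radius = half the voxel
diagonal) and, given a surface cutoff in voxels, marks beads within that
Euclidean distance of the thresholded boundary as refinable via a distance
transform (map borders count as background).

## Synthetic data (`synthio`)

Analytic bodies: solid sphere (closed form), triaxial ellipsoid
(64-point Gauss–Legendre orientation average per axis; doubling the order
changes results by < 0.1%), pure Guinier law.  Random bead models pack
beads uniformly in a (optionally z-stretched) spherical envelope with a
minimum separation; `dimerize` applies a P2 rotation plus abutting
translation.  Concentration series follow I(s,c) = I(s,0)(1 − k·c·g(s))
with g(s) = exp(−(s/s₀)²), s₀ = 0.05 Å⁻¹ — a smooth, low-angle-
concentrated interference term; defaults k = 0.05 and c ∈ {1, 2, 4} mg/ml
give ~5–20% low-angle suppression, typical of a moderately interacting
protein series.  The default noise model is 1% relative with a small
floor — good synchrotron data; the mixture experiments use 2%.

What the generators do *not* emulate: instrumental smearing, detector
geometry, inter-particle structure factors beyond the linear term,
hydration-shell contrast, and real chemical heterogeneity of scattering
lengths.  Passing tests therefore demonstrate the correctness of the
estimators under their stated models, not robustness to every real-data
pathology.

## Problem sizes

The test suite and the acceptance script run simulations sized for a
single CPU: 20-replicate Monte-Carlo loops, 50-seed χ² distribution
checks, 100-bead mixture models, 50-member ensemble pools, and a loop-
library slice over lengths 10–30 at 300 growth attempts per length.  These
sizes were chosen so each experiment's sampling error sits comfortably
below the tolerance it is tested against.

## Known limitations

- The Guinier quality score and its weights are conventions; different
  choices move the selected window by a few points on noisy data.
- The Porod route assumes a homogeneous particle; strongly structured or
  flexible particles violate the s⁻⁴ premise and the 0.625 kDa/nm³ ratio.
- `merge_extrapolated` assumes the concentration effect is negligible in
  the fit range's upper half; strongly interacting systems (charged
  particles at low ionic strength) can violate this.
- P1 superposition is a local refinement over a finite orientation grid;
  pathological near-symmetric shapes can settle into a secondary minimum.
- The Kelley-criterion boundary behaviour discussed above.
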