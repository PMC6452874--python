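# Methods

## Model system and quantities

The system is a competition between two yeast strains expressing a
Ura3p–GFP fusion: soluble (`SOL`) and aggregation-prone (`AGG`), the
latter forming stable, non-exchanging intracellular deposits (foci).
Three media set the selective role of Ura3p activity: dispensable
(+uracil), essential (−uracil), toxic (+5FOA).  All fitness quantities
are expressed per hour; doubling times τ are in hours and growth rates
ω = 1/τ in doublings per hour.

## Selection-coefficient estimation

The selection coefficient is defined as the time derivative of the
natural-log abundance ratio of the two strains.  Under exponential
growth the log2 ratio is linear in time,

log2(N_agg/N_sol)(t) = log2(N⁰_agg/N⁰_sol) + t·(ω_agg − ω_sol),

so `SelectionModel` fits an ordinary least-squares line to the pooled
log2 ratios of all replicates and reports S = slope·ln2 with
se(S) = se(slope)·ln2.  Pooling into a single fit is the default (one S
per environment/medium); a per-replicate mode
(`per_replicate_estimates`) is available for dispersion checks.
Culture dilutions between timepoints multiply both strains equally and
cancel in the ratio, so absolute copy numbers are never compared across
timepoints.  The default sampling grid is the assay's
{0, 17, 34, 51, 58, 75, 82} h.

qPCR quantification: each strain's Ct values are inverted through its
own standard dilution curve (Ct = slope·log10 copies + intercept;
efficiency 10^(−1/slope) − 1), with no shared-efficiency shortcut,
because the two primer pairs amplify different templates.

Doubling times come from a cubic smoothing spline on ln(OD600) against
time (`scipy.interpolate.make_smoothing_spline`; penalty selectable,
generalised cross-validation by default).  τ = ln2 / max d ln(OD)/dt
over the observed range — the maximum-derivative rule is appropriate
because cultures are held in exponential phase, where the maximum is
attained over most of the curve.

## Cost/benefit decomposition

Per environment, fitness effects are attributed to where the protein
sits:

S = α·f_foci + β·f_free·[essential] + γ·f_free·[toxic]

- f_foci: mean over all analysed `AGG` cells of the per-cell ratio
  F_FOCI/F_TOTAL (foci-free cells contribute zero).  A ratio-of-means
  variant and a foci-containing-cells-only variant are exposed as
  options, since per-cell averaging over all cells vs the foci subset
  is a genuine analysis choice.
- f_free: mean F_CYTO of `AGG` cells divided by mean F_TOTAL of `SOL`
  cells — a ratio of population means, because cells cannot be paired
  across strains.  The soluble strain's total fluorescence represents
  100 % available activity in that environment.

α is identified from the +uracil medium alone (S = α·f_foci there:
no loss or gain of function when the activity is dispensable) and is
assumed medium-independent within an environment; β and γ then follow
as (S_medium − α·f_foci)/f_free.  The loss and gain terms are never
simultaneously active.  The published middle expression for the
essential-medium case carries an extra factor of S that is inconsistent
with its own solved form and with the toxic-medium and combined
equations; the solved form (β = (S − α·f_foci)/f_free) is implemented.
Solve-then-predict is algebraically exact, which the tests verify to
1e−12.

Degenerate inputs are errors, not NaNs: f_foci = 0 makes α undefined
(no deposits to attribute fitness to) and f_free = 0 makes β/γ
undefined.

## Invasion simulation

Both strains grow exponentially; counts are integrated in natural-log
space by forward Euler with Δt = 60 min:

ln N(t) = ln N(t−Δt) + Δt·ln2/τ.

Because the update is linear in ln N with constant coefficient within a
segment, the scheme is exact for any step size (tests assert < 1e−9
deviation from the closed form over 5,000 h).  The variant's doubling
time is interpolated from the measured S and the wild-type τ by
inverting the definition of S: 1/τ_agg = 1/τ_sol + S/ln2; an implied
non-positive growth rate is rejected rather than simulated.

Defaults follow the study design: 1 mutant cell (ln N = 0) among 10⁶
wild-type cells, environment switches every 12 h, and the "generations"
axis uses the 30 °C wild-type doubling time of 2.7 h as the reference
generation regardless of simulated environment.  Switch times must be
whole multiples of Δt; misaligned schedules are rejected instead of
silently truncating a segment.  Dominance times are read off the first
grid point at or above the threshold (no interpolation).  The model is
purely deterministic — no drift, death, mutation or carrying capacity —
so the time-weighted mean selection coefficient S_h over a schedule
exactly determines the per-period change of the log ratio, which the
simulation reproduces to float round-off.  The pairwise environment
grid uses equal-time alternation by default (entry (i,j) then reduces
to (S_i+S_j)/2); the period is exposed.

## Image processing

Cells: pixels with intensity in [20, 255] (inclusive closed interval on
8-bit values), 8-connected components, kept when the physical area lies
in [8, 50] µm² and the circularity 4π·area/perimeter² in [0.25, 1]
(capped at 1; digitisation can exceed it).  Foci: intensity in
[40, 255], area in [0.2, 10] µm², each assigned to the cell containing
its centroid; orphan foci are discarded.  Regions touching the image
border are excluded, as in standard particle analysis.  "Fluorescence"
is integrated (summed) intensity over a region — the subtraction rule
F_CYTO = F_TOTAL − F_FOCI is only meaningful for sums.  No background
subtraction is applied beyond thresholding.  Area comparisons use a
relative epsilon of 1e−9 so that a pixel count whose physical area is
exactly a bound (e.g. 1250 px · 0.04 µm²/px = 50 µm²) is not lost to
floating-point representation.  Cells whose foci hold ≥ 70 % of total
fluorescence are classified BIG, else SMALL.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with one explicit integer seed per call and no global state.

- Competition: noiseless copies follow init·2^(t·ω) per strain;
  measurement noise is multiplicative lognormal in copy space (Gaussian
  in log2 space, sd `noise_sd_log2`, default 0.1), matching how ratio
  noise propagates through relative Ct quantification.  Independent per
  strain and timepoint.
- Cell populations: total fluorescence is lognormal; the foci fraction
  is zero-inflated Beta — a point mass at 0 (probability `p_no_foci`,
  forced to 1 for `SOL`) and Beta(23.5, 1.5) otherwise, whose 0.94 mean
  mirrors the ~94 % insoluble partition measured biochemically for the
  aggregating fusion.  `AGG` totals are scaled by 0.8 by default (the
  observed reduction is real but unquantified, so the factor is a free
  parameter), and `AGG` uses a wider log-sd (0.5 vs 0.35) so the
  higher cell-to-cell noise of the aggregating strain is reproduced
  qualitatively.  Cell areas are positive truncated normals
  (20 ± 4 µm²).
- Images: cells are rasterised as non-overlapping discs on a jittered
  grid at 0.2 µm/px, interior intensity 30 (inside the cell band,
  below the foci threshold, like a dim cytosol), with one bright
  central focus disc (intensity 200) per foci-containing cell, sized
  from its foci fraction and clipped to the detectable 0.2–10 µm²
  window; additive Gaussian background noise is clipped to [0, 255].
  Truth masks and the truth table record exactly what was rasterised.

What the generators do **not** emulate: cell crowding and touching
cells, uneven illumination, out-of-focus light, multiple foci per cell,
autofluorescence, plate effects or timepoint-correlated qPCR error.
Passing tests therefore demonstrate correctness of the estimators and
the segmentation logic under the stated model, not robustness to every
artefact of real microscopy or qPCR.

## End-to-end recovery design

The pipeline plants (α, β, γ) per environment, draws the cell
populations first, computes the *realised* fractions of those samples,
and only then sets the per-medium true S through the forward model with
those realised fractions before generating competition series.  This
ordering makes the noiseless chain close exactly (recovery to 1e−6 is
dominated by OLS round-off); using nominal generator fractions instead
would confound estimator error with sampling error of a 200-cell draw.
Default problem sizes — 200 cells per strain, 3 replicates on the
7-point grid, 5,000 h of simulated invasion — keep a full run under a
few seconds while leaving the noisy-recovery tolerance (10 %) far from
binding (observed errors ≈ 2 %).

## Statistics

CV uses the sample (n−1) standard deviation; population-vs-sample is
not specified by convention in this field, and n is large enough that
the choice is immaterial — it is recorded here for exactness.  The
rank-sum test enumerates the full permutation null (tie-aware, via
midranks) for combined n ≤ 20 and falls back to the tie-corrected
normal approximation above that; an independent pairwise-counting
enumeration oracle in the tests checks the exact branch.  Reported
p-values are unadjusted, and the noise report labels them as such.
Noise summaries restrict the foci and cytosol compartments to
foci-containing cells, matching how deposit-level variability is
quantified.

## Known limitations

- The invasion model cannot represent extinction or fixation by drift;
  a "never reached" dominance result is exact only within the
  deterministic model.
- Segmentation assumes well-separated cells; merged neighbours would be
  filtered by area/circularity rather than split (no watershed).
- The decomposition assumes α is medium-independent within an
  environment and that fractions measured in one imaging session apply
  to all three media of that environment; a joint refit across media is
  deliberately not attempted by default.
- β and γ inherit the full uncertainty of S, α and both fractions; no
  error propagation is currently reported for them.
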