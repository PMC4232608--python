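# Methods

`circlekeeper` re-implements, as a tested pipeline with synthetic data, the
quantitative machinery used to study how non-chromosomal DNA circles (ERCs
and excisable reporter plasmids) are retained in budding-yeast mother cells
by anchorage to nuclear pore complexes (NPCs), and how the joint
accumulation of circles and pores drives replicative ageing.  This note
documents the models, the generator assumptions, the numerical choices, and
what passing tests do and do not show.

## 1. Propagation-frequency (pf) estimator

A telophase tally records `x`, `y`, `z` cells carrying 1, 2 or 4 plasmid
foci and the percentages `a`, `b`, `c` of each category that retained *all*
plasmids in the mother.  If each plasmid propagates to the bud
independently with probability `p`, the all-retained fraction of an
m-plasmid cell is `(1-p)^m`, so the per-plasmid retention is its m-th root.
The estimator averages the per-category retentions with plasmid-number
weights and reports the complement:

    R1 = a,  R2 = 100*sqrt(b/100),  R4 = 100*(c/100)^(1/4)
    pf = 100 - (x*R1 + 2y*R2 + 4z*R4) / (x + 2y + 4z)

The historical formula applies the roots to the raw 0–100 percentages
(`sqrt(b)`, `c^(1/4)`); on that reading the retention terms are deflated
~10-fold and pf is not an estimate of `100p` (it reports ≈62% even at full
retention whenever multi-plasmid cells are present).  Both readings are
exposed (`variant="consistent"` (default) / `"as_printed"`) and both are
written to the pipeline report.  The Jensen bias of the root transforms at
small per-category counts is documented, not corrected: with the default
cohort sizes (≥ thousands of cells) it is far below the Monte-Carlo noise.
Categories with zero cells carry an *undefined* percentage (`None`), never
a fabricated zero.

Pedigree retention (fraction of mothers whose daughter lacks the circle
marker) equals `(1-p)^k` for a mother carrying `k` circles; `k` is a preset
constant (default 24) because per-mother copy number is not observable in
the marker assay.  The half-sector rate is the plain ratio of half-sectored
to total colonies; its generator factorises excision before the first
division (`p_excise`) and loss from one first-division lineage
(`p_first_loss`), so the rate converges to their product.

## 2. Photobleaching kinetics

FLIP traces are normalised to 100% at the last pre-bleach point after
subtracting the mean fluorescence loss of unbleached neighbor cells
(additive correction on the shared time base).  Decays are fitted by
nonlinear least squares to `I(t) = plateau + (100-plateau) exp(-k t)`
(`scipy.optimize.curve_fit`, tolerances 1e-10, ≤10⁴ evaluations;
initialisation: plateau from the last three points, rate from a log-linear
regression of the first half).  Non-convergence and flat traces are
flagged on the result, never silent.  Time-to-fraction statistics are
solved from the fitted curve, `t_q = -ln((100q - plateau)/(100 - plateau))/k`,
reported as infinite when the level lies below the plateau; a raw-crossing
mode exists for noiseless sanity checks.  FRAP recoveries are fitted to
`I(t) = plateau (1 - exp(-k t))` with `t15 = -ln(1 - 15/plateau)/k`.

The **barrier index** is the ratio of the bud over the mother time to lose
40% of the initial signal during mother-side FLIP (`q_lost` is a
parameter).  A figure legend elsewhere describes the inverse ratio at 70%;
the operational definition used here follows the methods text, so a
stronger bud-neck diffusion barrier gives a *larger* index.  The index is
exactly the rate ratio for plateau-free mono-exponentials and is invariant
to common intensity rescaling.

Identifiability: on the 9 s × 30-point acquisition grid a free-plateau
decay fit recovers the rate to ≤5% only in the regime where the trace
actually decays appreciably (k ≳ 0.008 s⁻¹ or small plateaus); for slow,
high-plateau traces the plateau–rate correlation dominates and errors of
~10% occur at noise SD 2.  The round-trip test therefore exercises the
identifiable envelope (k ∈ [0.008, 0.05] s⁻¹, plateau ≤ 40, noise SD 0.5).

## 3. Image and profile quantification

Synthetic nuclei are drawn as a Gaussian-blurred annulus (radial SD 0.25 µm
standing in for the optical PSF; no camera statistics are published for the
original data, so noise is Poisson shot noise scaled by a gain, then
additive Gaussian read noise).  A loaded nucleus multiplies the rim
intensity by `cap_ratio` inside the cap's angular span and places a
plasmid focus (red channel) at the cap centre.  The truth block records
every generating value; pixel size 0.07 µm on a 64×64 frame keeps the
blurred rim tails inside the field.

* Integrated fluorescence: sum over the ROI minus background mean × area;
  negatives are reported as-is.  On noiseless images with the known
  background level this equals the generator's photon bookkeeping to
  floating-point precision.
* Cap quantification: mean gray value of the circle-adjacent rim sector
  (Ic), the residual rim (Ir) and the opposite sector (Io), background
  subtracted, normalised by the *cohort median* of raw Ir so that
  median(Ir) = 1.  Per-cohort (not global) medians are used and recorded.
* Percent-to-mother: `100 * mother/(mother+bud)`; complements sum to 100
  (to 1e-9 in floating point).
* Rim traces: bilinear sampling (`scipy.ndimage.map_coordinates`) on the
  rim circle, arc step ≤ half a pixel; green normalised to its per-cell
  mean, red to its per-cell max.
* Profile alignment: each green profile is circularly shifted so the red
  peak maps to the origin; enrichment is the mean inside a ±130 nm window
  over the mean outside, minus one ("130 nm around the plasmid" is read as
  130 nm to each side; both the window and a whole-trace baseline are
  parameters).  The profile generator parameterises the *target*
  enrichment and solves the Gaussian bump amplitude in closed form on the
  sample grid, so the noiseless round-trip is exact to 1e-9.
* Rim proximity: a focus is "resolvable" when its radial distance from the
  rim circle exceeds 0.25 µm (≈ optical resolution; parameter).
* Track speed: mean 3-D step length per 3 s interval divided by 3;
  per-track mean, then cohort mean.  Step lengths of the generator follow
  `sigma * chi_3`, giving the closed-form mean `sigma * sqrt(2)
  Gamma(2)/Gamma(1.5)` used as the oracle.
* Age trends: 10 consecutive age-sorted values per display dot (mean ± SD);
  fits on the raw points, one-phase association
  `y0 + (plateau-y0)(1-exp(-k·age))` or exponential `y0·exp(rate·age)`
  with values renormalised by the fitted intercept.  A zero-variance cloud
  degenerates to plateau = constant, rate 0, by construction.

## 4. Ageing simulator

The source study asserts the mechanism (circles replicate each S phase,
are retained per-circle with high fidelity, and co-retain the NPCs they
are bound to) but writes no update rule; the simulator implements the
minimal stochastic model consistent with it:

    C_{g+1} = Binomial(2*C_g, rho) + Bernoulli(f_form)
    death when C_g >= T_death at the start of a division

so `E[C_{g+1}] = 2 rho E[C_g] + f_form`, and with `rho = 1` a single seeded
circle kills the cell exactly `ceil(log2 T_death)` divisions later.  An
alternative hazard mode (`P(death) = 1 - exp(-C/T_death)` per division) is
provided.  Daughters are not followed (mother-centric cohorts, as in
microfluidic trapping).  NPC coupling: with `N` pores and `min(kappa*C, N)`
bound, the mother share at division is `s = s0 + (s_bound - s0) *
min(kappa*C, N)/N`; after division the pool is replenished by a constant
production `(1-s0)*npc_pool`, putting circle-free nuclei at steady state.
Defaults `s0 = 0.63`, `s_bound = 0.99`, `kappa = 0.65`, `npc_pool = 100`
span the measured unloaded→loaded mother-share range (63% → 78%).

Wild-type parameters: `rho = 0.961` is fixed by the pf module (1 − pf/100).
`f_form = 0.1` per division and `T_death = 2^18` were set by the package's
own calibration search so that a 200-mother cohort reproduces the reference
median lifespan of 27 generations.  The (f_form, T_death) pair is
deliberately chosen in the regime where lifespan variance is dominated by
circle growth rather than the formation waiting time: because the
threshold-crossing time of exponential growth is `ln T / ln(2 rho)`, a low
formation rate with a small threshold also yields a median of 27 but makes
the median nearly insensitive to `rho`, which would contradict the model's
central claim that small retention defects have large longevity effects.
Survival curves use the lower median (first age at which the fraction
alive drops to ≤ 0.5); cohorts are compared with the log-rank (Mantel–Cox)
test via `lifelines`.  Calibration is a deterministic grid search over
`f_form` × `log2 T_death` followed by a bisection on `log2 T_death`,
reporting failure explicitly for unreachable targets.

## 5. Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analysis assumes:
independent per-plasmid propagation, the 61/33/6% focus-count mix,
cap-to-rim intensity ratios under shot + read noise, two-pool bleaching
decays on the real acquisition schedule, chi-distributed 3-D steps, and
threshold-death ageing cohorts.  They do not emulate segmentation errors,
focus drift, bleed-through, cell-to-cell expression variability beyond the
modelled noise, spatial diffusion of the envelope, or age-dependent
formation rates (an optional age ramp exists but no published functional
form backs it).  Passing recovery tests therefore shows that the
*estimators are correct and unbiased under the stated model*, not that the
model captures every property of real micrographs.  Plasmid focus counts
are restricted to {1, 2, 4} (doubling); rarer higher counts are not
generated.

## 6. Problem sizes and determinism

Default analysis sizes mirror the reference cohorts: 50 cells per imaging
cohort, 20 000 cells per segregation tally, 150–200 mothers per lifespan
cohort, 2–3 replicates per grid point in sensitivity scans.  Every
generator and the simulator are bit-for-bit deterministic given
`(preset, seed)`; pipeline stages derive their seeds by SHA-256 hashing of
`"<global seed>:<stage name>"`, so adding or reordering stages never
perturbs other stages' outputs.
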