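# Methods

`apostim` re-implements, end to end, the computational chain behind a
predator-wariness experiment: naturalistic warning patterns are generated at
exactly controlled achromatic (luminance) contrast, printed-stimulus
photometry is mapped into the visual world of the avian predator, and
behavioral trial data with the experiment's structure are simulated and
analysed with binomial mixed models. This note records the models, the
defaults and why they were chosen, and what the synthetic components do and
do not establish.

## Pattern synthesis (reaction-diffusion)

Patterns are steady states of the Gray-Scott two-species
substrate-depletion system on a periodic grid,

    du/dt = Du lap(u) - u v^2 + F (1 - u)
    dv/dt = Dv lap(v) + u v^2 - (F + k) v,

integrated with explicit Euler and a 5-point Laplacian. The activator `v`
is the pattern channel. Two named `(F, k)` presets select the morphology:

| preset  | F      | k      | morphology                      |
|---------|--------|--------|---------------------------------|
| spots   | 0.0367 | 0.0649 | isolated self-replicating blobs |
| stripes | 0.046  | 0.063  | elongated worm-like ribbons     |

with `Du = 0.16`, `Dv = 0.08`, `dt = 1` (explicit-Euler stable, since
`dt < dx^2 / (4 Du)`). The contract of a preset is its morphological
*class*, verified by `classify_morphology`, not a specific kinetics: the
solver accepts any `(F, k, Du, Dv)`. The stripes preset was chosen over the
classical labyrinthine corner of the Gray-Scott phase diagram because at
practical step counts the labyrinth regime reached ribbon-like morphology in
only about half of the seeds, while the worm regime does so in 20/20.

Integration starts from the trivial state `(u, v) = (1, 0)` — which is
linearly stable and is verified to stay exactly uniform forever — excited by
a centred square patch set to `(0.5, 0.25)` plus seeded uniform noise of
amplitude 0.05. Periodic boundaries make the dynamics exactly translation
equivariant, which the suite asserts bit-for-bit, and guarantee the centred
crop used by the stimulus factory contains no boundary artefacts.

Steady state is declared when the maximum per-cell change per step stays
below `2.5e-4` for 1000 consecutive steps (default budget 15 000 steps).
Two numerical facts force both parts of that rule: (a) the per-step drift of
a formed pattern plateaus around `2e-5`–`1e-4`, so tolerances much below
`1e-4` never trigger; (b) the excited patch passes through a brief quiescent
dip (~200 steps) before the instability grows, which a pointwise test
mistakes for convergence. Spots runs typically converge near 12 000 steps;
worm-regime runs often use the full budget and are flagged
`converged=False`, which is acceptable for stimulus work because the
morphology is fully formed. Any non-finite cell raises an instability error
naming the step; the solver never clamps.

`classify_morphology` thresholds the field at the Otsu level and measures
each foreground component's isoperimetric compactness `4 pi A / P^2` (1 for
a disc, small for a thin ribbon regardless of curvature — chosen over
second-moment anisotropy because Gray-Scott "stripes" are isotropically
oriented labyrinths/worms, not parallel bands). The anisotropy index is one
minus the median compactness; fields at or above 0.5 are stripes, below are
spots, and fields with no usable phase separation are `indeterminate`.

## Stimulus construction

Each stimulus is an apex-up isosceles triangle (base 44 mm, height 37 mm,
the shape of the artificial moth targets), rasterized at 600 dpi:
`round(mm / 25.4 * 600)` gives a 1039 x 874 px bounding box. The RD field
is upsampled isotropically, a centred window supplies the left half, and the
right half is its exact pixel mirror (wing symmetry); outside the triangle
the image is background white.

Contrast is Michelson contrast `C = (Rmax - Rmin)/(Rmax + Rmin)` over the
patterned (masked) pixels only, with nominal grey treated as reflectance.
The two experimental levels are 0.15 and 1.0. Holding *mean* luminance
fixed across contrast conditions is the design's confound control, and an
affine stretch alone cannot deliver it: the Gray-Scott amplitude
distribution is strongly skewed, so matching the band midpoint would let the
pixel mean drift by ~0.2 between conditions. The factory therefore
tone-normalizes first — masked pixel values are rank-equalized to a uniform
distribution (order preserving, ties averaged across mirror duplicates) —
which makes mean and midpoint coincide, then maps affinely onto the target
band centred on `mean_reflectance` (default 0.5, the only mean for which
`C = 1` is feasible symmetrically).

Export is 8-bit grey. The band endpoints are chosen directly on the 8-bit
grid as the integer pair whose Michelson contrast is closest to the target
(tie-broken toward the mean): for `C = 0.15`, greys (108, 146) give 0.1496,
whereas rounding each real endpoint separately would give 0.1529, a 2% bias.
Achieved contrast and mean are always measured on the quantized pixels, so
the manifest records exactly what a printed PNG contains.

Categories are batches of variants differing only by RD seed
(`base_seed + variant_id`); a variant whose field misclassifies for its
regime is regenerated from a deterministic fallback sequence (5 retries,
then a hard error). The standalone `rescale_to_michelson` keeps the plain
affine midpoint contract for use on raw fields.

## Arena luminance and the double cone

`CalibrationCurve` maps grey to arena luminance anchored at the measured
endpoints: the darkest pattern grey at 13 cd/m^2 and the lightest at
216 cd/m^2. Linear by default, with a gamma shape (`L = dark +
(light - dark) g^gamma`) available because physical print/illumination
chains are nonlinear; both shapes pass the endpoints exactly and are
strictly increasing, so luminance mapping never reorders pixels and the
effective in-arena Michelson of a full-range stimulus is
`(216 - 13)/(216 + 13) ~= 0.886`.

`double_cone_luminance` integrates reflectance x illuminant x double-cone
sensitivity (trapezoid on the native 1-nm grid, 350–800 nm, linear
interpolation onto the common range). The packaged sensitivity and
illuminant curves are smooth **synthetic** stand-ins (a mid/long-wavelength
unimodal curve with an oil-droplet-style short cut-off; a 4700 K blackbody):
the measured chicken double-cone function is not printed in any source
available to the package. Tests therefore exercise only algebraic
properties (linearity in each argument, identity reductions, resampling,
domain errors), never the stand-ins' values.

## Synthetic behavior generator

The generator reproduces the experiment's design exactly: groups of 19, 21,
20, 20 chicks (low-stripes, low-spots, high-stripes, high-spots), 5 trials
per chick, 2 batches (balanced alternation by default; batch has no effect
on behavior, mirroring the experiment's non-significant batch terms). The
outcome model is a two-stage hurdle with a single shared random intercept
`b_i ~ N(0, sigma^2)` per chick:

    P(approach)      = logistic(b0a + bca * high + bp * spots + b_i)
    P(eat | approach) = logistic(b0e + bce * high + bte * (trial - 1) + b_i)
    eaten = approached * Bernoulli(P(eat | approach))

so `eaten => approached` holds record by record. Defaults (log-odds):
`b0a = 1.1`, `bca = -2.2`, `b0e = 0`, `bce = -1.2`, `bte = 0.35`, `bp = 0`,
`sigma = 1.0`. These are synthetic magnitudes, not estimates — the study
reports no log-odds effects. They were fixed by a one-time calibration so
that a default 80-chick cohort reproduces the qualitative findings (high
contrast deters approach and eating; eating rises over trials) with ~90%
power for the approach-stage contrast term in the reduced factorial model,
and they are not tuned thereafter. Empirical cell probabilities are checked
against independently quadratured analytic marginals at 10 000 chicks.

What the generator does *not* emulate: avoidance learning or any
trial-to-trial dependence beyond the fixed trial slope, latency outcomes,
chick-by-batch heterogeneity, or stimulus-variant effects within category.
Passing tests validate the analysis machinery under the assumed model, not
the biology of real chicks.

## GLMM estimation and model reduction

The analysis model is a binomial logit GLMM with fixed factors (trial
categorical with 5 levels, pattern class, contrast level, batch) and a
per-chick random intercept. The marginal likelihood's per-chick
one-dimensional integral is evaluated with 31-node Gauss-Hermite quadrature
and maximized directly (L-BFGS-B on `(beta, log sigma)` with analytic
gradients; `log sigma` bounded in `[-8, 3]`, the lower bound acting as the
zero-variance boundary). This is genuine ML — not PQL — so AIC
(`2p + 2 - 2 logL`, counting the variance) is well defined for the reduction
rule. On shared fixtures the estimates, sigma, and AIC agree with
`lme4::glmer(nAGQ = 25)` to ~1e-3 and with a plain IRLS logistic regression
to 1e-4 when the variance estimate is on the zero boundary. Standard errors
come from the finite-differenced observed information of the analytic
gradient; when sigma sits on the boundary the variance row is profiled out
rather than inverted. Per-term tests are Wald chi-square on coefficient
blocks (treatment coding, references: low contrast, stripes, trial 1, batch
1). F statistics with software-specific denominator df conventions are
deliberately not reproduced.

Model reduction follows the study's two rules, in order: (1) drop the batch
main effect if its Wald p >= 0.05; (2) refit without the
trial x pattern x contrast three-way interaction and keep the reduced model
iff AIC decreases — the interaction is retained when AIC would rise, which
the suite exercises on a cohort with a genuine three-way effect. A
non-convergent candidate defers the decision (richer model kept, logged).
The `eaten_given_approached` response is implemented by row filtering.
Note a subtlety the suite documents: conditioning the second stage on
approach with a shared intercept tilts the intercept distribution among
analysed rows, so conditional-stage coefficient recovery is validated on
cohorts where the first stage is non-selective.

## Problem sizes in the validation suite

Simulation-based checks use: 20 seeds per RD preset for regime validity;
the full 120-stimulus set for photometry and geometry; 400 replicate
80-chick cohorts for the type-I error of the contrast term (exact binomial
95% interval around 0.05); 200 replicate 1000-chick cohorts for coefficient
bias (<10%) and Wald CI coverage (>=90%); 100 replicate default cohorts for
the calibrated power property. These sizes keep every Monte-Carlo tolerance
at 2–3 standard errors while the whole suite runs in minutes on one core.

## Known limitations

- The Gray-Scott parameterization is a configurable stand-in for "a general
  reaction-diffusion model"; any two-species kinetics with spot/stripe
  regimes can be substituted without touching the factory.
- Nominal grey is treated as reflectance; the physical printer/paper loop is
  represented only by the two-point calibration curve.
- The spectral fixtures are synthetic; photometric conclusions about real
  plumage/print spectra require measured curves.
- Wald tests are asymptotic; with 80 chicks they are calibrated (measured
  type-I 0.050) but small-sample refinements (Kenward-Roger-style) are out
  of scope.
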