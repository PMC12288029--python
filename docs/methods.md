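# Methods

This note records the models behind each pipeline stage, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
experiments can and cannot establish about real video data.

## Synthetic experiment design

The simulator reproduces the structure of the source experiment: four
holding tanks, groups of 26–32 guppies, and a 2 × 2 crossover of
temperature (22 / 29 °C) and turbidity (0 / 5 NTU).  Treatment order
follows a Williams Latin square — every treatment appears once per group
and equally often in every order position, balanced for first-order
carryover — with groups cycling through the four rows and tanks assigned
round-robin.  The default design uses 24 groups (96 trials) and removes
five trials (two warm, two turbid, one interaction), mimicking lost
recordings, to give 91 trials of 19,800 frames (11 min at 30 fps):
1,801,800 pooled magnitudes.  Trials are seeded individually from the
master seed through a `SeedSequence` spawn tree, so any trial can be
regenerated in isolation and the whole experiment is bit-reproducible.

Testing times (`minutes_from_midnight`) are drawn uniformly over a
09:00–18:00 window; the original testing hours are not recorded, and the
covariate exists to exercise the time-of-day model, not to match them.

### Series tier

The series tier emulates the *output* of the flow stage directly.  A trial
is an i.i.d. gamma background band (shape 20, scale 3 × 10⁻⁴: mean 0.006,
tightly concentrated — the "dark band" of a magnitude trace) plus
raised-cosine visit pulses.  Visits arrive as a Poisson process at 10 per
minute in clear water with geometric durations (mean 180 frames ≈ 6 s);
peak amplitudes are gamma with shape 1.5 and mean 0.04, a deliberately
heavy tail: most passes are faint (distant fish barely move the frame
mean) while close passes spike.  Clear-water visits cover roughly 60% of
frames, so all five pooled percentile thresholds (99th–70th) land above
the background band and detection events at every sensitivity level track
fish visits rather than background crossings — the regime the real data
occupies, where lowering the threshold from the 99th to the 70th
percentile multiplied events ~18-fold but never reversed the direction of
the turbidity effect.  Under the defaults the simulated event total grows
~22-fold over the same range.

Treatment effects enter as multipliers, all configurable:

| parameter | default | acts on | rationale |
|---|---|---|---|
| `temp_amplitude_factor` | 1.5 | visit amplitude (warm) | warming raises activity, hence apparent motion, of fish in view |
| `turb_rate_factor` | 0.5 | visit rate (turbid) | shorter visibility range shrinks the effective field of view |
| `turb_duration_factor` | 0.7 | visit duration (turbid) | crossings of a smaller visible volume are briefer |

Temperature deliberately does not alter arrival rate by default, matching
the finding that warming changed within-event magnitude rather than event
frequency.  The first value of every series is 0 by the flow convention
(below).

### Video tier

The video tier renders grayscale frames in [0, 1]: elliptical fish on a
correlated random walk (Gaussian heading increments, sd 0.3 rad/frame;
step length `base_speed`, × `temp_speed_multiplier` when warm).  At walls
the outward heading component is flipped *before* the move, so every step
is a straight segment of exactly the step length and total path length is
proportional to speed — a property the tests rely on.  Turbidity follows a
Beer–Lambert-style fog model: a fish at distance *d* from the camera
corner keeps a fraction exp(−β·d) of its clear-water contrast.  The real
mechanism (kaolin scattering) is only known to shrink the visible range;
exponential attenuation is the standard single-parameter surrogate.
Frames get a Gaussian blur (σ = 1 px) and additive pixel noise
(σ = 0.01) before clipping.  The renderer is for exercising the flow
stage at micro scale (e.g. 4 trials × 300 frames × 64²), not for
photorealism; fish are untextured, unoccluded ellipses.

## Optical flow

Single-level dense Lucas–Kanade.  Spatial gradients are central
differences with replicate padding, taken on the mean of the two frames
(the symmetric choice keeps sub-pixel estimates unbiased to first order);
the temporal gradient is the raw frame difference.  The 2 × 2 normal
equations are accumulated over a (2r+1)² box window, default r = 2.
Where the smaller eigenvalue of the summed structure tensor is below the
noise threshold (default 0.0039 on [0,1] intensities, the documented
default of the widely used reference implementation) the flow is zeroed;
this suppresses sensor-noise flow in flat regions and makes magnitude
non-increasing in the threshold.  No pyramid: sub-window translations
≤ 1 px are the regime of interest (tests recover 0.25–1 px shifts within
10%; in practice within ~2% on smooth textures).

The first frame of a trial has no predecessor, so its magnitude is defined
as 0 and the series length equals the frame count — which is what makes
91 × 19,800 = 1,801,800 magnitudes.  Frames may be supplied as PNG
directories or any iterable of arrays (the decoder is pluggable); RGB is
reduced by BT.601 luma weights.

## Detection metrics

Pooled percentiles use numpy's linear interpolation between order
statistics; the midpoint rule used by some environments is available as
`method="hazen"`, and at n ≈ 1.8 × 10⁶ the two agree to well past the
precision that matters.  "Exceeds" is strict (>): for continuous
magnitudes the choice is measure-zero, and strictness makes the all-equal
edge case unambiguous.  Events are maximal runs of above-threshold frames
within a single trial (runs never span trials); indices are 0-based and
inclusive, durations reported in frames and seconds.  Trials with no
above-threshold frames at a level contribute missing values for the two
conditional responses (mean magnitude above, mean event duration) and are
dropped case-wise by the affected models only — the proportion and count
responses keep them as exact zeros.

## GLMMs and model comparison

Eight candidates per response: a null model (intercept + tank random
intercept) and seven alternatives each adding one hypothesis — the two
stressors alone, additively, interactively, and three control variables
(group size, trial order, minutes from midnight) kept in separate
single-covariate models to limit overfitting.  Families follow the
response's support: beta with logit link (proportions; boundary values
compressed by (y(n−1)+0.5)/n when present), gamma with log link (positive
magnitudes), NB2 with log link (event counts; variance μ + μ²/θ), and
Gaussian with identity link (mean durations).

The marginal likelihood integrates the tank intercept out by adaptive
Gauss–Hermite quadrature, default 15 nodes (1 node = Laplace): per tank, a
damped Newton iteration (analytic first and second derivatives of each
family's log-density in the linear predictor) finds the integrand's mode
and curvature, and the Hermite grid is centred and scaled there.  The
log-likelihood moves by < 10⁻³ between 15 and 25 nodes on synthetic fits.
Optimisation is bounded L-BFGS-B on (β, log dispersion, log σ_tank) with
up to five jittered restarts on non-convergence; non-convergence is
flagged, never silently accepted.  Standard errors come from the inverse
numerical Hessian at the optimum.  The fitter reproduces statsmodels'
Gaussian MixedLM (ML) to ~10⁻⁸ and closed forms (OLS when the random
effect is pinned at zero; log-mean for the intercept-only gamma) to 10⁻⁶.

Parameter counting: k = fixed coefficients (incl. intercept) + 1 family
dispersion + 1 random-intercept variance, giving the ladder 3 / 4 / 5 / 6
for null / single covariate / additive / interaction in every family.
Temperature and turbidity are 0/1 dummies (22 °C, 0 NTU reference); trial
order is numeric 1–4 (one slope, consistent with the ladder); group size
and minutes from midnight are centred and scaled for optimizer stability,
with slopes also reported in natural units.  AICc requires n > k + 1 and
is refused otherwise.  Rankings sort by AICc; models within 2 units of the
best are annotated as equivalent, with an extra-parameter caveat when a
larger model sits within 2 units of an equally good smaller one.

## Replicate studies and problem sizes

Three seeded studies characterise the machinery over the 91-trial, 4-tank
design: (i) recovery — event counts simulated directly from the NB2 GLMM
with a known turbidity coefficient (−0.7, i.e. turbidity halves expected
counts) and refitted over 200 replicates, with the replicate-mean estimate
compared to truth on the Monte-Carlo SE scale; (ii) power — full
series-tier pipeline replicates (simulate → pool → threshold → count →
fit) checking how often the Turbidity model out-ranks the Null by AICc;
(iii) calibration — the same pipeline with all treatment factors at 1,
checking how often the Null stays within 2 AICc units of the best of all
eight candidates.  Pipeline replicates use 1,980-frame trials: event
counts scale linearly with trial length and the design (91 trials, 4
tanks, crossover balance) is what drives the sampling behaviour of the
fits, so shorter trials characterise the same machinery at a fraction of
the cost; the single full-scale experiment (19,800-frame trials) is used
for the threshold calibration and effect-direction checks.

## Limitations

* The series tier draws background magnitudes i.i.d.; real magnitude
  traces have short-range autocorrelation from video compression and
  lighting flicker.  Threshold calibration and event bookkeeping are
  insensitive to this, but absolute event counts at a given level are not
  comparable to any particular camera system.
* The fog model attenuates contrast only with distance to one corner; real
  turbidity also lowers overall luminance and adds backscatter.
* Flow magnitudes are camera- and scene-relative.  All downstream analysis
  is therefore threshold-relative (pooled percentiles), and only
  directions and rankings — not absolute magnitudes — are meaningful
  across systems.
* With four tanks the random-intercept variance is weakly identified; it
  is retained for structural fidelity (and counted in k), not because four
  levels estimate a variance well.
* ML fixed-effect estimates in small cluster designs carry O(1/n) bias;
  the recovery study bounds it at well under an MC SE at this design size.
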