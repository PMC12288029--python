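# preyflow

Quantifying the detectability of free-swimming prey fish to a stationary
visual predator, from video, and testing how warming and turbidity shift it.

## The problem

An ambush predator's opportunity to strike depends on how often prey enter
its field of view, for how long, and how conspicuous they are while there.
Two globally increasing stressors pull on these quantities in different
ways: turbidity scatters light and shortens the distance at which moving
prey are visible, while warmer water raises ectotherm activity and makes
prey that *are* in view more conspicuous.  `preyflow` implements a pipeline
for measuring these effects with an underwater camera standing in for the
predator: shoals of guppies (*Poecilia reticulata*) swim through a large
arena under a 2 × 2 crossover of temperature (22 / 29 °C) and turbidity
(0 / 5 NTU), and each trial's video is reduced to an objective per-frame
measure of apparent prey motion.

Because the pipeline is driven by a seeded synthetic-arena simulator (a
video tier that renders swimming fish, and a fast series tier that
synthesizes the magnitude traces directly), every stage is testable end to
end without any video downloads.

## The method

**Optical flow.** Consecutive grayscale frames are compared with dense
single-level Lucas–Kanade flow: at every pixel the displacement
$(u, v)$ minimises the windowed residual of the brightness-constancy
equation, solving

$$
\begin{pmatrix} \sum I_x^2 & \sum I_x I_y \\ \sum I_x I_y & \sum I_y^2 \end{pmatrix}
\begin{pmatrix} u \\ v \end{pmatrix}
= - \begin{pmatrix} \sum I_x I_t \\ \sum I_y I_t \end{pmatrix}
$$

over a 5 × 5 window, with the flow zeroed where the structure tensor's
smaller eigenvalue falls below a noise threshold.  The per-pixel magnitude
$\sqrt{u^2 + v^2}$ is averaged over the frame, so an 11-minute trial at
30 fps becomes a series of 19,800 mean magnitudes.

**Detection events.** Thresholds are set at the 99th, 95th, 90th, 80th and
70th percentiles of the magnitudes pooled across all trials (91 × 19,800 =
1,801,800 values); lower percentiles emulate predators with more sensitive
motion vision.  Maximal runs of frames strictly above a threshold form
*detection events*, yielding four responses per trial and level: the
proportion of frames above threshold, the mean magnitude within those
frames, the number of events, and their mean duration.

**Model comparison.** Each response is modelled with a GLMM carrying a
random intercept for the holding tank of origin — beta (logit) for
proportions, gamma (log) for mean magnitudes, negative binomial (NB2, log)
for event counts, Gaussian for durations — fitted by maximum likelihood
with the random effect integrated out by adaptive Gauss–Hermite quadrature.
A null model is compared against seven single-hypothesis alternatives
(Temperature, Turbidity, Temperature + Turbidity, Temperature × Turbidity,
group size, trial order, minutes from midnight) using
$\mathrm{AICc} = -2\ell + 2k + \frac{2k(k+1)}{n-k-1}$, with ΔAICc > 2 read
as strong support.

## Worked example

The numbered drivers under `analysis/` run the whole study; they write
their tables under `results/`.  `analysis/02_flow_video_demo.py` renders a
micro experiment (4 trials, 300 frames, 64 × 64 px) and pushes it through
the flow stage:

```
  treatment  mean_magnitude  p95_magnitude
    control        0.185947       0.210695
     turbid        0.095716       0.124529
       warm        0.280688       0.324008
interaction        0.128947       0.188251
```

Turbidity halves the mean flow magnitude on matched trajectories (contrast
attenuates exponentially with distance from the camera), and warming raises
it through faster swimming — the two directions the statistical stage is
built to detect.

`analysis/01` + `03` simulate the full series-tier experiment (91 trials,
1,801,800 pooled magnitudes) and extract events:

```
 percentile_level  threshold  pooled_n  frames_above  n_events
               99   0.162255   1801800         18018       571
               95   0.092325   1801800         90090      2271
               90   0.063745   1801800        180180      4356
               80   0.034118   1801800        360360      8069
               70   0.018256   1801800        540540     12323
```

Dropping the threshold from the 99th to the 70th percentile multiplies the
event count ~22-fold: a sensitive predator experiences many short
detection opportunities where an insensitive one sees only the strongest
spikes.  `analysis/04` then ranks the candidate GLMMs — with the default
effect directions, turbidity-bearing models dominate the event-count and
proportion responses while temperature dominates the within-event
magnitude — and `analysis/05` validates the machinery by simulation:

```
Recovery: true turbidity effect -0.7, mean estimate -0.7101 +- 0.0078 (MC SE, 200 replicates)
Power: Turbidity model out-ranks Null in 100% of 100 replicate experiments
Calibration: Null model within 2 AICc units of the best in 85% of 60 null-effect experiments
```

The same pipeline is scriptable from the shell:

```sh
preyflow all --tier series --seed 1 --out runs/demo --levels 99,95,90,80,70
```

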