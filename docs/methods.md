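# Methods

This note documents the generative model behind the synthetic sessions,
the detection and classification rules, the statistical procedures, the
numerical choices that were genuinely open, and what the validation suite
does and does not establish.

## Task and coordinate conventions

A trial is 1500 ms at 500 Hz: 800 ms fixation at the screen center, then a
horizontal fixation-point jump of ±7° and a 700 ms response window.
Direction 0° is rightward, counter-clockwise positive. The electrode array
is taken to sit in the left hemisphere, so rightward jumps/saccades are
*contraversive* and leftward ones *ipsiversive*. The electrode grid
(default 8 × 12 = 96 sites, ids row-major) is split along its row axis
into equal caudal (near the frontal eye fields) and rostral halves.

## Generative model

**Saccade waveform.** A saccade from **a** to **b** moves along the
straight line with displacement s(t) = A·(t/D − sin(2πt/D)/2π), i.e. a
raised-cosine velocity profile: at rest at both ends, peak speed 2A/D at
mid-flight. Duration follows a linear main sequence D = d₀ + d₁·A with
d₀ = 21 ms and d₁ = 2.2 ms/°, so a 7° saccade lasts 36.4 ms and peaks
near 385 deg/s — representative primate values. The waveform is a modeling
choice (the analysis never assumes it); any smooth unimodal profile with
the same main sequence would serve.

**Latency.** Task-saccade reaction time is ex-Gaussian:
RT = μ_dir + σ·N(0,1) + Exp(τ), with σ = 20 ms, τ = 40 ms,
μ_ipsi = 170 ms and μ_contra = μ_ipsi − 26 ms by default (the baseline
contraversive advantage; set it to 0 for unbiased animals). Stimulated
trials add the shift configured in the *effect map*, keyed by (electrode
group, current, direction). Defaults mirror the studied phenomenon:
+25 ms contraversive delay from caudal electrodes only (+4 ms at the low
current), −22 ms ipsiversive speeding from both groups (−9 ms at 100 µA).
A 25 ms physiological floor and, on evoked trials, a 12 ms minimum gap
after the evoked saccade keep trials well-formed.

**Evoked saccades.** Each configured evoking electrode has a preferred
vector; on a stimulation trial it evokes a movement with its configured
probability for that current, onset uniform in [20, 60] ms after
stimulation (stimulation is concurrent with the jump), direction von Mises
around the preferred direction (κ = 20), amplitude Gaussian with a
current-dependent mean (4.0° at 100 µA, 5.5° at 250 µA, SD 0.8°). The
default cluster sits on the caudal border: four sites evoke robustly at
both currents (p = 0.6 / 0.9) and three neighbours mostly at the high
current (p = 0.05 / 0.55), so the apparent evoking patch grows with
current and seven electrodes meet the inclusion criterion at 250 µA.
Stimulation itself is metadata only; no electrical waveform is synthesized
because no analysis stage inspects one.

**Sessions and noise.** One 20-trial block per electrode × current, with
exactly half the trials stimulated and jump directions balanced within
both the stimulated and control subsets of every block (pseudo-random
order). Isotropic Gaussian noise (SD 0.05°) is added to every sample;
traces are stored in single precision (ample above that noise floor).
Identical (config, seed) yields bit-identical data. Ground truth records
every injected latency, amplitude, direction and evoked event.

**What the generator does not emulate:** blinks and track loss (NaN gaps
are supported by the detector but off by default), drift and pursuit,
microsaccades, corrective saccades, error trials, head/vergence geometry,
per-session drift in excitability, and any neural signal. Passing the
suite therefore shows the *pipeline* is correct and calibrated under the
assumed statistical structure — not that the structure captures every
property of real recordings.

## Detection

Speed is the Euclidean norm of central-difference velocities (one-sided at
the ends), smoothed with a centered 3-sample (6 ms) boxcar. A saccade is a
maximal run of samples with speed > 100 deg/s; runs closer than 10 ms are
merged, runs shorter than 6 ms are dropped. Each run is then refined
outward to the surrounding rest: extended while speed stays above 30% of
the threshold, plus one sub-floor boundary sample on each side. The
refinement matters quantitatively — the first suprathreshold sample of a
7° saccade lies 6–8 ms after true movement onset, and taking endpoints at
the threshold crossings clips ~12% of the amplitude. With refinement,
onset error is unbiased (mean |error| ≈ 1.5 ms ≈ below one sample) and
amplitude error ≈ 0.5%. `refine_onset=False` restores the bare
threshold-crossing rule; window, floor and threshold are all arguments.
Start/end positions are averaged over up to three resting samples at each
edge to suppress sample noise. Runs touching missing samples are excluded,
not interpolated, with a logged reason.

Smoothing width trades noise robustness against peak-velocity fidelity: a
5-sample boxcar attenuates the 36 ms-long 7° peak by ~4–6%, the default
3-sample window by ~1–2% while the smoothed noise floor (≈ 10 deg/s at
0.05° noise) stays far under both the 100 deg/s criterion and the 30 deg/s
refinement floor.

## Classification and exclusions

Labels partition all detected saccades: *evoked* iff latency ∈ [0, 100) ms
and duration ≤ 75 ms; *task* iff latency ∈ [100, 400] ms and duration
< 75 ms; *other* otherwise. The shared 100 ms boundary is resolved
right-open/left-closed so the classes are disjoint; the duration edge
differs (≤ vs <) because the two rules are stated that way. An electrode
is saccade-evoking when evoked saccades occur on ≥ 30% of ≥ 10 stimulation
trials (exactly "3 of 10" at the standard block size). Electrodes evoking
at the highest tested current, and electrodes with non-`ok` status, are
excluded from all behavioral analyses; only the first task-classified
saccade per trial enters latency analyses. A filter ledger accounts for
every trial (broken electrode → evoking electrode → incorrect outcome → no
task saccade), and the report serializer is deterministic.

## Statistics

- **Reciprocal transform**: rate = 1000/RT; the primary latency tests run
  on rates (closer to Gaussian), with raw-ms and rank-sum companions and
  mean/median differences always reported in ms.
- **t tests**: pooled-variance Student by default (Welch behind a flag),
  paired t across electrodes for the spatial analysis.
- **Rank-sum**: Mann–Whitney, exact for small tie-free samples, normal
  approximation with tie correction otherwise; signed-rank when paired.
- **Fisher's exact test**: two-sided by the minimum-likelihood rule with a
  1e-7 relative slack, accumulated in exact rational arithmetic; odds
  ratio is the sample cross-product (0/∞ flagged when degenerate).
- **Circular two-way ANOVA** (Harrison–Kanji scheme): squared cell/margin
  resultants decompose the variation; the concentration κ̂ comes from the
  overall resultant length. For κ̂ > 2 the terms are F-referred against
  the residual (a type-I simulation at κ = 5, 2×2, n = 20/cell gave 0.048
  at α = 0.05, so no additional small-sample correction is applied); for
  κ̂ < 2 a χ² approximation with scale 2/(1 − ρ²) is used and a warning
  flag raised, because the approximation degrades at low concentration. A
  seeded permutation p (joint shuffling of cell labels; 9999 permutations
  by default, 999 in the pipeline for runtime) accompanies every term so
  conclusions need not rest on the approximation. A single-level factor
  collapses (df 0) instead of failing; empty cells are rejected.
- **Linear two-way ANOVA**: OLS with Type-II sums of squares (no a-priori
  factor ordering for unbalanced cells; Type I/III behind a flag).
- **Bonferroni**: α/n. The spatial family is the four group × direction
  paired tests (α = 0.0125). For kinematics the family is every
  per-combination comparison across the three measures (peak velocity,
  amplitude, endpoint error; 3 × 4 = 12 with one synthetic subject,
  α ≈ 0.0042); with a per-subject breakdown the family doubles, matching
  the convention of correcting the velocity comparisons as one family.

## Validation suite: problem sizes and what they show

Detector recovery uses 1000 generator trials at default noise (recall,
precision, onset and amplitude error against ground truth). Statistical
calibration uses 2000 null replicates (circular ANOVA type-I), 200
replicates each for power and permutation agreement, 5000 for t-test
p-uniformity, and 500 random tables against exhaustive Fisher
enumeration. End-to-end recovery runs 100 seeded full-size sessions
(≈ 480 stimulated trials per direction × current) and checks recovered
effects within ±5 ms of the injected values plus the qualitative pattern;
null calibration runs 200 half-size sessions (48 electrodes) and checks
that every headline test rejects at ≈ 5% and that kinematics families stay
clean under Bonferroni. These sizes make the suite sharp enough to catch
sign errors, mis-filtered trials and miscalibrated tests while completing
in a few minutes on one CPU.

## Known limitations

- The two-factor circular ANOVA is an approximation; at low concentration
  only the permutation p should be trusted (the result object says so).
- The pooled contraversive effect is diluted by design when the delay is
  caudal-only; interpret pooled and per-group numbers together.
- One synthetic subject by default; the per-animal breakdown of real
  studies needs a subject column, which the analyses accept but the
  generator only produces via separate configured sessions.
- Latency truncation to the 100–400 ms task window biases recovered shifts
  by well under 1 ms at the default parameters, but grows if μ + shifts
  push mass across the window edges.
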