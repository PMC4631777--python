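# Methods

## The model

`congression.model` implements a coarse-grained, 1-D, overdamped
force-balance model of the fission-yeast mitotic spindle from spindle-pole
separation through anaphase A.  The mechanical elements are:

* two spindle pole bodies (SPBs) on a common axis, pushed apart by the
  interdigitated-microtubule midzone force generator, a linear
  force-velocity element with stall force `F_mz` and unloaded velocity
  `V_mz`;
* `N_ch = 3` chromosomes, each a pair of sister centromeres joined by a
  single Hookean cohesin spring (`K_c`, rest length `d_0`);
* `M_sites = 3` microtubule attachment sites per kinetochore, each coupled
  to its centromere by a spring and damper (`K_k`, `mu_k`) and, when
  attached, pulled toward its pole by a linear force-velocity motor
  (stall force `F_k`, unloaded velocity `V_k`) that stands in for the
  depolymerizing kinetochore microtubule.

Every element obeys overdamped dynamics, `drag * velocity = sum of
forces`, with drags `mu_spb`, `mu_ch`, `mu_site`.  Directional instability
of the kinetochores emerges from stochastic attachment (rate `k_a` per
detached site) and detachment: the detachment rate is modulated by the
distance `d` between a site and the centre of its sister pair as

    rate(d) = k_d * d_alpha / max(d, d_floor)

so low-tension attachments near the pair centre — within the spatial range
`d_alpha` of the Aurora-B-like error-correction activity — are
destabilised and stretched attachments are stabilised.  `d_floor`
(0.01 um) bounds the rate; the hyperbolic form is the simplest monotone
law with `rate(d_alpha) = k_d`.  A newly attaching site picks the
"correct" pole (the pole on its sister's side of the pair midpoint) with
probability `(1 + beta)/2` whenever the pair already holds an attachment,
linearly interpolating between unbiased (`beta = 0`) and error-free
(`beta = 1`) attachment; a fully unattached pair attaches to either pole
with probability 1/2.

### Length-dependent pulling force

The pulling force on an attached site moving at speed `v` toward its pole
is

    F = L_dep * F_k * (1 - v / V_k) * pi,      pi in {-1, 0, +1}

where `pi` records attachment (and whether it is to the correct pole).
The length-dependent prefactor — the model's representation of kinesin-8's
length-dependent microtubule depolymerase activity, which makes long
kinetochore microtubules pull harder than short ones —

    L_dep = 1 + alpha * (d_site_pole / d_mean - 1),   clamped at >= 0

is normalized so that `L_dep(d_mean) = 1`: `alpha` is the fractional force
change per fractional deviation of the site-to-pole distance from its
mean.  With `alpha = 0.2` and `d_mean = 1 um` a kinetochore displaced from
the spindle centre feels a net restoring force of order
`2 * alpha * n_att * F_k` per micron of displacement.  A pure-proportional
variant (`L_dep = d/d_mean`) can be emulated by setting `alpha = 1`.
During anaphase `L_dep` is forced to 1 (kinesin-8 relocates to the
midzone at anaphase), and the cohesin spring is removed; erroneous
attachments are kept as they are.

### Integration and schedule

Explicit Euler with `dt = 0.05 s`; the site equation treats its own
force-velocity term implicitly (the motor contributes `L_dep*F_k/V_k` to
the effective drag), which keeps the scheme stable although site
relaxation times approach `dt`.  Damper cross-terms use previous-step
velocities.  Event probabilities are `rate * dt`, clamped to [0, 1];
parameter validation rejects `k * dt >= 0.1`.  Snapshots are stored every
1 s.  Anaphase is triggered at a fixed `t_meta = 600 s` (the simplest
scheme consistent with measurements made "prior to anaphase"); an
attachment-triggered mode was considered and not implemented.  Anaphase A
is followed for `t_ana = 300 s`.  Simulations start with a 0.5-um spindle,
all pairs centred and unattached; the spindle then elongates under the
midzone/kinetochore force balance to ~3.9 um (length dependence on) or
~4.1 um (off) at anaphase onset — reproducing the direction, though not
the exact magnitude, of the longer spindles of kinesin-8-deleted cells.

### Calibration

`F_k = 1` sets the (nondimensional) force unit and `alpha = 0.2`,
`d_mean = 1 um` are fixed.  The remaining defaults were calibrated, in
this order, to the in vivo anchors: drags and `F_mz`/`V_mz` so the spindle
elongates to ~3-4 um over metaphase; `K_c = 5`, `d_0 = 0.2 um` so the
mean metaphase inter-sister distance is ~0.5 um; `k_a = 0.045 /s`,
`k_d = 0.03 /s`, `mu_ch = 30`, `V_k = 0.15 um/s` so that (i) single-run
trajectories oscillate with amplitude ~0.2 um and half-period ~50 s,
(ii) the 600-run mean normalized anaphase-onset distance is ~0.11 with the
length dependence and ~0.24 without (the headline wild-type and
kinesin-8-deletion values), at attachment occupancy ~0.6.  `beta = 0.9`
and `d_alpha = 0.25 um` follow the error-correction reading of the
orientation and Aurora-B parameters.  All parameters are plain dataclass
fields, overridable from YAML.

### Parameter sweep and pathology screen

`parameter_sweep` varies one parameter at a time (default x0.5 / x2.0)
with the length dependence off.  Because the normalized distance can
shrink for degenerate reasons, every condition is screened: a mean
anaphase-onset spindle length outside 2-8 um (spindle collapse or
runaway; the in vivo range across genotypes is ~3-8 um) or a mean
inter-sister distance outside 0.25-1.2 um (cohesion loss or
hyper-compression; in vivo ~0.5 um) flags the condition `aberrant`.  With
the calibrated defaults, halving `F_mz` collapses the spindle to ~0.7 um —
its low normalized distance is an artifact of having no spindle to centre
on — and every non-aberrant condition remains worse-centered than the
length-dependent reference.

## Trajectory analysis

All metrics operate on per-frame positions of two poles and two sister
centromeres projected on the spindle axis (`TrackedTrajectory`), whether
tracked from microscopy-style spot tables or simulated.

* **Spot assignment**: of 4 spots per frame, the most distant pair are the
  poles; the rest are centromeres; all are projected orthogonally onto the
  pole-pole axis, relative to the pole midpoint.  Frames with a spot count
  other than 4 are skipped and logged, never interpolated.
* **Normalized distance** `nd = |pair midpoint - spindle centre| /
  spindle length`: 0 at the centre, 0.5 at a pole; invariant under
  translation, reflection and pole relabelling.
* **Fourier oscillation metrics**: the mean-detrended midpoint series is
  transformed; the magnitude spectrum is scaled by 2/N so a pure sinusoid
  of amplitude A peaks at ~A; local maxima below 5e-3 Hz are discarded
  (high-pass: slower components are midline drifts).  The dominant peak's
  frequency is refined by two-point interpolation (exact for the
  rectangular-window Dirichlet kernel) and its amplitude by summing
  spectral energy over the peak and both neighbours, keeping the estimate
  within ~5% regardless of where the true frequency falls between bins.
  `half_period = 1/(2 f_peak)`; a full period is `2 * half_period` (the
  field reports both conventions; outputs are labelled explicitly).
* **Extrema oscillation metrics**: a cubic smoothing spline whose residual
  budget comes from a second-difference MAD noise estimate (interpolating
  when noiseless); alternating extrema with prominence of at least 5% of
  the signal range; a semi-period runs from the time-midpoint between one
  extremum pair to the next, so semi-period i is `(e_{i+2} - e_i)/2`;
  per-segment amplitude is half the peak-to-trough excursion.
* **Drifts**: the segment boundaries are midline crossings of the smoothed
  trajectory, so the crossing values estimate the oscillation midline free
  of oscillation phase; `drift_i` is the absolute change of that midline
  between consecutive segments.  (Differencing raw segment means does not
  work: consecutive semi-periods contain opposite extrema, so their means
  differ by ~the oscillation amplitude even for a perfectly stationary
  oscillation.)
* **Lagging time**: after anaphase onset each sister's target pole is the
  pole it is nearest at the last frame; arrival is the first frame within
  `epsilon = 0.2 um` of that (moving) pole; the lagging time is the
  absolute arrival-time difference, censored when a sister never arrives.
* **Mis-segregation**: both sisters on the same side of the spindle centre
  at the end of anaphase A; a sister exactly at the centre counts as
  correctly segregated.
* **Plus-end intensity profiles**: each profile is divided by its own
  median, resampled to fractional position, and averaged within
  microtubule-length bins; the "tip" intensity is the mean over the distal
  10% of samples (at least one) — a windowed mean, not a maximum, chosen
  for robustness to single-pixel noise.  Monotonicity of tip intensity
  with length is reported, never assumed.
* **Group summaries**: mean +/- s.e.m. and unpaired two-sided Student's
  t-tests (`scipy.stats.ttest_ind`).

## Synthetic data

`congression.synth` generates trajectories with the statistical structure
the analysis assumes, so every metric has a ground-truth recovery test
without microscopy data.  The metaphase midline alternates
poleward/anti-poleward ramps (slope `2*amplitude/half_period`, clipped at
+/- amplitude) — the square-wave-like shape of depolymerization-driven
runs — with reversal waiting times either exponential with mean
`half_period` (truncated at 3x) or exactly `half_period`
(`regular_reversal`, used by recovery tests); a sinusoidal mode exists for
FFT closed-form tests.  Each reversal adds a Gaussian midline step
(`drift_sd`).  Sisters sit at midline +/- breathing/2 with slowly varying
breathing; optional detachment events (rate `detach_rate`) drive rapid
excursions toward the nearest pole with `burst = True`, emulating
checkpoint-labelled detachments.  Anaphase trajectories move sisters to
opposite poles at constant speed with a controllable lag.  Intensity
profiles are `1 + tip_gain * length * exp(-(length - x)/0.2 um)` plus
noise: a lattice signal with plus-end accumulation scaling linearly with
length.

Preset parameter values are the published in vivo measurements
(wild type: amplitude 0.23 um, half-period 63 s, drift 0.1 um; kinesin-8
deletion: 0.35 um, 76 s, 0.2 um plus detachment excursions; low-dose TBZ:
0.14 um, 64 s, 0.06 um).  These are generator inputs anchoring the
synthetic data, not quantities the model claims to predict.

What the generator does *not* emulate: photobleaching, frame-to-frame
tracking failures, 3-D projection artifacts, correlated sister noise, and
the force-balance origin of the oscillations themselves (the generator is
kinematic).  Passing recovery tests therefore validates the analysis
pipeline's estimators, not the biophysics of real trajectories.

Two estimator interactions worth knowing: (i) when drift steps coincide
with reversals (as in the generator), the apparent peak-to-trough swing
includes part of the step, biasing recovered amplitudes up by
~`drift_sd / sqrt(2 pi)`; recovery tests therefore measure amplitude on
drift-free trajectories and drift at its own condition.  (ii) with
stochastic (exponential) reversals the ramps often reverse before reaching
the clip amplitude, so recovered amplitudes are systematically below the
nominal parameter; deterministic reversal is the parameter-recovery
condition.

## Numerical choices and edge cases

* Euler step 0.05 s; snapshot interval 1 s; event probabilities clamped to
  [0, 1]; seeds below 2^32; ensembles use `base_seed + run_index`, so any
  ensemble member can be reproduced as a single run.
* Coincident sisters: the cohesin push-apart direction falls back to the
  sister index; a site exactly at its pole takes the pole direction from
  the sign of the remaining offset.
* Oscillation metrics return `None` (never raise) when no qualifying peak
  or fewer than 3 extrema exist; spectra shorter than 64 samples and
  non-uniform sampling are errors.
* Normalized distances beyond 0.5 (kinetochore outside the pole span) are
  returned but logged.
* CSV I/O is lossless: floats are written with shortest-round-trip
  precision and parsed with round-trip parsing, which makes `simulate`
  byte-reproducible for a given seed.

## Problem sizes

The headline comparison uses 600 simulations per arm (matching the
reported in-silico ensemble size) of 900 simulated seconds each at
dt = 0.05 s; the compiled core runs one simulation in ~25 ms, an ensemble
in ~15 s.  The parameter sweep uses 100 runs per condition; analysis
property tests use 100 synthetic trajectories.

## Known limitations

* 1-D geometry: no microtubule plus-end fields, no poleward flux, no 3-D
  spindle architecture; merotely is representable only as opposite-pole
  attachments within one kinetochore's three sites.
* The drug-treated (TBZ-like) condition exists only as altered rate
  parameters in configuration, not as an explicit mechanism.
* Anaphase onset is a clock, not a checkpoint: metaphase duration does not
  respond to attachment state.
* The calibration reproduces the two headline normalized distances, the
  inter-sister distance and the oscillation phenomenology, but was not
  fitted to the full in vivo distributions (e.g. the spindle-length
  difference between genotypes is smaller in the model than in vivo).
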