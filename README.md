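# congression

Stochastic force-balance modelling and quantitative trajectory analytics
of chromosome congression in the fission-yeast (*Schizosaccharomyces
pombe*) mitotic spindle.

## The problem

During metaphase, fission-yeast sister kinetochores oscillate between the
two spindle pole bodies yet stay aligned near the spindle centre; cells
deleted for kinesin-8 (Klp5/Klp6) lose this alignment and show lagging
chromosomes at anaphase, even though their oscillations and attachments
are otherwise functional.  Kinesin-8 accumulates at microtubule plus ends
in proportion to microtubule length, which suggests a simple centering
principle: *the longer the kinetochore microtubule, the stronger its
pull*.  A kinetochore displaced toward one pole is then pulled back by the
longer microtubules from the far pole — a force gradient that centres
chromosomes without any dedicated positioning machinery.

This package provides, for modellers and quantitative cell biologists:

* `congression.model` — a coarse-grained 1-D overdamped spindle model:
  two poles pushed apart by a midzone force generator (`F_mz`), three
  chromosomes with cohesin-linked sister centromeres (`K_c`), three
  stochastically attaching/detaching microtubule attachment sites per
  kinetochore (`k_a`, `k_d`, Aurora-B-like range `d_alpha`, orientation
  bias `beta`), each attached site pulled by a linear force-velocity motor

      F = L_dep * F_k * (1 - v/V_k) * pi,
      L_dep = 1 + alpha * (d_site_pole / d_mean - 1)

  where the prefactor `L_dep` (strength `alpha = 0.2`, reference
  `d_mean = 1` um) is the length-dependent pulling force and can be
  switched off to emulate kinesin-8 deletion.
* `congression.analysis` — the trajectory metrics used on tracked or
  simulated data: normalized distance to the spindle centre (`nd`, 0 at
  the centre, 0.5 at a pole), Fourier and local-extrema oscillation
  amplitude/half-period, inter-event midline drifts, anaphase lagging
  times, mis-segregation calls, poleward speeds, and length-binned
  plus-end intensity-profile statistics.
* `congression.synth` — synthetic trajectory and intensity-profile
  generators (with wild-type / kinesin-8-deletion / low-dose-TBZ presets
  carrying the published in vivo oscillation statistics) for
  ground-truth testing of every analysis operation.
* `congression.io` / a `congression` command line — YAML configs, a
  shared lossless CSV dialect, per-run manifests with checksums, and the
  `simulate`, `sweep`, `synth`, `analyze`, `profiles` subcommands.

## Worked example

```python
import congression as cg

params = cg.ModelParams()                      # calibrated wild-type-like defaults
on  = cg.run_ensemble(params, 600, base_seed=1, store_trajectories=False)
off = cg.run_ensemble(params.replace(ldep_enabled=False), 600, base_seed=1,
                      store_trajectories=False)
print(f"nd with length dependence:    {on.mean_nd:.4f} +/- {on.sem_nd:.4f}")
print(f"nd without length dependence: {off.mean_nd:.4f} +/- {off.sem_nd:.4f}")
print(f"inter-sister distance: {on.summary['isd_metaphase'].mean():.3f} um")
```

prints

```
nd with length dependence:    0.1241 +/- 0.0022
nd without length dependence: 0.2157 +/- 0.0031
inter-sister distance: 0.552 um
```

With the length-dependent pulling force the ensemble-mean normalized
distance of sister-kinetochore midpoints to the spindle centre at anaphase
onset is ~0.12 — kinetochores held near the centre, matching the
wild-type in vivo value (0.113) — and removing the prefactor (all else
equal) degrades centering to ~0.22, matching the kinesin-8-deletion value
(0.239).  The metaphase inter-sister distance stays at the in vivo
~0.5 um, showing the cohesin/pulling-force balance is realistic.  The
same removal lengthens anaphase lagging times while mis-segregation stays
below 1% in both conditions, and a one-at-a-time sweep of the other model
parameters (`congression sweep`) shows that none of them restores
centering in a non-aberrant mitosis — the force gradient is doing the
work.

The same metrics run on single trajectories:

```python
traj = cg.simulate_mitosis(params, seed=1)
mid = traj.to_tracked(0)                       # chromosome 0 as a tracked table
m = cg.extrema_oscillation_metrics(mid.mid[:600], mid.t[:600])
print(m.amplitude, m.half_period)              # ~0.2 um, ~50 s oscillations
```

From the shell:

```sh
congression simulate --n-runs 10 --seed 1 --out runs/
congression synth --preset wt --n 20 --seed 1 --out synthetic/
congression analyze --traj runs/run_0000.csv --method fft --out metrics.csv
```

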