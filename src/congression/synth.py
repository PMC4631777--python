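"""Synthetic kinetochore trajectories and intensity profiles.

Generates data with the statistical structure the analysis pipeline
assumes -- square-wave-like metaphase oscillations with stochastic
reversals, inter-event midline drifts, optional detachment excursions with
a checkpoint-burst label, anaphase separation with a controllable lag, and
microtubule intensity profiles with tip accumulation growing with length --
so every analysis operation is testable without microscopy data.

Preset parameter values are the published in vivo measurements for
wild-type, kinesin-8-deleted (klp6) and low-dose-TBZ cells (oscillation
amplitude 0.23 / 0.35 / 0.14 um, half-period 63 / 76 / 64 s, drift
amplitude 0.1 / 0.2 / 0.06 um).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .analysis import IntensityProfile, TrackedTrajectory

__all__ = [
    "SynthParams",
    "PRESETS",
    "preset",
    "synth_metaphase_trajectory",
    "synth_anaphase_trajectory",
    "synth_intensity_profiles",
]


@dataclass
class SynthParams:
    """Knobs of the trajectory generator (um, s)."""

    amplitude: float = 0.23        # oscillation amplitude (midline excursion)
    half_period: float = 63.0      # mean semi-period of poleward runs
    drift_sd: float = 0.1          # midline step s.d. per reversal event
    detach_rate: float = 0.0       # detachment-excursion events, 1/s
    detach_excursion: float = 0.8  # excursion distance toward a pole, um
    detach_speed: float = 2.5      # excursion speed, um/min
    spindle_length: float = 3.0    # pole-to-pole distance, um
    spindle_growth: float = 0.0    # elongation rate, um/s
    breathing_mean: float = 0.5    # inter-sister distance mean, um
    breathing_sd: float = 0.05     # inter-sister distance s.d., um
    noise_sd: float = 0.0          # localization noise per spot, um
    duration: float = 600.0
    dt: float = 0.1                # high-frame-rate sampling
    seed: int = 0
    waveform: str = "ramp"         # "ramp" (depolymerization runs) | "sine"
    regular_reversal: bool = False  # deterministic semi-periods if True

    def validate(self) -> None:
        for name in ("drift_sd", "detach_rate", "breathing_sd", "noise_sd",
                     "spindle_growth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("amplitude", "half_period", "spindle_length",
                     "breathing_mean", "duration", "dt", "detach_speed",
                     "detach_excursion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.waveform not in ("ramp", "sine"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    def replace(self, **kwargs) -> "SynthParams":
        p = dataclasses.replace(self, **kwargs)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: In-vivo-anchored presets (metaphase oscillation statistics).
PRESETS: dict[str, dict] = {
    "wt": dict(amplitude=0.23, half_period=63.0, drift_sd=0.1,
               detach_rate=0.0, spindle_length=3.0),
    "klp6": dict(amplitude=0.35, half_period=76.0, drift_sd=0.2,
                 detach_rate=2e-3, spindle_length=4.7),
    "tbz": dict(amplitude=0.14, half_period=64.0, drift_sd=0.06,
                detach_rate=0.0, spindle_length=3.0),
}


def preset(name: str, **overrides) -> SynthParams:
    """Named parameter preset ('wt', 'klp6' or 'tbz') with overrides."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = SynthParams(**{**PRESETS[name], **overrides})
    p.validate()
    return p


def _reversal_times(p: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Event times of directional reversals over [0, duration].

    Waiting times are exponential with mean ``half_period`` truncated at
    3x the mean, or exactly ``half_period`` when ``regular_reversal``.
    """
    times = [0.0]
    while times[-1] < p.duration:
        if p.regular_reversal:
            w = p.half_period
        else:
            w = min(rng.exponential(p.half_period), 3.0 * p.half_period)
        times.append(times[-1] + w)
    return np.asarray(times)


def synth_metaphase_trajectory(p: SynthParams) -> TrackedTrajectory:
    """Metaphase trajectory of one sister pair between static-ish poles.

    The sister midline alternates poleward / anti-poleward ramps (slope
    2*amplitude/half_period, i.e. peak-to-trough excursion 2*amplitude per
    semi-period at the nominal rate) with stochastic reversals; each
    reversal adds a Gaussian midline drift step of s.d. ``drift_sd``.
    Sisters sit at midline +/- breathing/2 with slowly varying breathing;
    Gaussian localization noise is added per spot per frame.  Optional
    detachment events (rate ``detach_rate``) send the pair toward the
    nearest pole at ``detach_speed`` and back, with ``burst=True`` while
    under way.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    t = np.arange(0.0, p.duration + 0.5 * p.dt, p.dt)
    n = t.size
    half_len = 0.5 * (p.spindle_length + p.spindle_growth * t)
    slope = 2.0 * p.amplitude / p.half_period

    events = _reversal_times(p, rng)
    baseline = 0.0
    direction = 1.0 if rng.random() < 0.5 else -1.0
    mid = np.empty(n)
    osc = 0.0
    e = 1  # next event index
    for i, ti in enumerate(t):
        while e < len(events) and ti >= events[e]:
            direction = -direction
            baseline += rng.normal(0.0, p.drift_sd) if p.drift_sd > 0 else 0.0
            e += 1
        if p.waveform == "sine":
            osc = p.amplitude * np.sin(np.pi * ti / p.half_period)
        else:
            osc += direction * slope * p.dt if i else 0.0
            osc = float(np.clip(osc, -p.amplitude, p.amplitude))
        mid[i] = baseline + osc
    # keep the midline inside the spindle
    limit = half_len - 0.5 * p.breathing_mean - 0.1
    mid = np.clip(mid, -limit, limit)

    # detachment excursions: rapid run toward the nearest pole and back
    burst = np.zeros(n, dtype=bool)
    if p.detach_rate > 0:
        speed = p.detach_speed / 60.0
        i = 0
        while i < n:
            if rng.random() < p.detach_rate * p.dt:
                pole = np.sign(mid[i]) if mid[i] != 0 else 1.0
                n_leg = max(1, int(round(p.detach_excursion / speed / p.dt)))
                exc = np.concatenate(
                    [np.linspace(0, p.detach_excursion, n_leg),
                     np.linspace(p.detach_excursion, 0, n_leg)]
                )
                j = min(n, i + exc.size)
                shift = pole * exc[: j - i]
                cap = half_len[i:j] - 0.15
                mid[i:j] = np.clip(mid[i:j] + shift, -cap, cap)
                burst[i:j] = True
                i = j
            else:
                i += 1

    breathing = np.clip(
        p.breathing_mean
        + (p.breathing_sd * _smooth_noise(n, rng) if p.breathing_sd > 0 else 0.0),
        0.05, None,
    )
    noise = lambda: rng.normal(0.0, p.noise_sd, n) if p.noise_sd > 0 else 0.0
    return TrackedTrajectory(
        t=t,
        pole1=-half_len + noise(),
        pole2=half_len + noise(),
        cenA=mid - 0.5 * breathing + noise(),
        cenB=mid + 0.5 * breathing + noise(),
        burst=burst,
        anaphase_onset=None,
    )


def _smooth_noise(n: int, rng: np.random.Generator, tau: int = 50) -> np.ndarray:
    """Unit-variance AR(1)-smoothed Gaussian noise (correlation ~tau samples)."""
    a = np.exp(-1.0 / tau)
    w = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    out[0] = w[0]
    for i in range(1, n):
        out[i] = a * out[i - 1] + np.sqrt(1 - a * a) * w[i]
    return out


def synth_anaphase_trajectory(
    p: SynthParams,
    lag: float = 0.0,
    speed: float = 1.5,
    missegregate: bool = False,
) -> TrackedTrajectory:
    """Anaphase-A trajectory: sisters travel to opposite poles at constant
    ``speed`` (um/min), sister B starting ``lag`` seconds later.  With
    ``missegregate`` both sisters go to the same (right) pole.  In the
    noiseless case :func:`~congression.analysis.lagging_time` recovers
    ``lag`` exactly (up to the frame interval)."""
    p.validate()
    if lag < 0:
        raise ValueError("lag must be >= 0")
    rng = np.random.default_rng(p.seed)
    v = speed / 60.0
    half = 0.5 * p.spindle_length
    travel = half - 0.5 * p.breathing_mean
    t_end = travel / v + lag + 30.0
    t = np.arange(0.0, t_end + 0.5 * p.dt, p.dt)
    startA, startB = -0.5 * p.breathing_mean, 0.5 * p.breathing_mean
    dirA = 1.0 if missegregate else -1.0
    cenA = np.clip(startA + dirA * v * t, -half, half)
    cenB = np.clip(startB + v * np.maximum(t - lag, 0.0), -half, half)
    noise = lambda: rng.normal(0.0, p.noise_sd, t.size) if p.noise_sd > 0 else 0.0
    return TrackedTrajectory(
        t=t,
        pole1=np.full(t.size, -half) + noise(),
        pole2=np.full(t.size, half) + noise(),
        cenA=cenA + noise(),
        cenB=cenB + noise(),
        burst=np.zeros(t.size, dtype=bool),
        anaphase_onset=0.0,
    )


def synth_intensity_profiles(
    n: int,
    lengths,
    tip_gain: float = 0.5,
    noise: float = 0.0,
    tip_decay: float = 0.2,
    sample_spacing: float = 0.1,
    seed: int = 0,
) -> list[IntensityProfile]:
    """Microtubule intensity profiles with length-proportional tip signal.

    Each profile is ``1 + tip_gain * length * exp(-(length - x)/tip_decay)``
    sampled every ``sample_spacing`` um from minus to plus end, plus
    Gaussian noise: a uniform lattice signal with a plus-end accumulation
    whose peak scales linearly with microtubule length.  ``lengths`` is
    cycled to produce ``n`` profiles.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if tip_gain < 0 or noise < 0:
        raise ValueError("tip_gain and noise must be >= 0")
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    if n > 0 and (lengths.size == 0 or np.any(lengths <= 0)):
        raise ValueError("lengths must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        ell = float(lengths[i % lengths.size])
        m = max(3, int(round(ell / sample_spacing)) + 1)
        x = np.linspace(0.0, ell, m)
        values = 1.0 + tip_gain * ell * np.exp(-(ell - x) / tip_decay)
        if noise > 0:
            values = values + rng.normal(0.0, noise, m)
        out.append(IntensityProfile(values=values, length=ell))
    return out
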