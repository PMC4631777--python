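"""Quantitative analysis of kinetochore / spindle-pole trajectories.

Works identically on tracked microscopy-style tables and on simulated
trajectories: centering statistics, oscillation amplitude and half-period
(Fourier and local-extrema methods), inter-event drifts, anaphase lagging
times, mis-segregation calls, poleward speeds, and plus-end intensity
profile statistics for length-dependent motor accumulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrackedTrajectory",
    "OscillationMetrics",
    "IntensityProfile",
    "assign_and_project",
    "track_frames",
    "normalized_distance",
    "center_distance_timecourse",
    "fft_oscillation_metrics",
    "extrema_oscillation_metrics",
    "cross_check_methods",
    "drift_amplitudes",
    "lagging_time",
    "missegregation_flag",
    "max_poleward_speed",
    "klp5_profile_stats",
    "summarize_groups",
]

#: Peaks below this frequency (Hz) are discarded by the Fourier method --
#: slower components are drifts of the oscillation midline, not oscillations.
FFT_HIGHPASS_HZ = 5e-3
#: Minimum series length for a meaningful spectrum.
FFT_MIN_SAMPLES = 64


@dataclass
class TrackedTrajectory:
    """Per-frame 1-D positions of the two poles and two sister centromeres.

    Positions are on the spindle axis in microns; ``mid`` is always
    recomputed from the sisters.  ``burst`` optionally labels frames inside
    a checkpoint-signal (detachment) event.
    """

    t: np.ndarray
    pole1: np.ndarray
    pole2: np.ndarray
    cenA: np.ndarray
    cenB: np.ndarray
    burst: np.ndarray | None = None
    anaphase_onset: float | None = None

    def __post_init__(self):
        for name in ("t", "pole1", "pole2", "cenA", "cenB"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.burst is not None:
            self.burst = np.asarray(self.burst, dtype=bool)
        n = len(self.t)
        for name in ("pole1", "pole2", "cenA", "cenB"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.cenA + self.cenB)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.pole1 + self.pole2)

    @property
    def spindle_length(self) -> np.ndarray:
        return np.abs(self.pole2 - self.pole1)

    def to_frame(self) -> pd.DataFrame:
        cols = dict(
            t=self.t, pole1=self.pole1, pole2=self.pole2,
            cenA=self.cenA, cenB=self.cenB,
        )
        if self.burst is not None:
            cols["burst"] = self.burst.astype(int)
        return pd.DataFrame(cols)


@dataclass
class OscillationMetrics:
    """Amplitude / half-period summary of one trajectory.

    ``segments`` lists the semi-period windows ``(start_t, end_t,
    extremum_value)`` found by the extrema method (empty for the Fourier
    method); ``drifts`` the midline displacements between consecutive
    segments.
    """

    amplitude: float
    half_period: float
    method: str
    frequency: float | None = None
    segments: list = field(default_factory=list)
    drifts: list = field(default_factory=list)

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.half_period <= 0:
            raise ValueError("half_period must be > 0")

    @property
    def period(self) -> float:
        return 2.0 * self.half_period


@dataclass
class IntensityProfile:
    """1-D fluorescence intensity along one microtubule, minus to plus end."""

    values: np.ndarray
    length: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 3:
            raise ValueError("profile needs >= 3 samples")
        if self.length <= 0:
            raise ValueError("length must be > 0")


class InvalidFrameError(ValueError):
    """A tracked frame that cannot be assigned (spot count != 4)."""


def assign_and_project(spots) -> dict:
    """Assign 4 image-plane spots to poles / centromeres and project.

    The pair with the maximal pairwise distance is taken as the SPBs; the
    remaining two spots are the sister centromeres.  All four are projected
    orthogonally onto the pole-pole axis and reported relative to the
    spindle centre (pole midpoint), with ``pole1 < pole2`` and
    ``cenA <= cenB``.
    """
    pts = np.asarray(spots, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] != 4:
        raise InvalidFrameError(f"expected 4 spots, got {pts.shape[0]}")
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    cen_idx = [k for k in range(4) if k not in (i, j)]
    p1, p2 = pts[i], pts[j]
    axis = p2 - p1
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InvalidFrameError("degenerate frame: coincident poles")
    axis = axis / norm
    # deterministic orientation: axis points toward the lexicographically
    # larger pole
    if tuple(p2) < tuple(p1):
        p1, p2 = p2, p1
        axis = -axis
    center = 0.5 * (p1 + p2)
    proj = (pts - center) @ axis
    c = sorted(proj[cen_idx])
    return dict(
        pole1=float(min(proj[i], proj[j])),
        pole2=float(max(proj[i], proj[j])),
        cenA=float(c[0]),
        cenB=float(c[1]),
    )


def track_frames(times, frames) -> TrackedTrajectory:
    """Build a trajectory from per-frame spot sets, skipping invalid frames.

    Frames whose spot count differs from 4 are dropped (and logged), not
    interpolated.
    """
    rows, ts = [], []
    for t, spots in zip(times, frames):
        try:
            rows.append(assign_and_project(spots))
            ts.append(t)
        except InvalidFrameError as exc:
            logger.warning("frame t=%s skipped: %s", t, exc)
    if not rows:
        raise ValueError("no valid frames")
    df = pd.DataFrame(rows)
    return TrackedTrajectory(
        np.asarray(ts), df["pole1"].values, df["pole2"].values,
        df["cenA"].values, df["cenB"].values,
    )


def normalized_distance(mid, pole1, pole2):
    """Distance of a sister-pair midpoint to the spindle centre, normalized
    by spindle length: 0 at the centre, 0.5 at a pole.  Values beyond 0.5
    (kinetochore outside the pole span) are allowed but logged."""
    mid = np.asarray(mid, dtype=float)
    p1 = np.asarray(pole1, dtype=float)
    p2 = np.asarray(pole2, dtype=float)
    length = np.abs(p2 - p1)
    if np.any(length == 0):
        raise ValueError("zero spindle length")
    nd = np.abs(mid - 0.5 * (p1 + p2)) / length
    if np.any(nd > 0.5):
        logger.warning("normalized distance beyond 0.5: kinetochore outside pole span")
    return nd[()] if nd.ndim == 0 else nd


def center_distance_timecourse(
    trajs: list[TrackedTrajectory], dt: float | None = None
) -> pd.DataFrame:
    """Ensemble mean +/- s.d. of |midpoint - centre| and pole distance,
    aligned on anaphase onset (time 0 = onset; metaphase times negative).

    Each trajectory must carry an ``anaphase_onset`` annotation.  Curves
    are resampled to a common grid with spacing ``dt`` (default: median
    sampling interval of the first trajectory).  Distances are absolute and
    *not* normalized by spindle size.
    """
    if not trajs:
        raise ValueError("empty trajectory collection")
    for traj in trajs:
        if traj.anaphase_onset is None:
            raise ValueError("every trajectory needs an anaphase_onset annotation")
    if dt is None:
        dt = float(np.median(np.diff(trajs[0].t)))
    lo = min(traj.t[0] - traj.anaphase_onset for traj in trajs)
    hi = max(traj.t[-1] - traj.anaphase_onset for traj in trajs)
    grid = np.arange(np.floor(lo / dt) * dt, hi + 0.5 * dt, dt)
    cen = np.full((len(trajs), grid.size), np.nan)
    pol = np.full((len(trajs), grid.size), np.nan)
    for k, traj in enumerate(trajs):
        rel = traj.t - traj.anaphase_onset
        inside = (grid >= rel[0]) & (grid <= rel[-1])
        cen[k, inside] = np.interp(
            grid[inside], rel, np.abs(traj.mid - traj.center)
        )
        pol[k, inside] = np.interp(grid[inside], rel, 0.5 * traj.spindle_length)
    n = np.sum(~np.isnan(cen), axis=0)
    keep = n > 0
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            dict(
                time=grid[keep],
                mean_cen=np.nanmean(cen[:, keep], axis=0),
                sd_cen=np.nanstd(cen[:, keep], axis=0, ddof=0),
                mean_pole=np.nanmean(pol[:, keep], axis=0),
                sd_pole=np.nanstd(pol[:, keep], axis=0, ddof=0),
                n=n[keep],
            )
        )
    return out


def fft_oscillation_metrics(
    x,
    dt: float,
    t=None,
    min_freq: float = FFT_HIGHPASS_HZ,
) -> OscillationMetrics | None:
    """Oscillation amplitude and half-period from the Fourier spectrum.

    The mean-detrended series is transformed, the magnitude spectrum is
    scaled by 2/N so a pure sinusoid of amplitude A gives a peak of height
    ~A, and local maxima below ``min_freq`` are excluded (high-pass: slower
    components are midline drifts).  The dominant remaining peak defines
    the oscillation: its frequency is refined by parabolic interpolation
    and its amplitude by summing spectral energy over the peak and its two
    neighbours, which keeps the estimate within a few percent of the true
    amplitude regardless of spectral leakage.  Half-period = 1/(2 f_peak).
    Returns None when no qualifying peak exists.
    """
    x = np.asarray(x, dtype=float)
    if x.size < FFT_MIN_SAMPLES:
        raise ValueError(f"series shorter than {FFT_MIN_SAMPLES} samples")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t is not None:
        steps = np.diff(np.asarray(t, dtype=float))
        if steps.size and (np.max(steps) - np.min(steps)) > 1e-6 * np.median(steps):
            raise ValueError("non-uniform sampling")
    n = x.size
    spec = np.abs(np.fft.rfft(x - x.mean())) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=dt)
    peaks, _ = signal.find_peaks(spec)
    peaks = peaks[freqs[peaks] >= min_freq]
    # numerical-noise floor: a genuine peak must carry real energy
    peaks = peaks[spec[peaks] > 1e-9 * max(spec.max(), 1e-300)]
    if peaks.size == 0:
        return None
    k = peaks[np.argmax(spec[peaks])]
    # two-point frequency refinement (exact for a rectangular window whose
    # spectral kernel is a Dirichlet/sinc shape)
    if 0 < k < spec.size - 1:
        if spec[k + 1] >= spec[k - 1]:
            r = spec[k + 1] / spec[k]
            delta = r / (1.0 + r)
        else:
            r = spec[k - 1] / spec[k]
            delta = -r / (1.0 + r)
    else:
        delta = 0.0
    f_peak = (k + delta) / (n * dt)
    lo, hi = max(k - 1, 1), min(k + 1, spec.size - 1)
    amplitude = float(np.sqrt(np.sum(spec[lo : hi + 1] ** 2)))
    if f_peak <= 0:
        return None
    return OscillationMetrics(
        amplitude=amplitude,
        half_period=1.0 / (2.0 * f_peak),
        frequency=float(f_peak),
        method="fft",
    )


def _smoothing_spline(t, x, smoothing: float | None):
    """Cubic smoothing spline with a data-driven default strength.

    The noise level is estimated from second differences (which annihilate
    locally linear signal, so slow ramps and oscillations do not inflate
    it) via the median absolute deviation: sigma_hat = 1.4826 * MAD(d2x) /
    sqrt(6).  The spline residual budget is s = n * sigma_hat^2, which
    reduces to an interpolating spline on noiseless data.
    """
    if smoothing is None:
        d2 = np.diff(x, n=2)
        sigma = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / np.sqrt(6.0)
        smoothing = len(x) * sigma**2
    if smoothing <= (len(x) * (1e-8 * (np.ptp(x) + 1e-300)) ** 2):
        smoothing = 0  # noiseless: interpolate exactly
    return interpolate.UnivariateSpline(t, x, k=3, s=smoothing)


def extrema_oscillation_metrics(
    x, t, smoothing: float | None = None
) -> OscillationMetrics | None:
    """Oscillation metrics from local extrema of a spline-smoothed series.

    Alternating maxima / minima are located on the smoothed trajectory; the
    midpoint in time between two consecutive extrema starts a semi-period
    and the following midpoint ends it, so semi-period i spans
    ``(e_i + e_{i+1})/2`` to ``(e_{i+1} + e_{i+2})/2``.  Per-segment
    amplitude is half the peak-to-trough excursion; the summary is the mean
    over segments.  Returns None with fewer than 3 extrema.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size != t.size:
        raise ValueError("x and t length mismatch")
    if x.size < 8:
        return None
    spl = _smoothing_spline(t, x, smoothing)
    ts = np.linspace(t[0], t[-1], max(4 * t.size, 512))
    y = spl(ts)
    # an extremum must be a real swing (a few percent of the overall range),
    # not corner ringing of the spline or residual noise texture
    prom = max(1e-12, 0.05 * float(np.ptp(y)))
    i_max, _ = signal.find_peaks(y, prominence=prom)
    i_min, _ = signal.find_peaks(-y, prominence=prom)
    idx = np.sort(np.concatenate([i_max, i_min]))
    if idx.size < 3:
        return None
    # enforce alternation: collapse runs of same-kind extrema to the extreme one
    kinds = np.isin(idx, i_max)
    keep = []
    for i, kind in zip(idx, kinds):
        if keep and kinds_last == kind:
            prev = keep[-1]
            better = y[i] > y[prev] if kind else y[i] < y[prev]
            if better:
                keep[-1] = i
        else:
            keep.append(i)
            kinds_last = kind
    idx = np.asarray(keep)
    if idx.size < 3:
        return None
    te, ye = ts[idx], y[idx]
    bounds = 0.5 * (te[:-1] + te[1:])
    segments = [
        (float(bounds[i]), float(bounds[i + 1]), float(ye[i + 1]))
        for i in range(len(bounds) - 1)
    ]
    semi_periods = np.diff(bounds)
    amplitudes = 0.5 * np.abs(np.diff(ye))
    # excursion amplitude per segment: pair each segment with the swing into
    # its extremum
    seg_amp = amplitudes[: len(segments)]
    return OscillationMetrics(
        amplitude=float(np.mean(seg_amp)),
        half_period=float(np.mean(semi_periods)),
        method="extrema",
        segments=segments,
    )


def cross_check_methods(
    x, t, rel_tol: float = 0.5
) -> tuple[OscillationMetrics | None, OscillationMetrics | None, bool]:
    """Run both oscillation methods and flag disagreement beyond
    ``rel_tol`` (relative, on amplitude or half-period)."""
    dt = float(np.median(np.diff(t)))
    m_fft = fft_oscillation_metrics(x, dt, t=t) if len(x) >= FFT_MIN_SAMPLES else None
    m_ext = extrema_oscillation_metrics(x, t)
    flag = False
    if m_fft is not None and m_ext is not None:
        rel_a = abs(m_fft.amplitude - m_ext.amplitude) / max(m_fft.amplitude, 1e-12)
        rel_p = abs(m_fft.half_period - m_ext.half_period) / m_fft.half_period
        flag = rel_a > rel_tol or rel_p > rel_tol
        if flag:
            logger.warning(
                "oscillation methods disagree: fft (A=%.3f, T12=%.1f) vs "
                "extrema (A=%.3f, T12=%.1f)",
                m_fft.amplitude, m_fft.half_period,
                m_ext.amplitude, m_ext.half_period,
            )
    return m_fft, m_ext, flag


def drift_amplitudes(x, t, segments, smoothing: float | None = None) -> list[float]:
    """Midline displacement between consecutive oscillation events.

    Each semi-period segment from :func:`extrema_oscillation_metrics`
    starts at the time-midpoint between two extrema, where the smoothed
    trajectory crosses its local oscillation midline; the crossing value
    therefore estimates the midline free of the oscillation component.
    drift_i = |midline(segment i+1) - midline(segment i)|, one value per
    consecutive segment pair.  For a strictly stationary oscillation every
    crossing sits at the same midline, so all drifts are ~0.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(segments) < 2:
        return []
    spl = _smoothing_spline(t, x, smoothing)
    starts = np.asarray([seg[0] for seg in segments], dtype=float)
    vals = spl(starts)
    return [float(v) for v in np.abs(np.diff(vals))]


def lagging_time(
    traj: TrackedTrajectory,
    anaphase_onset: float | None = None,
    epsilon: float = 0.2,
) -> tuple[float, bool, dict]:
    """Delay between the arrivals of the two sisters at their poles.

    From anaphase onset, each sister's target pole is the pole it is
    nearest at the last frame; its arrival time is the first frame at which
    it comes within ``epsilon`` um of that (tracked, moving) pole.  Returns
    ``(lag_seconds, censored, detail)``; ``lag`` is NaN and ``censored``
    True when a sister never arrives.  Symmetric in the sister labels.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if anaphase_onset is None:
        anaphase_onset = traj.anaphase_onset
    if anaphase_onset is None:
        raise ValueError("missing anaphase onset annotation")
    sel = traj.t >= anaphase_onset
    if not np.any(sel):
        raise ValueError("trajectory ends before anaphase onset")
    t = traj.t[sel]
    poles = np.stack([traj.pole1[sel], traj.pole2[sel]], axis=1)
    arrivals = {}
    censored = False
    for name, cen in (("cenA", traj.cenA[sel]), ("cenB", traj.cenB[sel])):
        target = int(np.argmin(np.abs(poles[-1] - cen[-1])))
        hit = np.flatnonzero(np.abs(cen - poles[:, target]) <= epsilon)
        if hit.size:
            arrivals[name] = float(t[hit[0]])
        else:
            arrivals[name] = np.nan
            censored = True
    lag = (
        abs(arrivals["cenA"] - arrivals["cenB"]) if not censored else float("nan")
    )
    return lag, censored, arrivals


def missegregation_flag(traj: TrackedTrajectory) -> bool:
    """True iff both sisters end on the same side of the spindle centre
    (two centromere signals at the same pole).  A sister exactly at the
    centre counts as not mis-segregated."""
    center = traj.center[-1]
    sideA = np.sign(traj.cenA[-1] - center)
    sideB = np.sign(traj.cenB[-1] - center)
    return bool(sideA == sideB and sideA != 0)


def max_poleward_speed(x, t, window: int = 5) -> float:
    """Maximum |velocity| of a window-smoothed trace, in um/min.

    A centered moving average of ``window`` samples (odd, >= 3) suppresses
    localization noise before the centered finite difference.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    if x.size < window:
        raise ValueError("interval shorter than window")
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    xs = np.convolve(xp, kernel, mode="valid")
    v = np.gradient(xs, t)
    return float(np.max(np.abs(v)) * 60.0)


def klp5_profile_stats(
    profiles: list[IntensityProfile],
    bins,
    n_resample: int = 101,
    tip_fraction: float = 0.1,
):
    """Length-binned, median-normalized intensity profiles and tip signal.

    Each profile is divided by its own median intensity (profiles with zero
    median are excluded and logged), resampled onto a fractional position
    axis [0, 1] (0 = minus end, 1 = plus end), and averaged within
    microtubule-length bins.  The plus-end ("tip") intensity of a profile
    is the mean of its last ``tip_fraction`` of samples (at least one).

    Returns ``(tips, mean_profiles)`` where ``tips`` is a per-bin table
    (bin edges, n, mean and s.e.m. of tip intensity) and ``mean_profiles``
    maps bin index to a DataFrame with the fractional position, mean and
    s.d. of the normalized profile.  Monotonicity of the tip intensity with
    length is reported in ``tips.attrs['tip_monotonic']``, not assumed.
    """
    bins = np.asarray(bins, dtype=float)
    if bins.size < 2 or np.any(np.diff(bins) <= 0):
        raise ValueError("bins must be ordered length edges")
    pos = np.linspace(0.0, 1.0, n_resample)
    per_bin_profiles: dict[int, list[np.ndarray]] = {}
    per_bin_tips: dict[int, list[float]] = {}
    for k, prof in enumerate(profiles):
        med = np.median(prof.values)
        if med == 0:
            logger.warning("profile %d excluded: zero median intensity", k)
            continue
        norm = prof.values / med
        b = int(np.digitize(prof.length, bins)) - 1
        if b < 0 or b >= bins.size - 1:
            logger.debug("profile %d outside bin range (length %.2f)", k, prof.length)
            continue
        src = np.linspace(0.0, 1.0, norm.size)
        per_bin_profiles.setdefault(b, []).append(np.interp(pos, src, norm))
        n_tip = max(1, int(np.ceil(tip_fraction * norm.size)))
        per_bin_tips.setdefault(b, []).append(float(np.mean(norm[-n_tip:])))

    rows = []
    mean_profiles = {}
    for b in sorted(per_bin_profiles):
        stack = np.vstack(per_bin_profiles[b])
        mean_profiles[b] = pd.DataFrame(
            dict(
                position=pos,
                mean=stack.mean(axis=0),
                sd=stack.std(axis=0, ddof=0),
            )
        )
        tips = np.asarray(per_bin_tips[b])
        rows.append(
            dict(
                bin=b, length_lo=bins[b], length_hi=bins[b + 1],
                n=len(tips), tip_mean=tips.mean(),
                tip_sem=tips.std(ddof=1) / np.sqrt(len(tips))
                if len(tips) > 1 else np.nan,
            )
        )
    tips_df = pd.DataFrame(rows)
    if len(tips_df) > 1:
        tips_df.attrs["tip_monotonic"] = bool(
            np.all(np.diff(tips_df["tip_mean"].values) > 0)
        )
    else:
        tips_df.attrs["tip_monotonic"] = True
    return tips_df, mean_profiles


def summarize_groups(groups: dict, pairs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean +/- s.e.m. and unpaired two-sided Student's t-tests.

    ``groups`` maps group name to a 1-D sample; ``pairs`` optionally lists
    the (name, name) comparisons (default: all consecutive pairs).
    """
    cleaned = {}
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        cleaned[name] = v
    summary = pd.DataFrame(
        [
            dict(
                group=name, n=v.size, mean=v.mean(),
                sem=v.std(ddof=1) / np.sqrt(v.size),
            )
            for name, v in cleaned.items()
        ]
    )
    names = list(cleaned)
    if pairs is None:
        pairs = list(zip(names[:-1], names[1:]))
    rows = []
    for a, b in pairs:
        tt = stats.ttest_ind(cleaned[a], cleaned[b])
        rows.append(dict(group1=a, group2=b, t=tt.statistic, p=tt.pvalue))
    return summary, pd.DataFrame(rows)
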