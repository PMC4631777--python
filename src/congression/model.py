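"""Coarse-grained stochastic force-balance model of the fission-yeast spindle.

The metaphase spindle is reduced to a 1-D axis: two spindle pole bodies
(SPBs) pushed apart by the interdigitated-microtubule midzone force
generator, three chromosomes whose sister centromeres are tied by a single
cohesin spring, and three microtubule attachment sites per kinetochore that
stochastically attach to / detach from the poles.  An attached site is
pulled toward its pole by a linear force-velocity motor, optionally scaled
by a length-dependent prefactor ``L_dep`` that grows with the site-to-pole
distance -- the coarse-grained signature of kinesin-8's length-dependent
depolymerase activity.  All elements move overdamped (drag * velocity =
sum of forces).

Units: microns, seconds; forces are nondimensional with the single-motor
stall force ``F_k = 1`` as the unit; drags are force*s/um, springs force/um.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernel

logger = logging.getLogger(__name__)

__all__ = [
    "ModelParams",
    "SpindleState",
    "SimTrajectory",
    "EnsembleResult",
    "length_dep_factor",
    "pulling_force",
    "detachment_rate",
    "choose_attachment_pole",
    "step_dynamics",
    "simulate_mitosis",
    "run_ensemble",
    "parameter_sweep",
    "DEFAULT_SWEEP_FACTORS",
    "PATHOLOGY_LENGTH_RANGE",
    "PATHOLOGY_ISD_RANGE",
]


@dataclass
class ModelParams:
    """Every parameter of the force-balance model plus integration settings.

    Defaults are the calibrated wild-type-like condition: with
    ``ldep_enabled`` the ensemble-mean normalized anaphase-onset distance of
    kinetochores to the spindle centre is ~0.11 (wild type), without it
    ~0.24 (kinesin-8 deletion), and the mean metaphase inter-sister
    distance is ~0.5 um.
    """

    # pulling-force motor at each attachment site
    F_k: float = 1.0           # stall force (force unit)
    V_k: float = 0.15          # maximum velocity, um/s
    # stochastic attachment / detachment
    k_a: float = 0.045          # attachment rate, 1/s
    k_d: float = 0.03          # baseline detachment rate, 1/s
    d_alpha: float = 0.25      # spatial range of Aurora-B-like activity, um
    d_floor: float = 0.01      # lower clamp on site-to-centre distance, um
    beta: float = 0.9          # orientation-effect parameter in [0, 1]
    # cohesin spring between sister centromeres
    K_c: float = 5.0           # spring constant, force/um
    d_0: float = 0.2           # rest length, um
    # centromere <-> attachment-site spring and damper
    K_k: float = 10.0
    mu_k: float = 2.0
    # midzone force generator acting on the poles
    F_mz: float = 8.0          # stall force
    V_mz: float = 0.01         # maximum velocity, um/s
    # drag coefficients
    mu_spb: float = 100.0
    mu_ch: float = 30.0
    mu_site: float = 2.0
    # geometry / composition
    N_ch: int = 3              # chromosomes
    M_sites: int = 3           # attachment sites per kinetochore
    L0: float = 0.5            # initial spindle length, um
    # length-dependent pulling-force prefactor
    alpha: float = 0.2         # strength of the length dependence
    d_mean: float = 1.0        # mean site-to-pole distance, um
    ldep_enabled: bool = True
    # integration / schedule
    dt: float = 0.05           # Euler step, s
    t_meta: float = 600.0      # metaphase duration, s (anaphase trigger)
    t_ana: float = 300.0       # simulated anaphase-A duration, s
    out_dt: float = 1.0        # snapshot interval, s
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on any violation."""
        nonneg = [
            "F_k", "k_a", "k_d", "d_alpha", "K_c", "d_0", "K_k", "mu_k",
            "F_mz", "mu_spb", "mu_ch", "mu_site", "alpha",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        positive = ["V_k", "V_mz", "d_mean", "dt", "out_dt", "L0", "d_floor"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.N_ch < 1:
            raise ValueError(f"N_ch must be >= 1, got {self.N_ch}")
        if self.M_sites < 1:
            raise ValueError(f"M_sites must be >= 1, got {self.M_sites}")
        if self.t_meta < 0 or self.t_ana < 0:
            raise ValueError("t_meta and t_ana must be >= 0")
        for name in ("k_a", "k_d"):
            if getattr(self, name) * self.dt >= 0.1:
                raise ValueError(
                    f"dt too large for rate {name}: {name}*dt = "
                    f"{getattr(self, name) * self.dt:.3f} >= 0.1"
                )
        if self.out_dt < self.dt:
            raise ValueError("out_dt must be >= dt")

    def replace(self, **kwargs) -> "ModelParams":
        p = dataclasses.replace(self, **kwargs)
        p.validate()
        return p

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def length_dep_factor(
    d_site_pole, alpha: float, d_mean: float, enabled: bool = True
):
    """Length-dependent prefactor on the pulling force.

    ``L_dep = 1 + alpha * (d_site_pole / d_mean - 1)``, clamped at >= 0, so
    that the prefactor is exactly 1 at the mean site-to-pole geometry and
    ``alpha`` is the fractional force change per fractional length change.
    Returns 1 when ``enabled`` is false.  Accepts scalars or arrays.
    """
    d = np.asarray(d_site_pole, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_site_pole must be >= 0")
    if d_mean <= 0:
        raise ValueError("d_mean must be > 0")
    if not enabled:
        return np.ones_like(d)[()] if d.ndim else 1.0
    out = np.maximum(1.0 + alpha * (d / d_mean - 1.0), 0.0)
    return out[()] if d.ndim == 0 else out


def pulling_force(v, pi, ldep: float, F_k: float, V_k: float):
    """Linear force-velocity pulling force at one attachment site.

    ``F = ldep * F_k * (1 - v / V_k) * pi`` where ``v`` is the site speed
    toward its attached pole (so the force vanishes at ``v = V_k``) and
    ``pi`` in {-1, 0, +1} is the attachment state.  Detached sites (pi = 0)
    exert no force.
    """
    if V_k <= 0:
        raise ValueError("V_k must be > 0")
    v = np.asarray(v, dtype=float)
    pi = np.asarray(pi)
    out = ldep * F_k * (1.0 - v / V_k) * pi
    return out[()] if out.ndim == 0 else out


def detachment_rate(d_site_center, k_d: float, d_alpha: float, d_floor: float = 0.01):
    """Effective detachment rate of an attached site.

    ``rate = k_d * d_alpha / max(d_site_center, d_floor)`` -- attachments
    close to the sister-pair centre (low tension, within the spatial range
    ``d_alpha`` of the Aurora-B-like activity) are destabilised; stretched
    attachments are stabilised.  The clamp ``d_floor`` keeps the rate finite.
    """
    if d_alpha <= 0:
        raise ValueError("d_alpha must be > 0")
    d = np.asarray(d_site_center, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_site_center must be >= 0")
    out = k_d * d_alpha / np.maximum(d, d_floor)
    return out[()] if out.ndim == 0 else out


def choose_attachment_pole(
    n_left: int, n_right: int, correct_pole: int, beta: float, rng: np.random.Generator
) -> int:
    """Pole label (0 = left, 1 = right) for a newly attaching site.

    If the sister pair currently holds no attachment at all, both poles are
    equiprobable.  Otherwise the attachment is biased toward the correct
    pole with probability ``(1 + beta) / 2`` -- beta = 1 makes a new
    attachment of an oriented pair always correct, beta = 0 makes correct
    and erroneous attachments equiprobable.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    if correct_pole not in (0, 1):
        raise ValueError("correct_pole must be 0 or 1")
    if n_left == 0 and n_right == 0:
        return 0 if rng.random() < 0.5 else 1
    if rng.random() < 0.5 * (1.0 + beta):
        return correct_pole
    return 1 - correct_pole


@dataclass
class SpindleState:
    """Snapshot of all 1-D positions and attachment states.

    ``att`` holds the attached pole per site (-1 detached, 0 left, 1 right);
    ``pi`` the correctness bookkeeping in {-1, 0, +1}.  ``v_cen`` /
    ``v_site`` carry the previous-step velocities used by the spring-damper
    cross terms.
    """

    t: float
    x_spb: np.ndarray          # (2,)
    x_cen: np.ndarray          # (N, 2)
    x_site: np.ndarray         # (N, 2, M)
    att: np.ndarray            # (N, 2, M) int8
    pi: np.ndarray             # (N, 2, M) int8
    anaphase: bool = False
    v_cen: np.ndarray | None = None
    v_site: np.ndarray | None = None

    def __post_init__(self):
        if self.v_cen is None:
            self.v_cen = np.zeros_like(self.x_cen)
        if self.v_site is None:
            self.v_site = np.zeros_like(self.x_site)

    @property
    def spindle_length(self) -> float:
        return float(self.x_spb[1] - self.x_spb[0])

    @classmethod
    def initial(cls, params: ModelParams) -> "SpindleState":
        N, M = params.N_ch, params.M_sites
        x_spb = np.array([-0.5 * params.L0, 0.5 * params.L0])
        x_cen = np.tile([-0.5 * params.d_0, 0.5 * params.d_0], (N, 1))
        x_site = np.repeat(x_cen[:, :, None], M, axis=2).astype(float)
        att = -np.ones((N, 2, M), dtype=np.int8)
        pi = np.zeros((N, 2, M), dtype=np.int8)
        return cls(0.0, x_spb, x_cen.astype(float), x_site, att, pi)


def step_dynamics(
    state: SpindleState, params: ModelParams, rng: np.random.Generator
) -> SpindleState:
    """Advance the state by one Euler step ``params.dt``.

    Mechanics first (overdamped force balance on sites, centromeres and
    poles), then stochastic attachment events with probability ``k_a*dt``
    per detached site and detachment events with probability
    ``detachment_rate*dt`` per attached site (both clamped to [0, 1]).
    Randomness is drawn from ``rng``; the compiled ensemble path uses its
    own seeded stream but identical update rules.
    """
    params.validate()
    new = SpindleState(
        t=state.t + params.dt,
        x_spb=state.x_spb.copy(),
        x_cen=state.x_cen.copy(),
        x_site=state.x_site.copy(),
        att=state.att.copy(),
        pi=state.pi.copy(),
        anaphase=state.anaphase,
        v_cen=state.v_cen.copy(),
        v_site=state.v_site.copy(),
    )
    metaphase = not state.anaphase
    ldep_on = bool(params.ldep_enabled and metaphase)
    v_poles = np.zeros(2)
    _kernel.advance_positions(
        new.x_spb, new.x_cen, new.x_site, new.att, new.v_cen, new.v_site,
        v_poles,
        params.F_k, params.V_k, params.K_c, params.d_0, params.K_k,
        params.mu_k, params.mu_site, params.mu_ch, params.mu_spb,
        params.F_mz, params.V_mz, params.alpha, params.d_mean,
        ldep_on, metaphase, params.dt,
    )
    shape = new.x_site.shape
    u_evt = rng.random(shape)
    u_pole = rng.random(shape)
    _kernel.attachment_events(
        new.x_cen, new.x_site, new.att, new.pi,
        params.k_a, params.k_d, params.d_alpha, params.d_floor,
        params.beta, params.dt, u_evt, u_pole,
    )
    return new


@dataclass
class SimTrajectory:
    """Fixed-interval snapshot record of one simulation."""

    t: np.ndarray              # (n,)
    x_spb: np.ndarray          # (n, 2)
    x_cen: np.ndarray          # (n, N, 2)
    x_site: np.ndarray         # (n, N, 2, M)
    att: np.ndarray            # (n, N, 2, M) int8
    pi: np.ndarray             # (n, N, 2, M) int8
    anaphase: np.ndarray       # (n,) bool
    params: ModelParams
    seed: int

    @property
    def n_chromosomes(self) -> int:
        return self.x_cen.shape[1]

    @property
    def spindle_length(self) -> np.ndarray:
        return self.x_spb[:, 1] - self.x_spb[:, 0]

    @property
    def spindle_center(self) -> np.ndarray:
        return 0.5 * (self.x_spb[:, 0] + self.x_spb[:, 1])

    def anaphase_onset_index(self) -> int:
        """Index of the last metaphase snapshot (the anaphase-onset frame)."""
        idx = np.flatnonzero(self.anaphase)
        return int(idx[0] - 1) if idx.size else len(self.t) - 1

    def states(self) -> Iterator[SpindleState]:
        for i in range(len(self.t)):
            yield SpindleState(
                float(self.t[i]), self.x_spb[i], self.x_cen[i],
                self.x_site[i], self.att[i], self.pi[i],
                bool(self.anaphase[i]),
            )

    def to_tracked(self, chromosome: int):
        """View one chromosome as an experimental-style tracked trajectory."""
        from .analysis import TrackedTrajectory

        return TrackedTrajectory(
            t=self.t.copy(),
            pole1=self.x_spb[:, 0].copy(),
            pole2=self.x_spb[:, 1].copy(),
            cenA=self.x_cen[:, chromosome, 0].copy(),
            cenB=self.x_cen[:, chromosome, 1].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide per-snapshot table (the CSV dialect written by the CLI)."""
        n, N, _, M = self.x_site.shape
        cols: dict[str, np.ndarray] = {
            "t": self.t,
            "x_spbL": self.x_spb[:, 0],
            "x_spbR": self.x_spb[:, 1],
        }
        for c in range(N):
            for s in range(2):
                cols[f"cen_{c}_{s}"] = self.x_cen[:, c, s]
        for c in range(N):
            for s in range(2):
                for m in range(M):
                    cols[f"site_{c}_{s}_{m}"] = self.x_site[:, c, s, m]
        for c in range(N):
            for s in range(2):
                for m in range(M):
                    cols[f"pi_{c}_{s}_{m}"] = self.pi[:, c, s, m]
        cols["anaphase"] = self.anaphase.astype(int)
        return pd.DataFrame(cols)


def simulate_mitosis(params: ModelParams, seed: int | None = None) -> SimTrajectory:
    """Run one full simulation: metaphase for ``t_meta`` seconds, then
    anaphase A (cohesin released, length-dependent prefactor off, erroneous
    attachments kept) for ``t_ana`` seconds.  Deterministic given the seed.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in uint32")
    n_meta = int(round(params.t_meta / params.dt))
    n_total = n_meta + int(round(params.t_ana / params.dt))
    rec_every = max(1, int(round(params.out_dt / params.dt)))
    t, poles, cen, site, att, pi, ana = _kernel.simulate_core(
        seed, params.N_ch, params.M_sites,
        params.F_k, params.V_k, params.k_a, params.k_d, params.d_alpha,
        params.d_floor, params.beta,
        params.K_c, params.d_0, params.K_k, params.mu_k, params.mu_site,
        params.mu_ch, params.mu_spb,
        params.F_mz, params.V_mz, params.alpha, params.d_mean,
        bool(params.ldep_enabled),
        params.dt, n_meta, n_total, rec_every, params.L0,
    )
    return SimTrajectory(t, poles, cen, site, att, pi, ana, params, seed)


def _summarize_run(traj: SimTrajectory, run: int, arrival_epsilon: float) -> list[dict]:
    """Per-chromosome observables of one run (anaphase-onset nd, metaphase
    inter-sister distance, lagging time, mis-segregation)."""
    from .analysis import lagging_time, missegregation_flag, normalized_distance

    i_on = traj.anaphase_onset_index()
    meta = slice(0, i_on + 1)
    center = traj.spindle_center
    length = traj.spindle_length
    rows = []
    for c in range(traj.n_chromosomes):
        mid = 0.5 * (traj.x_cen[:, c, 0] + traj.x_cen[:, c, 1])
        nd = normalized_distance(
            mid[i_on], traj.x_spb[i_on, 0], traj.x_spb[i_on, 1]
        )
        isd = np.abs(traj.x_cen[meta, c, 0] - traj.x_cen[meta, c, 1]).mean()
        tracked = traj.to_tracked(c)
        onset_t = float(traj.t[i_on])
        lag, censored, _ = lagging_time(tracked, onset_t, epsilon=arrival_epsilon)
        misseg = missegregation_flag(tracked)
        rows.append(
            dict(
                run=run, seed=traj.seed, chromosome=c,
                nd_anaphase=float(nd), isd_metaphase=float(isd),
                lagging_time=lag, lagging_censored=censored,
                missegregated=misseg,
                spindle_length_anaphase=float(length[i_on]),
            )
        )
    return rows


@dataclass
class EnsembleResult:
    """Summary (and optionally the trajectories) of a seeded ensemble."""

    summary: pd.DataFrame
    trajectories: list[SimTrajectory] = field(default_factory=list)
    params: ModelParams | None = None

    @property
    def mean_nd(self) -> float:
        return float(self.summary["nd_anaphase"].mean())

    @property
    def sem_nd(self) -> float:
        x = self.summary["nd_anaphase"]
        return float(x.std(ddof=1) / np.sqrt(len(x)))


def run_ensemble(
    params: ModelParams,
    n_runs: int,
    base_seed: int = 0,
    store_trajectories: bool = True,
    arrival_epsilon: float = 0.2,
    progress: bool = False,
) -> EnsembleResult:
    """Run ``n_runs`` independent simulations with seeds ``base_seed + i``.

    The summary table has one row per run and chromosome with the
    anaphase-onset normalized distance to the spindle centre, the metaphase
    time-averaged inter-sister distance, the anaphase lagging time (NaN if
    a sister never reaches its pole within ``arrival_epsilon`` um) and the
    mis-segregation flag.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    params.validate()
    iterator = range(n_runs)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="ensemble", unit="run")
    rows: list[dict] = []
    trajs: list[SimTrajectory] = []
    for i in iterator:
        traj = simulate_mitosis(params, seed=base_seed + i)
        rows.extend(_summarize_run(traj, i, arrival_epsilon))
        if store_trajectories:
            trajs.append(traj)
    return EnsembleResult(pd.DataFrame(rows), trajs, params)


#: Default low/high multipliers probing each spindle process around the
#: calibrated operating point (MT attachment/detachment, error correction,
#: cohesion, midzone motors, pulling-motor speed).
#: Plausible-mitosis screens for sweep conditions (um).  Spindle lengths at
#: anaphase onset far outside the range observed across genotypes, or mean
#: inter-sister distances far from the ~0.5 um in vivo value, mark a
#: condition as an aberrant mitosis rather than genuine centering.
PATHOLOGY_LENGTH_RANGE: tuple[float, float] = (2.0, 8.0)
PATHOLOGY_ISD_RANGE: tuple[float, float] = (0.25, 1.2)

DEFAULT_SWEEP_FACTORS: dict[str, tuple[float, float]] = {
    "k_a": (0.5, 2.0),
    "k_d": (0.5, 2.0),
    "d_alpha": (0.5, 2.0),
    "K_c": (0.5, 2.0),
    "F_mz": (0.5, 2.0),
    "V_k": (0.5, 2.0),
}


def parameter_sweep(
    base: ModelParams,
    factors: Mapping[str, Sequence[float]] | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Low/high one-at-a-time sweep with the length dependence off.

    Each named parameter is multiplied by its low and high factor in turn
    (all simulations with ``ldep_enabled = False``), plus two reference
    rows: the unperturbed ldep-off baseline and the ldep-on condition.
    Returns a table of mean anaphase-onset normalized distance +/- s.e.m.,
    mean inter-sister distance and mean spindle length per condition.

    Each condition is also screened for aberrant mitotic phenotypes: a
    perturbation can shrink the *normalized* distance while wrecking the
    spindle, e.g. a weak midzone force collapses spindle elongation and a
    weak cohesin spring lets the inter-sister distance approach the whole
    spindle length.  A condition is flagged ``aberrant`` when its mean
    spindle length at anaphase onset leaves ``PATHOLOGY_LENGTH_RANGE`` or
    its mean metaphase inter-sister distance leaves ``PATHOLOGY_ISD_RANGE``
    (bounds bracketing the in vivo anchors: ~3-4.7 um spindles across
    genotypes, ~0.5 um inter-sister distance).
    """
    if factors is None:
        factors = DEFAULT_SWEEP_FACTORS
    for name in factors:
        if not hasattr(base, name):
            raise ValueError(f"unknown model parameter in sweep factors: {name!r}")

    conditions: list[tuple[str, str, float, ModelParams]] = [
        ("ldep_on", "-", 1.0, base.replace(ldep_enabled=True)),
        ("baseline_off", "-", 1.0, base.replace(ldep_enabled=False)),
    ]
    for name, (low, high) in factors.items():
        for label, mult in (("low", low), ("high", high)):
            p = base.replace(
                ldep_enabled=False, **{name: getattr(base, name) * mult}
            )
            conditions.append((name, label, mult, p))

    rows = []
    for name, level, mult, p in conditions:
        res = run_ensemble(
            p, n_runs, base_seed=base_seed, store_trajectories=False,
            progress=progress,
        )
        mean_isd = float(res.summary["isd_metaphase"].mean())
        mean_len = float(res.summary["spindle_length_anaphase"].mean())
        aberrant = not (
            PATHOLOGY_LENGTH_RANGE[0] <= mean_len <= PATHOLOGY_LENGTH_RANGE[1]
            and PATHOLOGY_ISD_RANGE[0] <= mean_isd <= PATHOLOGY_ISD_RANGE[1]
        )
        rows.append(
            dict(
                parameter=name, level=level, multiplier=mult,
                mean_nd=res.mean_nd, sem_nd=res.sem_nd,
                mean_isd=mean_isd, mean_spindle_length=mean_len,
                aberrant=aberrant, n_runs=n_runs,
            )
        )
        logger.info(
            "sweep %s/%s: nd = %.3f +/- %.3f%s", name, level,
            rows[-1]["mean_nd"], rows[-1]["sem_nd"],
            " (aberrant mitosis)" if aberrant else "",
        )
    return pd.DataFrame(rows)
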