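"""Configuration files, trajectory / profile CSV I/O and run manifests.

One CSV dialect (UTF-8, header, '.' decimal separator, full float
precision) is shared by the simulator output and the analyzer input, so
in-silico and in-vivo-style data flow through the same code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import IntensityProfile, TrackedTrajectory
from .model import ModelParams, SimTrajectory
from .synth import SynthParams

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "SchemaError",
    "load_config",
    "save_config",
    "read_trajectory",
    "write_trajectory",
    "read_sim_trajectory",
    "write_sim_trajectory",
    "sim_to_tracked_frames",
    "read_profiles",
    "write_profiles",
    "RunManifest",
]


def _fmt_float(x) -> str:
    """Shortest decimal representation that round-trips to the same float."""
    return repr(float(x))


class ConfigError(ValueError):
    """Invalid configuration file (unknown keys or invariant violations)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


def load_config(path, cls=ModelParams):
    """Load a YAML parameter file into ``cls`` (ModelParams or SynthParams).

    Missing keys take their defaults; an empty file yields all defaults;
    unknown keys and invariant violations raise :class:`ConfigError`
    naming the offending fields.
    """
    raw = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of parameter names")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown parameter(s): {', '.join(unknown)}")
    params = cls(**data)
    try:
        params.validate()
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return params


def save_config(params, path) -> None:
    """Write parameters as YAML (field names mirror the dataclass)."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=False), encoding="utf-8"
    )


_TRACKED_REQUIRED = ["t", "pole1", "pole2", "cenA", "cenB"]


def read_trajectory(path) -> TrackedTrajectory:
    """Read a tracked-trajectory CSV (t, pole1, pole2, cenA, cenB[, burst])."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACKED_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if np.any(np.diff(df["t"].values) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    burst = df["burst"].values.astype(bool) if "burst" in df.columns else None
    return TrackedTrajectory(
        df["t"].values, df["pole1"].values, df["pole2"].values,
        df["cenA"].values, df["cenB"].values, burst=burst,
    )


def write_trajectory(traj: TrackedTrajectory, path) -> None:
    """Write the tracked CSV dialect (shortest round-trip float precision)."""
    traj.to_frame().to_csv(path, index=False, float_format=_fmt_float)


def write_sim_trajectory(traj: SimTrajectory, path) -> None:
    """Write the wide simulation CSV (poles, centromeres, sites, pi states)."""
    traj.to_frame().to_csv(path, index=False, float_format=_fmt_float)


_SIM_CEN = re.compile(r"^cen_(\d+)_([01])$")


def read_sim_trajectory(path) -> pd.DataFrame:
    """Read the wide simulation CSV back as a validated DataFrame."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("t", "x_spbL", "x_spbR"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column(s): {col}")
    if not any(_SIM_CEN.match(c) for c in df.columns):
        raise SchemaError(f"{path}: no centromere columns (cen_<c>_<s>)")
    if np.any(np.diff(df["t"].values) <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return df


def sim_to_tracked_frames(df: pd.DataFrame) -> dict[int, TrackedTrajectory]:
    """Split a wide simulation table into per-chromosome tracked
    trajectories (the analyzer's native input)."""
    chromosomes = sorted(
        {int(m.group(1)) for c in df.columns if (m := _SIM_CEN.match(c))}
    )
    onset = None
    if "anaphase" in df.columns and df["anaphase"].any():
        i = int(np.flatnonzero(df["anaphase"].values)[0])
        onset = float(df["t"].values[max(i - 1, 0)])
    out = {}
    for c in chromosomes:
        out[c] = TrackedTrajectory(
            df["t"].values, df["x_spbL"].values, df["x_spbR"].values,
            df[f"cen_{c}_0"].values, df[f"cen_{c}_1"].values,
            anaphase_onset=onset,
        )
    return out


_PROFILE_REQUIRED = ["profile_id", "position_index", "intensity", "mt_length"]


def read_profiles(path) -> list[IntensityProfile]:
    """Read a long-format profile CSV (profile_id, position_index,
    intensity, mt_length)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PROFILE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for _, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("position_index")
        out.append(
            IntensityProfile(
                values=grp["intensity"].values,
                length=float(grp["mt_length"].iloc[0]),
            )
        )
    return out


def write_profiles(profiles: list[IntensityProfile], path) -> None:
    rows = []
    for k, prof in enumerate(profiles):
        for j, v in enumerate(prof.values):
            rows.append(
                dict(profile_id=k, position_index=j, intensity=v,
                     mt_length=prof.length)
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_fmt_float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one CLI run: the exact configuration,
    seeds, package version, and a checksum for every output file."""

    command: str
    config: dict
    seeds: list[int]
    version: str = ""
    created: str = ""
    files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def add_file(self, path) -> None:
        p = Path(path)
        self.files[p.name] = _sha256(p)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2), encoding="utf-8"
        )

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
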