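"""Lagrangian leeway particle simulation, run backward from collection sites.

Particles carry a leeway class (downwind and crosswind slopes as fractions
of 10-m wind speed, with per-particle draws) and are advected by Euler
steps under current + leeway velocity with no stochastic diffusion.
Backward integration negates the total velocity and steps time backward;
runs terminate when the particle leaves the domain box, comes within the
target hit radius, or exceeds the maximum drift duration.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .envfields import DomainError, EnvStats, GridField, interpolate_field, trajectory_env_stats

EARTH_RADIUS_KM = 6371.0
M_PER_DEG_LAT = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0

REACHED_TARGET = "reached_target"
LEFT_DOMAIN = "left_domain"
TIMED_OUT = "timed_out"

__all__ = [
    "LeewayClass",
    "ParticleState",
    "Trajectory",
    "TargetZone",
    "RaftDriftSummary",
    "haversine_km",
    "seed_particles",
    "leeway_velocity",
    "advect_backward",
    "advect_forward",
    "summarize_raft",
    "match_drifter_window",
    "DEFAULT_LEEWAY_CLASSES",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a spherical Earth (R = 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclasses.dataclass(frozen=True)
class LeewayClass:
    """Leeway drift coefficients, as fractions of 10-m wind speed."""

    name: str
    downwind_slope: float
    downwind_sd: float
    crosswind_slope: float
    crosswind_sd: float

    def __post_init__(self) -> None:
        for f in ("downwind_slope", "downwind_sd", "crosswind_slope", "crosswind_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


# Approximate person-in-water coefficients; the real values are run-time
# configuration — these defaults exist so scenarios work out of the box.
DEFAULT_LEEWAY_CLASSES = (
    LeewayClass("PIW-1", 0.0200, 0.0070, 0.0060, 0.0030),
    LeewayClass("PIW-5", 0.0150, 0.0050, 0.0040, 0.0020),
    LeewayClass("PIW-6", 0.0070, 0.0030, 0.0020, 0.0010),
)


@dataclasses.dataclass
class ParticleState:
    lon: float
    lat: float
    time: float  # days
    crosswind_sign: int
    leeway_class: LeewayClass
    downwind_draw: float
    crosswind_draw: float

    def __post_init__(self) -> None:
        if self.crosswind_sign not in (-1, 1):
            raise ValueError("crosswind_sign must be -1 or +1")
        if self.downwind_draw < 0 or self.crosswind_draw < 0:
            raise ValueError("slope draws must be >= 0")


@dataclasses.dataclass
class Trajectory:
    """Time-ordered particle path; times decrease along backward runs."""

    times: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    status: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if len(self.times) < 1:
            raise ValueError("trajectory needs >= 1 state")
        if self.status not in (REACHED_TARGET, LEFT_DOMAIN, TIMED_OUT):
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def elapsed_days(self) -> float:
        return float(abs(self.times[0] - self.times[-1]))

    def __len__(self) -> int:
        return len(self.times)


@dataclasses.dataclass
class TargetZone:
    """Coastal point set (degrees) with a hit radius for the drift test."""

    lats: np.ndarray
    lons: np.ndarray
    hit_radius_km: float = 2.0

    def __post_init__(self) -> None:
        self.lats = np.atleast_1d(np.asarray(self.lats, dtype=float))
        self.lons = np.atleast_1d(np.asarray(self.lons, dtype=float))
        if len(self.lats) == 0 or len(self.lats) != len(self.lons):
            raise ValueError("target zone needs a non-empty matching point set")
        if self.hit_radius_km <= 0:
            raise ValueError("hit_radius_km must be > 0")

    def contains(self, lat: float, lon: float) -> bool:
        return bool(
            np.min(haversine_km(lat, lon, self.lats, self.lons)) <= self.hit_radius_km
        )


@dataclasses.dataclass
class RaftDriftSummary:
    n_particles: int
    fraction_reached: float
    times_to_source: list
    median_raft_time: float  # NaN when no particle reached
    representative_sst: float
    representative_sigma_sst: float

    @property
    def any_reached(self) -> bool:
        return len(self.times_to_source) > 0


def seed_particles(
    site_lat: float,
    site_lon: float,
    collection_time: float,
    n: int,
    radius_km: float = 1.0,
    time_jitter_days: float = 1.0,
    classes: Sequence[LeewayClass] = DEFAULT_LEEWAY_CLASSES,
    class_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> list[ParticleState]:
    """Seed ``n`` particles area-uniformly on a disc around the site.

    Times are uniform in ±``time_jitter_days`` around the collection time;
    crosswind sign is ±1 with equal probability and per-particle slopes are
    Normal(slope, sd) truncated at zero.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius_km <= 0:
        raise ValueError("radius_km must be > 0")
    rng = np.random.default_rng(seed)
    if class_weights is None:
        class_weights = np.full(len(classes), 1.0 / len(classes))
    class_weights = np.asarray(class_weights, dtype=float)
    class_weights = class_weights / class_weights.sum()

    r = radius_km * np.sqrt(rng.uniform(size=n))  # area-uniform
    theta = rng.uniform(0, 2 * math.pi, size=n)
    dlat = (r * np.cos(theta)) * 1000.0 / M_PER_DEG_LAT
    dlon = (r * np.sin(theta)) * 1000.0 / (M_PER_DEG_LAT * math.cos(math.radians(site_lat)))
    times = collection_time + rng.uniform(-time_jitter_days, time_jitter_days, size=n)
    signs = rng.choice([-1, 1], size=n)
    class_idx = rng.choice(len(classes), size=n, p=class_weights)

    particles = []
    for i in range(n):
        cls = classes[class_idx[i]]
        dw = max(0.0, rng.normal(cls.downwind_slope, cls.downwind_sd))
        cw = max(0.0, rng.normal(cls.crosswind_slope, cls.crosswind_sd))
        particles.append(
            ParticleState(
                lon=site_lon + dlon[i],
                lat=site_lat + dlat[i],
                time=float(times[i]),
                crosswind_sign=int(signs[i]),
                leeway_class=cls,
                downwind_draw=dw,
                crosswind_draw=cw,
            )
        )
    return particles


def leeway_velocity(wind_u: float, wind_v: float, particle: ParticleState) -> tuple[float, float]:
    """Leeway velocity: downwind slope along the wind, crosswind perpendicular."""
    speed = math.hypot(wind_u, wind_v)
    if speed == 0.0:
        return 0.0, 0.0
    ux, uy = wind_u / speed, wind_v / speed
    # perpendicular unit vector = wind rotated +90 degrees
    px, py = -uy, ux
    dw = particle.downwind_draw * speed
    cw = particle.crosswind_sign * particle.crosswind_draw * speed
    return dw * ux + cw * px, dw * uy + cw * py


def _sample_pair(fields: tuple[GridField, GridField], lat, lon, time) -> tuple[float, float]:
    return (
        interpolate_field(fields[0], lat, lon, time),
        interpolate_field(fields[1], lat, lon, time),
    )


def _check_coverage(fields, t_start, t_need):
    lo = min(t_start, t_need)
    hi = max(t_start, t_need)
    for f in fields:
        if f.times[0] > lo or f.times[-1] < hi:
            raise DomainError(
                f"forcing field time axis [{f.times[0]}, {f.times[-1]}] does not "
                f"cover required range [{lo}, {hi}]"
            )


def _advect(
    particle: ParticleState,
    currents: tuple[GridField, GridField],
    winds: tuple[GridField, GridField] | None,
    target: TargetZone | None,
    domain: tuple[float, float, float, float],
    dt_hours: float,
    max_days: float,
    direction: int,
) -> Trajectory:
    if dt_hours <= 0:
        raise ValueError("dt_hours must be > 0")
    lat_min, lat_max, lon_min, lon_max = domain
    lat, lon, t = particle.lat, particle.lon, particle.time
    if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
        raise ValueError("particle outside domain at start")
    t_need = t + direction * max_days
    all_fields = list(currents) + (list(winds) if winds is not None else [])
    _check_coverage(all_fields, t, t_need)

    dt_days = dt_hours / 24.0
    dt_sec = dt_hours * 3600.0
    n_steps = int(round(max_days / dt_days))
    times, lats, lons = [t], [lat], [lon]
    status = TIMED_OUT
    if target is not None and target.contains(lat, lon):
        return Trajectory(times, lats, lons, REACHED_TARGET)

    for _ in range(n_steps):
        cu, cv = _sample_pair(currents, lat, lon, t)
        if winds is not None:
            wu, wv = _sample_pair(winds, lat, lon, t)
            lu, lv = leeway_velocity(wu, wv, particle)
        else:
            lu, lv = 0.0, 0.0
        u = cu + lu
        v = cv + lv
        dlat = direction * v * dt_sec / M_PER_DEG_LAT
        # cos at the step-midpoint latitude: forward and backward steps over
        # the same segment are exact inverses in uniform fields
        lat_mid = lat + 0.5 * dlat
        lon = lon + direction * u * dt_sec / (M_PER_DEG_LAT * math.cos(math.radians(lat_mid)))
        lat = lat + dlat
        t = t + direction * dt_days
        times.append(t)
        lats.append(lat)
        lons.append(lon)
        if not (lat_min <= lat <= lat_max and lon_min <= lon <= lon_max):
            status = LEFT_DOMAIN
            break
        if target is not None and target.contains(lat, lon):
            status = REACHED_TARGET
            break
    return Trajectory(times, lats, lons, status)


def advect_backward(
    particle: ParticleState,
    currents: tuple[GridField, GridField],
    winds: tuple[GridField, GridField] | None,
    target: TargetZone | None,
    domain: tuple[float, float, float, float],
    dt_hours: float = 1.0,
    max_days: float = 730.0,
) -> Trajectory:
    """Euler backward advection until target hit, domain exit, or timeout.

    ``domain`` is (lat_min, lat_max, lon_min, lon_max); velocities are
    current + leeway, negated for backward time; no stochastic diffusion.
    """
    return _advect(particle, currents, winds, target, domain, dt_hours, max_days, -1)


def advect_forward(
    particle: ParticleState,
    currents: tuple[GridField, GridField],
    winds: tuple[GridField, GridField] | None,
    domain: tuple[float, float, float, float],
    dt_hours: float = 1.0,
    max_days: float = 730.0,
    target: TargetZone | None = None,
) -> Trajectory:
    """Forward twin of :func:`advect_backward` (drifter surrogates, reversibility checks)."""
    return _advect(particle, currents, winds, target, domain, dt_hours, max_days, +1)


def summarize_raft(
    trajectories: Sequence[Trajectory],
    sst: GridField | None = None,
    reached_only: bool = True,
) -> RaftDriftSummary:
    """Aggregate an ensemble: reach fraction, median raft time, representative SST.

    Representative SST / σ-SST are medians across per-trajectory means / sds;
    by default only trajectories that reached the target contribute
    (``reached_only=False`` switches to all trajectories).
    """
    if len(trajectories) == 0:
        raise ValueError("need >= 1 trajectory")
    reached = [tr for tr in trajectories if tr.status == REACHED_TARGET]
    frac = len(reached) / len(trajectories)
    times = [tr.elapsed_days for tr in reached]
    median_time = float(np.median(times)) if times else float("nan")

    rep_mean = rep_sigma = float("nan")
    if sst is not None:
        pool = reached if reached_only else list(trajectories)
        means, sigmas = [], []
        for tr in pool:
            try:
                st = trajectory_env_stats(tr, sst)
            except Exception:
                continue
            means.append(st.mean_sst)
            sigmas.append(st.sigma_sst)
        if means:
            rep_mean = float(np.median(means))
            rep_sigma = float(np.median(sigmas))
    return RaftDriftSummary(
        n_particles=len(trajectories),
        fraction_reached=frac,
        times_to_source=times,
        median_raft_time=median_time,
        representative_sst=rep_mean,
        representative_sigma_sst=rep_sigma,
    )


def match_drifter_window(
    drifter_track: Trajectory, sst: GridField, window_days: int = 11
) -> EnvStats:
    """EnvStats over the final ``window_days`` of a forward drifter track."""
    t_end = drifter_track.times[-1]
    t_start = t_end - window_days
    if drifter_track.times[0] > t_start:
        raise ValueError(
            f"track covers {drifter_track.elapsed_days:.2f} days, "
            f"shorter than window of {window_days}"
        )
    keep = drifter_track.times >= t_start - 1e-9
    sub = Trajectory(
        drifter_track.times[keep],
        drifter_track.lats[keep],
        drifter_track.lons[keep],
        drifter_track.status,
    )
    return trajectory_env_stats(sub, sst)
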