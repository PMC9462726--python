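"""Lagrangian larval dispersal over gridded surface currents.

Particles seeded inside habitat polygons are advected by bilinearly
interpolated daily current fields with an isotropic random-walk
approximation of eddy diffusivity:

    dx = u dt + xi,   xi ~ Normal(0, sqrt(2 K dt)) per component,

positions held in geographic coordinates on a sphere of radius 6,371 km.
A particle may settle into a sink polygon only during the settlement
window, between the pelagic larval duration (PLD) and PLD + window days of
age; afterwards it expires.  The run summary is a source x sink
connectivity matrix of settled fractions.

Velocity fields are regular lon/lat grids with daily snapshots, read and
written as plain gridded CSV; analytic synthetic fields (uniform flow,
solid-body rotation, double gyre) stand in for hindcast ocean models in
tests and desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.geometry import Polygon

__all__ = [
    "EARTH_RADIUS_M",
    "VelocityField",
    "DispersalConfig",
    "ParticleState",
    "make_synthetic_field",
    "read_polygons_geojson",
    "seed_particles",
    "interpolate_velocity",
    "advect_diffuse_step",
    "settle",
    "run_dispersal",
    "DispersalRun",
]

EARTH_RADIUS_M = 6_371_000.0
DEG2M = EARTH_RADIUS_M * np.pi / 180.0  # metres per degree latitude

ACTIVE, SETTLED, BEACHED, EXPIRED = 0, 1, 2, 3
STATUS_NAMES = {ACTIVE: "active", SETTLED: "settled", BEACHED: "beached", EXPIRED: "expired"}


# ---------------------------------------------------------------------------
# Velocity fields
# ---------------------------------------------------------------------------

@dataclass
class VelocityField:
    """Daily surface-current snapshots on a regular lon/lat grid.

    ``u``/``v`` are eastward/northward velocities (m/s) of shape
    ``(n_days, n_lat, n_lon)``; ``land`` marks cells with undefined
    velocity (treated as zero-velocity nodes in interpolation).
    """

    lon: np.ndarray
    lat: np.ndarray
    time_days: np.ndarray
    u: np.ndarray
    v: np.ndarray
    land: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time_days = np.asarray(self.time_days, dtype=float)
        for name in ("lon", "lat", "time_days"):
            a = getattr(self, name)
            if a.ndim != 1 or (np.diff(a) <= 0).any():
                raise ValueError(f"{name} axis must be strictly increasing 1-D")
        expect = (self.time_days.size, self.lat.size, self.lon.size)
        for name in ("u", "v"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != expect:
                raise ValueError(f"{name} must have shape {expect}, got {a.shape}")
            setattr(self, name, a)
        if self.land is None:
            self.land = np.zeros((self.lat.size, self.lon.size), dtype=bool)
        else:
            self.land = np.asarray(self.land, dtype=bool)
        water = ~self.land
        if not (np.isfinite(self.u[:, water]).all() and np.isfinite(self.v[:, water]).all()):
            raise ValueError("non-finite velocity on water cells")

    @property
    def n_days(self) -> float:
        return float(self.time_days[-1])

    def in_domain(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def is_land(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Land lookup by nearest grid cell; out-of-domain counts as land."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        inside = self.in_domain(lon, lat)
        i = np.clip(np.searchsorted(self.lat, lat) - 1, 0, self.lat.size - 2)
        j = np.clip(np.searchsorted(self.lon, lon) - 1, 0, self.lon.size - 2)
        # nearest of the four surrounding nodes
        i_near = np.where(lat - self.lat[i] > self.lat[i + 1] - lat, i + 1, i)
        j_near = np.where(lon - self.lon[j] > self.lon[j + 1] - lon, j + 1, j)
        out = np.where(inside, self.land[i_near, j_near], True)
        return out

    # -- plain-text I/O -------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Long-format CSV: day, lat, lon, u, v, land."""
        T, Y, X = np.meshgrid(self.time_days, self.lat, self.lon, indexing="ij")
        land3 = np.broadcast_to(self.land, self.u.shape)
        pd.DataFrame({
            "day": T.ravel(), "lat": Y.ravel(), "lon": X.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(), "land": land3.ravel().astype(int),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VelocityField":
        t = pd.read_csv(path)
        days = np.unique(t["day"])
        lats = np.unique(t["lat"])
        lons = np.unique(t["lon"])
        t = t.sort_values(["day", "lat", "lon"])
        shp = (days.size, lats.size, lons.size)
        u = t["u"].to_numpy().reshape(shp)
        v = t["v"].to_numpy().reshape(shp)
        land = t["land"].to_numpy().reshape(shp)[0].astype(bool) if "land" in t else None
        return cls(lons, lats, days, u, v, land)


def make_synthetic_field(
    kind: str,
    lon: np.ndarray | None = None,
    lat: np.ndarray | None = None,
    days: int = 31,
    **params,
) -> VelocityField:
    """Analytic velocity fields sampled onto a grid.

    kinds: ``zero``; ``uniform`` (params u0, v0 in m/s); ``rotation``
    (omega in rad/s about center=(lon0, lat0), planar small-domain
    approximation); ``double_gyre`` (amplitude A m/s over the grid box,
    divergence-free).
    """
    lon = np.asarray(lon if lon is not None else np.linspace(-1.0, 1.0, 25), dtype=float)
    lat = np.asarray(lat if lat is not None else np.linspace(-1.0, 1.0, 25), dtype=float)
    time_days = np.arange(days + 1, dtype=float)
    Y, X = np.meshgrid(lat, lon, indexing="ij")
    if kind == "zero":
        u2 = np.zeros_like(X)
        v2 = np.zeros_like(X)
    elif kind == "uniform":
        u2 = np.full_like(X, float(params.get("u0", 0.1)))
        v2 = np.full_like(X, float(params.get("v0", 0.0)))
    elif kind == "rotation":
        omega = float(params.get("omega", 1e-5))
        lon0, lat0 = params.get("center", (float(lon.mean()), float(lat.mean())))
        xm = (X - lon0) * DEG2M
        ym = (Y - lat0) * DEG2M
        u2 = -omega * ym
        v2 = omega * xm
    elif kind == "double_gyre":
        A = float(params.get("amplitude", 0.1))
        # stream function psi = A sin(pi x') sin(pi y') on the unit box
        xs = (X - lon[0]) / (lon[-1] - lon[0]) * 2.0
        ys = (Y - lat[0]) / (lat[-1] - lat[0])
        Lx = (lon[-1] - lon[0]) * DEG2M / 2.0
        Ly = (lat[-1] - lat[0]) * DEG2M
        u2 = -A * np.pi * np.sin(np.pi * xs) * np.cos(np.pi * ys) * (Lx / Ly)
        v2 = A * np.pi * np.cos(np.pi * xs) * np.sin(np.pi * ys)
    else:
        raise ValueError(f"unknown synthetic field kind {kind!r}")
    u = np.broadcast_to(u2, (time_days.size, *u2.shape)).copy()
    v = np.broadcast_to(v2, (time_days.size, *v2.shape)).copy()
    return VelocityField(lon, lat, time_days, u, v)


# ---------------------------------------------------------------------------
# Habitat polygons
# ---------------------------------------------------------------------------

def read_polygons_geojson(path: str | Path) -> dict[str, Polygon]:
    """Named simple polygons from a GeoJSON FeatureCollection.

    Feature names come from the ``name`` property (or ``id``).  Polygons
    must be valid and simple; names must be unique.  Declaration order is
    preserved (it is the settlement tie-break order).
    """
    data = json.loads(Path(path).read_text())
    out: dict[str, Polygon] = {}
    for k, feat in enumerate(data.get("features", [])):
        geom = shapely_shape(feat["geometry"])
        name = feat.get("properties", {}).get("name") or feat.get("id") or f"poly{k}"
        if not isinstance(geom, Polygon):
            raise ValueError(f"feature {name!r} is not a Polygon")
        if not geom.is_valid:
            raise ValueError(f"polygon {name!r} is invalid (self-intersecting?)")
        if name in out:
            raise ValueError(f"duplicate polygon name {name!r}")
        out[name] = geom
    if not out:
        raise ValueError("no polygon features found")
    return out


def write_polygons_geojson(polygons: dict[str, Polygon], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"name": name},
            "geometry": json.loads(shapely.to_geojson(poly)),
        }
        for name, poly in polygons.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------------------
# Particle state
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """Struct-of-arrays particle ensemble."""

    lon: np.ndarray
    lat: np.ndarray
    age_days: np.ndarray
    source: np.ndarray        # index into source-polygon order
    status: np.ndarray        # ACTIVE / SETTLED / BEACHED / EXPIRED
    sink: np.ndarray          # index of settlement polygon, -1 if none
    refusals: np.ndarray      # consecutive refused (land) steps

    @classmethod
    def empty(cls) -> "ParticleState":
        z = np.empty(0)
        zi = np.empty(0, dtype=int)
        return cls(z.copy(), z.copy(), z.copy(), zi.copy(), zi.copy(), zi.copy(), zi.copy())

    @property
    def n(self) -> int:
        return self.lon.size

    def extend(self, other: "ParticleState") -> "ParticleState":
        return ParticleState(*[
            np.concatenate([getattr(self, f), getattr(other, f)])
            for f in ("lon", "lat", "age_days", "source", "status", "sink", "refusals")
        ])

    def status_counts(self) -> dict[str, int]:
        return {name: int((self.status == code).sum()) for code, name in STATUS_NAMES.items()}


def seed_particles(
    polygons: dict[str, Polygon],
    n: int,
    rng: np.random.Generator,
    weighting: str = "area",
) -> ParticleState:
    """Uniform random points inside each polygon by rejection sampling.

    ``n`` particles are split across polygons proportionally to area
    (``weighting="area"``) or equally (``"equal"``); remainders go to the
    first polygons in declaration order.
    """
    names = list(polygons)
    areas = np.array([polygons[k].area for k in names])
    if (areas <= 0).any():
        bad = names[int(np.argmin(areas))]
        raise ValueError(f"polygon {bad!r} has zero area")
    if weighting == "area":
        w = areas / areas.sum()
    elif weighting == "equal":
        w = np.full(len(names), 1.0 / len(names))
    else:
        raise ValueError("weighting must be 'area' or 'equal'")
    counts = np.floor(w * n).astype(int)
    for k in range(n - counts.sum()):
        counts[k % len(names)] += 1
    lons, lats, src = [], [], []
    for k, name in enumerate(names):
        m = counts[k]
        if m == 0:
            continue
        poly = polygons[name]
        minx, miny, maxx, maxy = poly.bounds
        got = 0
        while got < m:
            batch = max(2 * (m - got), 64)
            xs = rng.uniform(minx, maxx, batch)
            ys = rng.uniform(miny, maxy, batch)
            inside = shapely.contains_xy(poly, xs, ys)
            xs, ys = xs[inside][: m - got], ys[inside][: m - got]
            lons.append(xs), lats.append(ys), src.append(np.full(xs.size, k))
            got += xs.size
    if not lons:
        return ParticleState.empty()
    lon = np.concatenate(lons)
    lat = np.concatenate(lats)
    source = np.concatenate(src)
    npart = lon.size
    return ParticleState(
        lon, lat, np.zeros(npart), source,
        np.full(npart, ACTIVE), np.full(npart, -1), np.zeros(npart, dtype=int),
    )


# ---------------------------------------------------------------------------
# Interpolation and stepping
# ---------------------------------------------------------------------------

def interpolate_velocity(
    field: VelocityField, lon: np.ndarray, lat: np.ndarray, t_days: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bilinear-in-space, linear-in-time velocity at particle positions.

    Land nodes contribute zero velocity without weight renormalisation.
    Returns ``(u, v, in_domain)``; out-of-domain positions get zero
    velocity and ``in_domain=False``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    inside = field.in_domain(lon, lat)
    t = np.clip(t_days, field.time_days[0], field.time_days[-1])
    kt = int(np.clip(np.searchsorted(field.time_days, t) - 1, 0, field.time_days.size - 2))
    ft = (t - field.time_days[kt]) / (field.time_days[kt + 1] - field.time_days[kt])
    u_t = (1 - ft) * field.u[kt] + ft * field.u[kt + 1]
    v_t = (1 - ft) * field.v[kt] + ft * field.v[kt + 1]
    water = np.where(field.land, 0.0, 1.0)
    u_t = u_t * water
    v_t = v_t * water

    i = np.clip(np.searchsorted(field.lat, lat) - 1, 0, field.lat.size - 2)
    j = np.clip(np.searchsorted(field.lon, lon) - 1, 0, field.lon.size - 2)
    fy = np.clip((lat - field.lat[i]) / (field.lat[i + 1] - field.lat[i]), 0, 1)
    fx = np.clip((lon - field.lon[j]) / (field.lon[j + 1] - field.lon[j]), 0, 1)
    w00 = (1 - fy) * (1 - fx)
    w01 = (1 - fy) * fx
    w10 = fy * (1 - fx)
    w11 = fy * fx
    u = w00 * u_t[i, j] + w01 * u_t[i, j + 1] + w10 * u_t[i + 1, j] + w11 * u_t[i + 1, j + 1]
    v = w00 * v_t[i, j] + w01 * v_t[i, j + 1] + w10 * v_t[i + 1, j] + w11 * v_t[i + 1, j + 1]
    u = np.where(inside, u, 0.0)
    v = np.where(inside, v, 0.0)
    return u, v, inside


def advect_diffuse_step(
    state: ParticleState,
    field: VelocityField,
    t_days: float,
    dt_seconds: float,
    K: float,
    rng: np.random.Generator,
    land_policy: str = "beach",
    refusal_limit: int = 3,
    advance_age: bool = True,
) -> ParticleState:
    """One explicit-Euler advection-diffusion step for active particles.

    Displacements (m): u dt + Normal(0, sqrt(2 K dt)) per component,
    converted to degrees with the spherical metric (lon scaled by
    1/cos(lat)).  A step that would land in a land cell (or leave the
    domain) is refused; after ``refusal_limit`` consecutive refusals the
    particle is flagged beached (``land_policy="beach"``) or simply held in
    place (``"hold"``).
    """
    if dt_seconds <= 0:
        raise ValueError("dt must be positive")
    act = state.status == ACTIVE
    if act.any():
        lon0, lat0 = state.lon[act], state.lat[act]
        u, v, _ = interpolate_velocity(field, lon0, lat0, t_days)
        sd = np.sqrt(2.0 * K * dt_seconds)
        xi_u = rng.normal(0.0, sd, u.size) if K > 0 else 0.0
        xi_v = rng.normal(0.0, sd, v.size) if K > 0 else 0.0
        dlon = (u * dt_seconds + xi_u) / (EARTH_RADIUS_M * np.cos(np.radians(lat0))) * (180.0 / np.pi)
        dlat = (v * dt_seconds + xi_v) / EARTH_RADIUS_M * (180.0 / np.pi)
        new_lon = lon0 + dlon
        new_lat = lat0 + dlat
        blocked = field.is_land(new_lon, new_lat)
        ok = ~blocked
        idx = np.flatnonzero(act)
        state.lon[idx[ok]] = new_lon[ok]
        state.lat[idx[ok]] = new_lat[ok]
        state.refusals[idx[ok]] = 0
        state.refusals[idx[blocked]] += 1
        if land_policy == "beach":
            dead = state.refusals[idx] >= refusal_limit
            state.status[idx[dead]] = BEACHED
        elif land_policy != "hold":
            raise ValueError("land_policy must be 'beach' or 'hold'")
    if advance_age:
        moving = state.status == ACTIVE
        state.age_days[moving] += dt_seconds / 86_400.0
    return state


def settle(
    state: ParticleState,
    sink_polygons: dict[str, Polygon],
    pld_days: float,
    window_days: float,
) -> ParticleState:
    """Settle active particles inside a sink polygon during the window.

    Eligible when pld <= age <= pld + window; the first polygon in
    declaration order containing the particle wins.  Particles older than
    the window expire.
    """
    tol = 1e-9
    eligible = (state.status == ACTIVE) & (state.age_days >= pld_days - tol) \
        & (state.age_days <= pld_days + window_days + tol)
    if eligible.any():
        idx = np.flatnonzero(eligible)
        remaining = np.ones(idx.size, dtype=bool)
        for k, poly in enumerate(sink_polygons.values()):
            if not remaining.any():
                break
            sel = idx[remaining]
            hit = shapely.contains_xy(poly, state.lon[sel], state.lat[sel])
            hit_idx = sel[hit]
            state.status[hit_idx] = SETTLED
            state.sink[hit_idx] = k
            remaining[np.isin(idx, hit_idx)] = False
    over = (state.status == ACTIVE) & (state.age_days > pld_days + window_days + tol)
    state.status[over] = EXPIRED
    return state


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

@dataclass
class DispersalConfig:
    """Run parameters; defaults follow sandfish biology at full scale.

    duration must cover pld + settlement window; particle counts are
    configurable for desk-scale runs.
    """

    duration_days: int = 30
    pld_days: float = 25.0
    settlement_window_days: float = 5.0
    particles_per_day: int = 256_000
    seeding_days: int = 3
    substeps_per_day: int = 24
    eddy_diffusivity: float = 5.0  # m^2/s, horizontal; free parameter
    seed: int = 0
    seeding_weighting: str = "area"
    land_policy: str = "beach"
    log_every_days: int = 1

    def __post_init__(self) -> None:
        if self.duration_days < self.pld_days + self.settlement_window_days:
            raise ValueError("duration must cover pld + settlement window")
        for f in ("particles_per_day", "seeding_days", "substeps_per_day"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.eddy_diffusivity < 0:
            raise ValueError("eddy diffusivity must be non-negative")


@dataclass
class DispersalRun:
    particles: ParticleState
    trajectories: pd.DataFrame
    connectivity: pd.DataFrame
    source_names: list[str]
    sink_names: list[str]


def run_dispersal(
    field: VelocityField,
    polygons: dict[str, Polygon],
    config: DispersalConfig,
    sink_polygons: dict[str, Polygon] | None = None,
) -> DispersalRun:
    """Run the full seeding/advection/settlement schedule.

    ``polygons`` are the sources (and by default also the sinks).  The
    connectivity row of source i holds the fraction of its particles that
    settled in each sink, plus unsettled (active at end), beached and
    expired fractions; each row sums to 1.
    """
    if field.n_days < config.duration_days:
        raise ValueError("velocity field does not cover the run duration")
    sinks = sink_polygons if sink_polygons is not None else polygons
    rng = np.random.default_rng(config.seed)
    state = ParticleState.empty()
    dt = 86_400.0 / config.substeps_per_day
    logs = []
    total_seeded = 0
    for day in range(config.duration_days):
        if day < config.seeding_days:
            batch = seed_particles(polygons, config.particles_per_day, rng,
                                   weighting=config.seeding_weighting)
            total_seeded += batch.n
            state = state.extend(batch)
        for s in range(config.substeps_per_day):
            t = day + s / config.substeps_per_day
            state = advect_diffuse_step(
                state, field, t, dt, config.eddy_diffusivity, rng,
                land_policy=config.land_policy, advance_age=True,
            )
        state = settle(state, sinks, config.pld_days, config.settlement_window_days)
        counts = state.status_counts()
        if sum(counts.values()) != total_seeded:
            raise RuntimeError("particle bookkeeping lost particles")
        if (day + 1) % config.log_every_days == 0 or day == config.duration_days - 1:
            logs.append(pd.DataFrame({
                "particle": np.arange(state.n),
                "day": day + 1,
                "lon": state.lon.copy(),
                "lat": state.lat.copy(),
                "status": [STATUS_NAMES[s] for s in state.status],
            }))
    source_names = list(polygons)
    sink_names = list(sinks)
    rows = []
    for i, src in enumerate(source_names):
        mine = state.source == i
        n_src = int(mine.sum())
        row = {}
        for k, snk in enumerate(sink_names):
            row[snk] = float(((state.sink == k) & mine).sum() / n_src) if n_src else 0.0
        for code, name in ((ACTIVE, "unsettled"), (BEACHED, "beached"), (EXPIRED, "expired")):
            row[name] = float(((state.status == code) & mine).sum() / n_src) if n_src else 0.0
        rows.append(row)
    conn = pd.DataFrame(rows, index=source_names)
    traj = pd.concat(logs, ignore_index=True) if logs else pd.DataFrame(
        columns=["particle", "day", "lon", "lat", "status"])
    return DispersalRun(state, traj, conn, source_names, sink_names)
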