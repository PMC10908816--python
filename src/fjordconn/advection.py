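"""Lagrangian drifter advection on a gridded 2-D velocity field.

Drifters stand in for passively transported picoplankton: cohorts are seeded
around each sampling site at a fixed interval, advected by the daily-mean
velocity field with a 4th-order Runge–Kutta integrator, and tracked until
they beach, leave the domain, or reach their lifetime.  Positions are stored
at daily resolution; connectivity statistics are computed downstream from
these snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .config import SeedingSchedule

STATUS_ACTIVE = 0
STATUS_BEACHED = 1
STATUS_OUT = 2


class AdvectionError(RuntimeError):
    pass


class SeedingError(AdvectionError):
    pass


class OutOfDomainError(AdvectionError):
    pass


@dataclass
class VelocityField:
    """Gridded 2-D time-varying flow with a land mask.

    ``u``/``v`` are km day⁻¹ on (time, y, x); ``mask`` is True on ocean
    cells.  Time is in days; velocities are piecewise-constant per day
    (daily means).
    """

    x: np.ndarray          # (nx,) cell-centre x, km
    y: np.ndarray          # (ny,) cell-centre y, km
    time: np.ndarray       # (nt,) days
    u: np.ndarray          # (nt, ny, nx) km/day
    v: np.ndarray          # (nt, ny, nx) km/day
    mask: np.ndarray       # (ny, nx) bool, True = ocean

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        nt, ny, nx = len(self.time), len(self.y), len(self.x)
        if self.u.shape != (nt, ny, nx) or self.v.shape != (nt, ny, nx):
            raise ValueError("u/v shapes inconsistent with coordinates")
        if self.mask.shape != (ny, nx):
            raise ValueError("mask shape inconsistent with coordinates")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        ocean = self.mask[None, :, :]
        if not (np.isfinite(self.u[np.broadcast_to(ocean, self.u.shape)]).all()
                and np.isfinite(self.v[np.broadcast_to(ocean, self.v.shape)]).all()):
            raise ValueError("non-finite velocity on ocean cells")
        self._dx = float(self.x[1] - self.x[0]) if nx > 1 else 1.0
        self._dy = float(self.y[1] - self.y[0]) if ny > 1 else 1.0
        # land velocities are treated as zero when interpolating
        m = self.mask.astype(float)
        self._u0 = np.nan_to_num(self.u) * m
        self._v0 = np.nan_to_num(self.v) * m

    # -- geometry ---------------------------------------------------------
    @property
    def dx(self) -> float:
        return self._dx

    @property
    def dy(self) -> float:
        return self._dy

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the domain, cell edges included."""
        return (self.x[0] - self._dx / 2, self.x[-1] + self._dx / 2,
                self.y[0] - self._dy / 2, self.y[-1] + self._dy / 2)

    def cell_index(self, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid (iy, ix) of the cell containing each position (n, 2)."""
        pos = np.atleast_2d(pos)
        ix = np.clip(np.round((pos[:, 0] - self.x[0]) / self._dx).astype(int),
                     0, len(self.x) - 1)
        iy = np.clip(np.round((pos[:, 1] - self.y[0]) / self._dy).astype(int),
                     0, len(self.y) - 1)
        return iy, ix

    def in_domain(self, pos: np.ndarray) -> np.ndarray:
        pos = np.atleast_2d(pos)
        xmin, xmax, ymin, ymax = self.bounds
        return ((pos[:, 0] >= xmin) & (pos[:, 0] <= xmax)
                & (pos[:, 1] >= ymin) & (pos[:, 1] <= ymax))

    def on_ocean(self, pos: np.ndarray) -> np.ndarray:
        iy, ix = self.cell_index(pos)
        return self.mask[iy, ix]

    # -- IO ----------------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"u": (("time", "y", "x"), self.u),
             "v": (("time", "y", "x"), self.v),
             "mask": (("y", "x"), self.mask.astype(np.int8))},
            coords={"time": self.time, "y": self.y, "x": self.x},
            attrs={"units_uv": "km day-1", "units_xy": "km",
                   "units_time": "days"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "VelocityField":
        return cls(x=ds["x"].values, y=ds["y"].values, time=ds["time"].values,
                   u=ds["u"].values, v=ds["v"].values,
                   mask=ds["mask"].values.astype(bool))

    def save(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def load(cls, path: str | Path) -> "VelocityField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


def interpolate_velocity(field: VelocityField, positions: np.ndarray,
                         t: float) -> np.ndarray:
    """Velocity at positions (n, 2) and time t.

    Bilinear in space between cell centres (land cells contribute zero
    velocity), piecewise-constant (daily mean) in time.  Raises
    :class:`OutOfDomainError` if any position lies outside the domain box.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    inside = field.in_domain(positions)
    if not inside.all():
        bad = positions[~inside][0]
        raise OutOfDomainError(f"position {tuple(bad)} outside domain")
    it = int(np.clip(np.searchsorted(field.time, t, side="right") - 1,
                     0, len(field.time) - 1))
    u2, v2 = field._u0[it], field._v0[it]

    nx, ny = len(field.x), len(field.y)
    fx = (positions[:, 0] - field.x[0]) / field.dx
    fy = (positions[:, 1] - field.y[0]) / field.dy
    ix = np.clip(np.floor(fx).astype(int), 0, max(nx - 2, 0))
    iy = np.clip(np.floor(fy).astype(int), 0, max(ny - 2, 0))
    wx = np.clip(fx - ix, 0.0, 1.0)
    wy = np.clip(fy - iy, 0.0, 1.0)
    ix1 = np.minimum(ix + 1, nx - 1)
    iy1 = np.minimum(iy + 1, ny - 1)

    out = np.empty_like(positions)
    for k, comp in enumerate((u2, v2)):
        c00 = comp[iy, ix]
        c01 = comp[iy, ix1]
        c10 = comp[iy1, ix]
        c11 = comp[iy1, ix1]
        out[:, k] = ((1 - wy) * ((1 - wx) * c00 + wx * c01)
                     + wy * ((1 - wx) * c10 + wx * c11))
    return out


@dataclass
class TrajectorySet:
    """Stored drifter trajectories for one release site and cohort.

    ``positions`` has shape (n_drifters, n_stored, 2); ``status`` the same
    leading shape with codes 0=active, 1=beached, 2=out-of-domain.  Beached
    and out-of-domain drifters keep their last position (frozen).
    """

    release_site: str
    release_time: float
    times: np.ndarray              # (n_stored,) absolute days
    positions: np.ndarray          # (n_drifters, n_stored, 2) km
    status: np.ndarray             # (n_drifters, n_stored) int8

    @property
    def ages(self) -> np.ndarray:
        return self.times - self.release_time

    @property
    def n_drifters(self) -> int:
        return self.positions.shape[0]

    def counts(self) -> dict[str, np.ndarray]:
        """Per-snapshot counts by status (drifter conservation bookkeeping)."""
        return {
            "active": (self.status == STATUS_ACTIVE).sum(axis=0),
            "beached": (self.status == STATUS_BEACHED).sum(axis=0),
            "out": (self.status == STATUS_OUT).sum(axis=0),
        }


def seed_cohorts(site_pos: tuple[float, float], field: VelocityField,
                 schedule: SeedingSchedule, rng: np.random.Generator,
                 ) -> list[tuple[float, np.ndarray]]:
    """Initial drifter positions for every cohort of a release site.

    Positions are drawn uniformly over the ocean portion of a
    ``seeding_window`` × ``seeding_window`` cell square centred on the site's
    grid cell; land cells in the window receive no drifters.

    Returns a list of (release_time, positions (floats_per_cohort, 2)).
    """
    iy0, ix0 = field.cell_index(np.array([site_pos]))
    iy0, ix0 = int(iy0[0]), int(ix0[0])
    if not field.mask[iy0, ix0]:
        raise SeedingError(f"site at {site_pos} lies on a land cell")
    half = schedule.seeding_window // 2
    cells = []
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            iy, ix = iy0 + dy, ix0 + dx
            if (0 <= iy < len(field.y) and 0 <= ix < len(field.x)
                    and field.mask[iy, ix]):
                cells.append((iy, ix))
    if not cells:
        raise SeedingError("seeding window entirely on land")
    cells = np.array(cells)
    out = []
    for t0 in schedule.release_times:
        pick = rng.integers(0, len(cells), size=schedule.floats_per_cohort)
        cy, cx = cells[pick, 0], cells[pick, 1]
        px = field.x[cx] + (rng.random(len(cx)) - 0.5) * field.dx
        py = field.y[cy] + (rng.random(len(cy)) - 0.5) * field.dy
        out.append((float(t0), np.column_stack([px, py])))
    return out


def advect(initial: np.ndarray, field: VelocityField, release_time: float,
           lifetime: float, dt: float = 0.25, release_site: str = "",
           store_interval: float = 1.0) -> TrajectorySet:
    """Advect drifters with RK4 through the gridded field.

    Drifters entering a land cell are flagged beached and frozen there;
    drifters crossing the domain boundary are flagged out-of-domain and
    frozen at their last in-domain position.  Positions are stored at
    ``store_interval`` (default daily) up to ``lifetime`` days after release.
    """
    if dt > 1.0 + 1e-12:
        raise ValueError("dt must be <= 1 day (daily-mean fields)")
    steps_per_store = store_interval / dt
    if abs(steps_per_store - round(steps_per_store)) > 1e-9:
        raise ValueError("dt must divide the storage interval")
    steps_per_store = int(round(steps_per_store))

    pos = np.atleast_2d(np.asarray(initial, dtype=float)).copy()
    n = pos.shape[0]
    n_stored = int(np.floor(lifetime / store_interval + 1e-9)) + 1
    times = release_time + np.arange(n_stored) * store_interval
    positions = np.empty((n, n_stored, 2))
    status = np.zeros((n, n_stored), dtype=np.int8)

    state = np.zeros(n, dtype=np.int8)
    state[~field.in_domain(pos)] = STATUS_OUT
    beach_now = (state == STATUS_ACTIVE) & ~field.on_ocean(pos)
    state[beach_now] = STATUS_BEACHED

    positions[:, 0] = pos
    status[:, 0] = state

    def vel(p: np.ndarray, t: float) -> np.ndarray:
        if np.any(~np.isfinite(p)):
            raise AdvectionError(f"non-finite position at t={t}")
        out = interpolate_velocity(field, p, t)
        if np.any(~np.isfinite(out)):
            iy, ix = field.cell_index(p[~np.isfinite(out).all(axis=1)][:1])
            raise AdvectionError(
                f"NaN velocity at cell (iy={iy[0]}, ix={ix[0]}), t={t}")
        return out

    t = release_time
    for istore in range(1, n_stored):
        for _ in range(steps_per_store):
            act = state == STATUS_ACTIVE
            if act.any():
                p = pos[act]
                k1 = vel(p, t)
                k2 = _vel_clipped(field, p + 0.5 * dt * k1, t + 0.5 * dt)
                k3 = _vel_clipped(field, p + 0.5 * dt * k2, t + 0.5 * dt)
                k4 = _vel_clipped(field, p + dt * k3, t + dt)
                newp = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                inside = field.in_domain(newp)
                sub = state[act].copy()
                # drifters crossing the boundary freeze at the last position
                sub[~inside] = STATUS_OUT
                keep = pos[act]
                keep[inside] = newp[inside]
                beached = inside & ~field.on_ocean(newp)
                sub[beached] = STATUS_BEACHED
                pos[act] = keep
                state[act] = sub
            t += dt
        positions[:, istore] = pos
        status[:, istore] = state
    return TrajectorySet(release_site=release_site, release_time=release_time,
                         times=times, positions=positions, status=status)


def _vel_clipped(field: VelocityField, p: np.ndarray, t: float) -> np.ndarray:
    """Velocity with intermediate RK4 stage positions clipped to the domain.

    Only internal stage evaluations are clipped; boundary crossing is decided
    on the full step.
    """
    xmin, xmax, ymin, ymax = field.bounds
    q = p.copy()
    q[:, 0] = np.clip(q[:, 0], xmin, xmax)
    q[:, 1] = np.clip(q[:, 1], ymin, ymax)
    return interpolate_velocity(field, q, t)


def run_site(site_id: str, site_pos: tuple[float, float],
             field: VelocityField, schedule: SeedingSchedule,
             rng: np.random.Generator, dt: float = 0.25,
             ) -> list[TrajectorySet]:
    """Seed and advect all cohorts for one release site."""
    cohorts = seed_cohorts(site_pos, field, schedule, rng)
    out = []
    for t0, init in cohorts:
        out.append(advect(init, field, release_time=t0,
                          lifetime=schedule.lifetime, dt=dt,
                          release_site=site_id))
    return out
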