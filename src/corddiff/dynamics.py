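"""Monte Carlo random walk of spins among impermeable parallel cylinders.

Walkers take fixed-length, uniformly-oriented in-plane steps of length
``l = sqrt(4 * D0 * dt)`` (the 2-D Brownian step for the compartment's
intrinsic diffusivity ``D0``).  Membranes are impermeable: a step crossing a
cylinder wall is specularly reflected about the tangent at the crossing
point, possibly several times within one step.  Intra-axonal walkers are
confined to their inner circle; extra-axonal walkers move in the periodic
box, reflecting off the outer circles, with displacements unwrapped so the
perpendicular statistics Δx(t), Δy(t) accumulate across box crossings.

Myelin is treated as MR-invisible: no walkers are seeded there and both of
its faces reflect.  Only perpendicular (x, y) dynamics are simulated — the
parallel component decouples for straight parallel cylinders and carries no
restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from numba import njit

from .substrate import Substrate, locate_compartment

__all__ = [
    "WalkerEnsemble",
    "DisplacementSeries",
    "seed_walkers",
    "run_dynamics",
    "reflect_step",
    "default_sample_times",
]


@dataclass
class WalkerEnsemble:
    """Initial walker positions with compartment assignment.

    ``cyl_index`` holds, for intra-axonal walkers, the index of the cylinder
    each walker lives in (-1 for extra-axonal walkers).
    """

    positions: np.ndarray  # (n, 2) μm
    compartment: np.ndarray  # (n,) 'intra' | 'extra'
    cyl_index: np.ndarray  # (n,) int
    seed: int | None = None


@dataclass
class DisplacementSeries:
    """Per-walker perpendicular displacements at the sample times.

    ``dx``/``dy`` are (n_walkers, n_times), unwrapped (not reduced modulo
    the box), with dx = dy = 0 at t = 0 if 0 is sampled.
    """

    times: np.ndarray  # (n_t,) ms, ascending
    dx: np.ndarray
    dy: np.ndarray
    compartment: str
    seed: int | None = None
    n_rejected: int = 0  # reflection-cap fallbacks (diagnostic)

    def save_hdf5(self, path, mode="w", group="/") -> None:
        with h5py.File(path, mode) as fh:
            g = fh.require_group(group)
            g.create_dataset("times", data=self.times)
            g.create_dataset("dx", data=self.dx)
            g.create_dataset("dy", data=self.dy)
            g.attrs["compartment"] = self.compartment
            g.attrs["seed"] = -1 if self.seed is None else self.seed
            g.attrs["n_rejected"] = self.n_rejected

    @classmethod
    def load_hdf5(cls, path, group="/") -> "DisplacementSeries":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            seed = int(g.attrs["seed"])
            return cls(
                times=g["times"][()],
                dx=g["dx"][()],
                dy=g["dy"][()],
                compartment=str(g.attrs["compartment"]),
                seed=None if seed < 0 else seed,
                n_rejected=int(g.attrs.get("n_rejected", 0)),
            )


def default_sample_times(duration: float = 75.0, n: int = 60) -> np.ndarray:
    """Log-spaced sample-time grid in (0, duration] ms."""
    return np.geomspace(duration / 10**2.5, duration, n)


# ---------------------------------------------------------------------------
# seeding


def seed_walkers(
    substrate: Substrate,
    n_intra: int,
    n_extra: int,
    rng: np.random.Generator,
) -> WalkerEnsemble:
    """Seed walkers uniformly over their compartment.

    Intra-axonal walkers are distributed across cylinders with probability
    proportional to inner-circle area, then uniformly within the disk.
    Extra-axonal walkers are drawn by rejection sampling over the box.
    """
    pos = []
    comp = []
    cyl = []
    if n_intra > 0:
        if substrate.n_cylinders == 0:
            raise ValueError("cannot seed intra-axonal walkers: no cylinders")
        areas = substrate.r_in**2
        probs = areas / areas.sum()
        idx = rng.choice(substrate.n_cylinders, size=n_intra, p=probs)
        u = rng.random(n_intra)
        r = substrate.r_in[idx] * np.sqrt(u)
        phi = rng.uniform(0, 2 * np.pi, n_intra)
        p = substrate.centers[idx] + np.c_[r * np.cos(phi), r * np.sin(phi)]
        pos.append(p)
        comp.append(np.full(n_intra, "intra", dtype=object))
        cyl.append(idx.astype(np.int64))
    if n_extra > 0:
        extra_frac = 1.0 - substrate.fvf
        if extra_frac <= 1e-6:
            raise ValueError("cannot seed extra-axonal walkers: no extra space")
        got = []
        n_need = n_extra
        while n_need > 0:
            n_try = int(np.ceil(n_need / max(extra_frac, 0.05))) + 16
            cand = rng.uniform(0, substrate.L, size=(n_try, 2))
            ok = locate_compartment(cand, substrate) == "extra"
            got.append(cand[ok][:n_need])
            n_need -= len(got[-1])
        pos.append(np.concatenate(got))
        comp.append(np.full(n_extra, "extra", dtype=object))
        cyl.append(np.full(n_extra, -1, dtype=np.int64))
    return WalkerEnsemble(
        positions=np.concatenate(pos) if pos else np.empty((0, 2)),
        compartment=np.concatenate(comp) if comp else np.empty(0, dtype=object),
        cyl_index=np.concatenate(cyl) if cyl else np.empty(0, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# reflection kernels

_MAX_REFLECT = 64


@njit(cache=True, inline="always")
def _exit_time_inside(px, py, vx, vy, r):
    """Largest root of |p + t v| = r for p inside the circle (t >= 0)."""
    a = vx * vx + vy * vy
    b = 2.0 * (px * vx + py * vy)
    c = px * px + py * py - r * r
    disc = b * b - 4.0 * a * c
    if disc <= 0.0 or a == 0.0:
        return 2.0  # no exit within this step
    return (-b + np.sqrt(disc)) / (2.0 * a)


@njit(cache=True, inline="always")
def _entry_time_outside(px, py, vx, vy, r):
    """Smallest positive root of |p + t v| = r for p outside (2.0 if none)."""
    a = vx * vx + vy * vy
    b = 2.0 * (px * vx + py * vy)
    c = px * px + py * py - r * r
    if b >= 0.0:
        return 2.0  # moving away from the circle center's near side
    disc = b * b - 4.0 * a * c
    if disc <= 0.0 or a == 0.0:
        return 2.0
    sq = np.sqrt(disc)
    t = (-b - sq) / (2.0 * a)
    if t < -1e-12:
        return 2.0
    return t if t > 0.0 else 0.0


@njit(cache=True)
def _walk_intra(rel0, radii_w, n_steps, step_len, sample_steps, dx, dy, seed):
    """Confined walk inside per-walker circles (positions relative to center).

    Returns the number of reflection-cap fallback events.
    """
    np.random.seed(seed)
    n_w = rel0.shape[0]
    n_rej = 0
    for w in range(n_w):
        px = rel0[w, 0]
        py = rel0[w, 1]
        x0 = px
        y0 = py
        r = radii_w[w]
        k_s = 0
        n_s = sample_steps.shape[0]
        while k_s < n_s and sample_steps[k_s] == 0:
            dx[w, k_s] = 0.0
            dy[w, k_s] = 0.0
            k_s += 1
        for step in range(1, n_steps + 1):
            theta = np.random.uniform(0.0, 2.0 * np.pi)
            vx = step_len * np.cos(theta)
            vy = step_len * np.sin(theta)
            ok = False
            for _ in range(_MAX_REFLECT):
                t = _exit_time_inside(px, py, vx, vy, r)
                if t >= 1.0:
                    px += vx
                    py += vy
                    ok = True
                    break
                qx = px + t * vx
                qy = py + t * vy
                # unit outward normal
                nx = qx / r
                ny = qy / r
                rvx = (1.0 - t) * vx
                rvy = (1.0 - t) * vy
                dot = rvx * nx + rvy * ny
                vx = rvx - 2.0 * dot * nx
                vy = rvy - 2.0 * dot * ny
                # pull the contact point slightly inside to avoid re-hits
                px = qx * (1.0 - 1e-12)
                py = qy * (1.0 - 1e-12)
            if not ok:
                n_rej += 1  # remain at the wall contact; drop the remainder
            while k_s < n_s and sample_steps[k_s] == step:
                dx[w, k_s] = px - x0
                dy[w, k_s] = py - y0
                k_s += 1
    return n_rej


@njit(cache=True)
def _build_cell_list(centers, radii, L, n_cells, reach):
    """CSR candidate lists: cylinders relevant to segments starting in a cell.

    A cylinder is a candidate for a cell when its wall can be touched by a
    path of total length <= reach starting anywhere in the cell.
    """
    h = L / n_cells
    half_diag = 0.5 * h * np.sqrt(2.0)
    n_cyl = centers.shape[0]
    counts = np.zeros(n_cells * n_cells, dtype=np.int64)
    for ci in range(n_cells):
        ccx = (ci + 0.5) * h
        for cj in range(n_cells):
            ccy = (cj + 0.5) * h
            cnt = 0
            for k in range(n_cyl):
                ddx = _pm(centers[k, 0] - ccx, L)
                ddy = _pm(centers[k, 1] - ccy, L)
                lim = radii[k] + half_diag + reach
                if ddx * ddx + ddy * ddy <= lim * lim:
                    cnt += 1
            counts[ci * n_cells + cj] = cnt
    starts = np.zeros(n_cells * n_cells + 1, dtype=np.int64)
    for i in range(n_cells * n_cells):
        starts[i + 1] = starts[i] + counts[i]
    items = np.zeros(starts[-1], dtype=np.int64)
    fill = starts[:-1].copy()
    for ci in range(n_cells):
        ccx = (ci + 0.5) * h
        for cj in range(n_cells):
            ccy = (cj + 0.5) * h
            cell = ci * n_cells + cj
            for k in range(n_cyl):
                ddx = _pm(centers[k, 0] - ccx, L)
                ddy = _pm(centers[k, 1] - ccy, L)
                lim = radii[k] + half_diag + reach
                if ddx * ddx + ddy * ddy <= lim * lim:
                    items[fill[cell]] = k
                    fill[cell] += 1
    return starts, items


@njit(cache=True, inline="always")
def _pm(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def _walk_extra(
    pos0, centers, radii, L, n_cells, starts, items, n_steps, step_len,
    sample_steps, dx, dy, seed,
):
    """Periodic walk outside the outer circles with specular reflection."""
    np.random.seed(seed)
    n_w = pos0.shape[0]
    h = L / n_cells
    n_rej = 0
    for w in range(n_w):
        # unwrapped position; geometry uses the wrapped image + minimum image
        ux = pos0[w, 0]
        uy = pos0[w, 1]
        x0 = ux
        y0 = uy
        k_s = 0
        n_s = sample_steps.shape[0]
        while k_s < n_s and sample_steps[k_s] == 0:
            dx[w, k_s] = 0.0
            dy[w, k_s] = 0.0
            k_s += 1
        for step in range(1, n_steps + 1):
            theta = np.random.uniform(0.0, 2.0 * np.pi)
            vx = step_len * np.cos(theta)
            vy = step_len * np.sin(theta)
            wx = ux % L
            wy = uy % L
            ci = int(wx / h)
            cj = int(wy / h)
            if ci >= n_cells:
                ci = n_cells - 1
            if cj >= n_cells:
                cj = n_cells - 1
            cell = ci * n_cells + cj
            a0 = starts[cell]
            a1 = starts[cell + 1]
            ok = False
            for _ in range(_MAX_REFLECT):
                # earliest wall hit among candidate cylinders
                t_min = 2.0
                k_min = -1
                for a in range(a0, a1):
                    k = items[a]
                    rx = _pm(wx - centers[k, 0], L)
                    ry = _pm(wy - centers[k, 1], L)
                    t = _entry_time_outside(rx, ry, vx, vy, radii[k])
                    if t < t_min:
                        t_min = t
                        k_min = k
                if k_min < 0 or t_min >= 1.0:
                    ux += vx
                    uy += vy
                    ok = True
                    break
                k = k_min
                rx = _pm(wx - centers[k, 0], L)
                ry = _pm(wy - centers[k, 1], L)
                qx = rx + t_min * vx
                qy = ry + t_min * vy
                r = radii[k]
                nx = qx / r
                ny = qy / r
                rvx = (1.0 - t_min) * vx
                rvy = (1.0 - t_min) * vy
                dot = rvx * nx + rvy * ny
                vx = rvx - 2.0 * dot * nx
                vy = rvy - 2.0 * dot * ny
                # advance to contact, pushed slightly outside the wall
                newrx = qx * (1.0 + 1e-12)
                newry = qy * (1.0 + 1e-12)
                ux += (newrx - rx)
                uy += (newry - ry)
                wx = ux % L
                wy = uy % L
            if not ok:
                n_rej += 1
            while k_s < n_s and sample_steps[k_s] == step:
                dx[w, k_s] = ux - x0
                dy[w, k_s] = uy - y0
                k_s += 1
    return n_rej


# ---------------------------------------------------------------------------


def reflect_step(pos, step, circle, side: str):
    """Specular reflection of a single step off one circle (test utility).

    ``circle`` is anything with attributes x, y and either r_in/r_out; the
    radius used is r_in for ``side='inside'`` (confined walker) and r_out
    for ``side='outside'``.  Returns (new_position, remaining_step); the
    remaining step still has to be applied (possibly reflecting again).
    If the segment does not intersect the circle, returns (pos+step, 0).
    """
    pos = np.asarray(pos, dtype=float)
    v = np.asarray(step, dtype=float)
    c = np.array([circle.x, circle.y])
    r = circle.r_in if side == "inside" else circle.r_out
    p = pos - c
    if side == "inside":
        t = _exit_time_inside(p[0], p[1], v[0], v[1], r)
    else:
        t = _entry_time_outside(p[0], p[1], v[0], v[1], r)
    if t >= 1.0:
        return pos + v, np.zeros(2)
    q = p + t * v
    n = q / r
    rv = (1.0 - t) * v
    rv = rv - 2.0 * (rv @ n) * n
    eps = -1e-12 if side == "inside" else 1e-12
    return c + q * (1.0 + eps), rv


def run_dynamics(
    substrate: Substrate,
    ensemble: WalkerEnsemble,
    duration: float,
    n_steps: int,
    sample_times: np.ndarray | None = None,
    seed: int = 0,
) -> list[DisplacementSeries]:
    """Run the random walk and record displacements at the sample times.

    Returns one :class:`DisplacementSeries` per compartment present in the
    ensemble.  Sample times are snapped to the nearest step boundary; the
    reported ``times`` are the snapped values.
    """
    if duration <= 0 or n_steps < 1:
        raise ValueError("need duration > 0 and n_steps >= 1")
    if sample_times is None:
        sample_times = default_sample_times(duration)
    sample_times = np.sort(np.asarray(sample_times, dtype=float))
    if sample_times[0] < 0 or sample_times[-1] > duration * (1 + 1e-9):
        raise ValueError("sample_times must lie in [0, duration]")
    dt = duration / n_steps
    sample_steps = np.clip(np.round(sample_times / dt).astype(np.int64), 0, n_steps)
    times_out = sample_steps * dt

    out = []
    intra = ensemble.compartment == "intra"
    extra = ensemble.compartment == "extra"

    if intra.any():
        step_len = float(np.sqrt(4.0 * substrate.d_in0 * dt))
        if substrate.n_cylinders and step_len > 0.5 * substrate.r_in.min():
            import warnings

            warnings.warn(
                f"intra step length {step_len:.3g} exceeds half the smallest "
                f"inner radius {substrate.r_in.min():.3g}; increase n_steps",
                stacklevel=2,
            )
        idx = ensemble.cyl_index[intra]
        rel0 = ensemble.positions[intra] - substrate.centers[idx]
        radii_w = substrate.r_in[idx]
        n_w = int(intra.sum())
        dx = np.empty((n_w, len(sample_steps)))
        dy = np.empty((n_w, len(sample_steps)))
        n_rej = _walk_intra(
            np.ascontiguousarray(rel0),
            np.ascontiguousarray(radii_w),
            n_steps,
            step_len,
            sample_steps,
            dx,
            dy,
            seed,
        )
        out.append(
            DisplacementSeries(times_out, dx, dy, "intra", seed=seed, n_rejected=n_rej)
        )

    if extra.any():
        step_len = float(np.sqrt(4.0 * substrate.d_ex0 * dt))
        n_w = int(extra.sum())
        dx = np.empty((n_w, len(sample_steps)))
        dy = np.empty((n_w, len(sample_steps)))
        if substrate.n_cylinders:
            centers = np.ascontiguousarray(np.mod(substrate.centers, substrate.L))
            radii = np.ascontiguousarray(substrate.r_out)
            r_max = float(radii.max())
            # cell size must keep every reachable wall inside the 1-cell list
            n_cells = max(1, int(substrate.L / max(r_max + 2 * step_len, 1e-6)))
            n_cells = min(n_cells, 64)
            starts, items = _build_cell_list(
                centers, radii, substrate.L, n_cells, reach=2 * step_len
            )
        else:
            centers = np.zeros((0, 2))
            radii = np.zeros(0)
            n_cells = 1
            starts = np.zeros(2, dtype=np.int64)
            items = np.zeros(0, dtype=np.int64)
        n_rej = _walk_extra(
            np.ascontiguousarray(ensemble.positions[extra]),
            centers,
            radii,
            substrate.L,
            n_cells,
            starts,
            items,
            n_steps,
            step_len,
            sample_steps,
            dx,
            dy,
            seed + 1,
        )
        out.append(
            DisplacementSeries(times_out, dx, dy, "extra", seed=seed, n_rejected=n_rej)
        )
    return out
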