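"""Synthetic white-matter cross-sections of parallel myelinated cylinders.

White matter is modelled as a periodic 2-D cross-section of impermeable,
parallel cylinders ("axons") aligned with z.  Each myelinated axon is a pair
of concentric circles: the outer circle bounds the myelin sheath, the inner
circle (radius ``g * r_out`` for g-ratio ``g``) bounds the intra-axonal
water.  Outer radii follow a gamma law truncated below ``r_min``.

Two density regimes are used throughout: a fibre volume fraction (FVF,
myelinated-fibre area over box area) of 0.7 ("high") or 0.4 ("low").  The
MR-visible axonal water fraction (AWF) excludes myelin water and relates to
FVF through the g-ratio::

    AWF = g^2 FVF / (1 + (g^2 - 1) FVF)

so FVF = 0.7 with g = 0.75 gives AWF = 0.57, and FVF = 0.4 gives 0.27.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

__all__ = [
    "GammaRadiusParams",
    "Cylinder",
    "Substrate",
    "PackingError",
    "awf_from_fvf",
    "fvf_from_awf",
    "gamma_radius_moments",
    "sample_radii",
    "pack_substrate",
    "locate_compartment",
    "make_preset_substrate",
    "PRESETS",
]

#: truncation floor for sampled radii (μm); avoids pores smaller than a few
#: walker steps
DEFAULT_R_MIN = 0.1


class PackingError(RuntimeError):
    """Raised when the packer cannot reach the target fibre volume fraction."""

    def __init__(self, msg: str, achieved_fvf: float):
        super().__init__(msg)
        self.achieved_fvf = achieved_fvf


@dataclass(frozen=True)
class GammaRadiusParams:
    """Gamma law for axon radii: shape ``a`` (dimensionless), scale ``b`` (μm).

    Mean and variance of the untruncated law are ``a*b`` and ``a*b**2``.
    ``r_min`` is a hard truncation floor enforced by rejection sampling.
    """

    a: float
    b: float
    r_min: float = DEFAULT_R_MIN

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0 and self.r_min >= 0):
            raise ValueError(
                f"invalid gamma radius parameters a={self.a}, b={self.b}, "
                f"r_min={self.r_min}"
            )


@dataclass(frozen=True)
class Cylinder:
    """One myelinated axon cross-section: concentric inner/outer circles (μm)."""

    x: float
    y: float
    r_out: float
    r_in: float

    def __post_init__(self):
        if not (0 < self.r_in < self.r_out):
            raise ValueError(f"need 0 < r_in < r_out, got {self.r_in}, {self.r_out}")


def awf_from_fvf(fvf: float, g: float) -> float:
    """Axonal water fraction implied by a fibre volume fraction and g-ratio.

    AWF = g²·FVF / (1 + (g² − 1)·FVF).  Monotone increasing in FVF, with
    AWF(0) = 0 and AWF(1) = 1 for any valid g.
    """
    if not 0 <= fvf <= 1:
        raise ValueError(f"fvf must be in [0, 1], got {fvf}")
    if not 0 < g <= 1:
        raise ValueError(f"g must be in (0, 1], got {g}")
    return g * g * fvf / (1.0 + (g * g - 1.0) * fvf)


def fvf_from_awf(awf: float, g: float) -> float:
    """Algebraic inverse of :func:`awf_from_fvf` at fixed g-ratio."""
    if not 0 <= awf <= 1:
        raise ValueError(f"awf must be in [0, 1], got {awf}")
    if not 0 < g <= 1:
        raise ValueError(f"g must be in (0, 1], got {g}")
    return awf / (g * g + (1.0 - g * g) * awf)


def gamma_radius_moments(params: GammaRadiusParams) -> tuple[float, float]:
    """(mean, variance) of the untruncated gamma radius law: (a·b, a·b²)."""
    return params.a * params.b, params.a * params.b**2


def sample_radii(
    params: GammaRadiusParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` radii from the gamma law, resampling any below ``r_min``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    from scipy.stats import gamma as gamma_dist

    if params.r_min > 0:
        q999 = gamma_dist.ppf(0.999, params.a, scale=params.b)
        if params.r_min >= q999:
            raise ValueError(
                f"r_min={params.r_min} is above the 99.9th percentile "
                f"({q999:.4g}) of the gamma law; truncation infeasible"
            )
    radii = rng.gamma(params.a, params.b, size=n)
    bad = radii < params.r_min
    while bad.any():
        radii[bad] = rng.gamma(params.a, params.b, size=int(bad.sum()))
        bad = radii < params.r_min
    return radii


@dataclass
class Substrate:
    """Periodic box [0, L) × [0, L) of non-overlapping myelinated cylinders."""

    L: float
    g: float
    centers: np.ndarray  # (N, 2) μm
    r_out: np.ndarray  # (N,) μm
    d_in0: float = 2.0  # intrinsic intra-axonal diffusivity, μm² ms⁻¹
    d_ex0: float = 1.0  # intrinsic extra-axonal diffusivity, μm² ms⁻¹
    seed: int | None = None

    r_in: np.ndarray = field(init=False)

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = np.empty((0, 2))
        self.r_out = np.asarray(self.r_out, dtype=float)
        self.r_in = self.g * self.r_out

    @property
    def n_cylinders(self) -> int:
        return len(self.r_out)

    @property
    def fvf(self) -> float:
        """Achieved fibre volume fraction from outer-circle areas.

        Each cylinder's area is counted exactly once; under periodic
        wrapping the full disk lies inside the box.
        """
        return float(np.sum(np.pi * self.r_out**2) / self.L**2)

    @property
    def awf(self) -> float:
        """Achieved axonal water fraction: inner area over MR-visible area."""
        inner = float(np.sum(np.pi * self.r_in**2))
        myelin = float(np.sum(np.pi * (self.r_out**2 - self.r_in**2)))
        visible = self.L**2 - myelin
        return inner / visible

    @property
    def cylinders(self) -> list[Cylinder]:
        return [
            Cylinder(float(x), float(y), float(ro), float(ri))
            for (x, y), ro, ri in zip(self.centers, self.r_out, self.r_in)
        ]

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "L": self.L,
            "g": self.g,
            "seed": self.seed,
            "d_in0": self.d_in0,
            "d_ex0": self.d_ex0,
            "achieved_fvf": self.fvf,
            "achieved_awf": self.awf,
            "cylinders": [
                {"x": float(x), "y": float(y), "r_out": float(ro), "r_in": float(ri)}
                for (x, y), ro, ri in zip(self.centers, self.r_out, self.r_in)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "Substrate":
        with open(path) as fh:
            doc = json.load(fh)
        cyl = doc["cylinders"]
        centers = np.array([[c["x"], c["y"]] for c in cyl]) if cyl else np.empty((0, 2))
        r_out = np.array([c["r_out"] for c in cyl])
        return cls(
            L=doc["L"],
            g=doc["g"],
            centers=centers,
            r_out=r_out,
            d_in0=doc.get("d_in0", 2.0),
            d_ex0=doc.get("d_ex0", 1.0),
            seed=doc.get("seed"),
        )


# -- packing ---------------------------------------------------------------


@njit(cache=True)
def _min_image(d: float, L: float) -> float:
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def _relax_overlaps(centers, radii, L, max_sweeps, tol):
    """Iterative pairwise overlap repulsion with periodic minimum image.

    Each sweep pushes every overlapping pair apart symmetrically along the
    line of centers.  Returns the number of sweeps used; -1 on failure.
    O(N²) per sweep which is fine for the few-thousand-disk substrates here.
    """
    n = centers.shape[0]
    for sweep in range(max_sweeps):
        moved = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx = _min_image(centers[j, 0] - centers[i, 0], L)
                dy = _min_image(centers[j, 1] - centers[i, 1], L)
                target = radii[i] + radii[j]
                d2 = dx * dx + dy * dy
                if d2 < target * target:
                    d = np.sqrt(d2)
                    if d < 1e-12:
                        # coincident: nudge deterministically
                        dx, dy, d = target, 0.0, 1e-12
                    # push each disk half the overlap, tiny margin on top
                    push = 0.5 * (target - d) * (1.0 + 1e-6)
                    ux, uy = dx / d, dy / d
                    centers[i, 0] = (centers[i, 0] - push * ux) % L
                    centers[i, 1] = (centers[i, 1] - push * uy) % L
                    centers[j, 0] = (centers[j, 0] + push * ux) % L
                    centers[j, 1] = (centers[j, 1] + push * uy) % L
                    moved += 1
        if moved == 0:
            return sweep
    # final check with tolerance
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(centers[j, 0] - centers[i, 0], L)
            dy = _min_image(centers[j, 1] - centers[i, 1], L)
            target = radii[i] + radii[j]
            if dx * dx + dy * dy < (target * (1.0 - tol)) ** 2:
                return -1
    return max_sweeps


@njit(cache=True)
def _rsa_insert(centers, radii, L, n_placed, r_new, trial_xy, max_trials):
    """Try to insert one disk without overlap; returns trial index or -1."""
    for t in range(max_trials):
        x = trial_xy[t, 0]
        y = trial_xy[t, 1]
        ok = True
        for i in range(n_placed):
            dx = _min_image(x - centers[i, 0], L)
            dy = _min_image(y - centers[i, 1], L)
            target = r_new + radii[i]
            if dx * dx + dy * dy < target * target:
                ok = False
                break
        if ok:
            return t
    return -1


def pack_substrate(
    radii: np.ndarray,
    g: float,
    L: float,
    target_fvf: float,
    rng: np.random.Generator,
    max_iter: int = 2000,
    d_in0: float = 2.0,
    d_ex0: float = 1.0,
    seed: int | None = None,
    fvf_tol: float = 0.02,
    clearance: float = 0.04,
) -> Substrate:
    """Pack outer radii into a periodic box at the target fibre volume fraction.

    Largest-first placement: random sequential addition while it succeeds,
    then (for dense targets beyond RSA jamming) random placement of the
    remainder followed by iterative overlap-repulsion relaxation under the
    periodic minimum image.  Deterministic given ``rng``.

    ``clearance`` is the fractional wall-to-wall gap enforced between
    neighbouring cylinders (packing runs on radii inflated by
    ``1 + clearance``; the substrate keeps the true radii).  In a 2-D
    cross-section, cylinders left in exact contact would seal the
    extra-cellular space into closed pockets and drive its long-time
    diffusivity to zero, which is unphysical for real fibre bundles where
    an extra-cellular matrix keeps the sheaths apart; a few percent of
    clearance keeps every throat open.

    The supplied radius list may be oversampled; disks are consumed in the
    given (sampling) order until their summed area reaches
    ``target_fvf * L**2`` — preserving the sampled size distribution — and
    only the placement order is largest-first.
    """
    radii = np.asarray(radii, dtype=float)
    areas = np.pi * radii**2
    cum = np.cumsum(areas) / L**2
    if cum[-1] < target_fvf - fvf_tol:
        raise PackingError(
            f"supplied radii reach FVF {cum[-1]:.3f} < target {target_fvf}",
            achieved_fvf=float(cum[-1]),
        )
    n_use = int(np.searchsorted(cum, target_fvf) + 1)
    n_use = min(n_use, len(radii))
    radii = radii[:n_use]
    if abs(cum[n_use - 1] - target_fvf) > fvf_tol:
        # overshoot from one huge disk; drop it if that is closer to target
        if n_use > 1 and abs(cum[n_use - 2] - target_fvf) < abs(
            cum[n_use - 1] - target_fvf
        ):
            radii = radii[: n_use - 1]
    radii = np.sort(radii)[::-1]  # placement order only

    n = len(radii)
    packing_radii = radii * (1.0 + clearance)
    centers = np.empty((n, 2))
    n_placed = 0
    # stage 1: RSA largest-first
    for i in range(n):
        trials = rng.uniform(0, L, size=(200, 2))
        t = _rsa_insert(
            centers, packing_radii, L, n_placed, packing_radii[i], trials, len(trials)
        )
        if t < 0:
            break
        centers[n_placed] = trials[t]
        n_placed += 1
    # stage 2: random placement of the remainder + relaxation
    if n_placed < n:
        centers[n_placed:] = rng.uniform(0, L, size=(n - n_placed, 2))
        status = _relax_overlaps(centers, packing_radii, L, max_iter, tol=1e-6)
        if status < 0:
            ach = float(np.sum(np.pi * radii**2) / L**2)
            raise PackingError(
                f"overlap relaxation did not converge in {max_iter} sweeps "
                f"(target FVF {target_fvf})",
                achieved_fvf=ach,
            )
    sub = Substrate(
        L=L, g=g, centers=centers, r_out=radii, d_in0=d_in0, d_ex0=d_ex0, seed=seed
    )
    if abs(sub.fvf - target_fvf) > fvf_tol:
        raise PackingError(
            f"achieved FVF {sub.fvf:.4f} outside ±{fvf_tol} of {target_fvf}",
            achieved_fvf=sub.fvf,
        )
    return sub


# -- point queries ---------------------------------------------------------


def _periodic_tree(substrate: Substrate) -> cKDTree:
    return cKDTree(np.mod(substrate.centers, substrate.L), boxsize=substrate.L)


def locate_compartment(points: np.ndarray, substrate: Substrate) -> np.ndarray:
    """Classify points as 'intra', 'myelin' or 'extra' (periodic wrap applied).

    intra: strictly inside some inner circle; myelin: inside an outer circle
    but not its inner one; extra: otherwise.
    """
    pts = np.mod(np.atleast_2d(np.asarray(points, dtype=float)), substrate.L)
    out = np.full(len(pts), "extra", dtype=object)
    if substrate.n_cylinders == 0:
        return out
    tree = _periodic_tree(substrate)
    r_max = float(substrate.r_out.max())
    neighbours = tree.query_ball_point(pts, r=r_max + 1e-9)
    L = substrate.L
    for k, idx in enumerate(neighbours):
        for i in idx:
            d = pts[k] - np.mod(substrate.centers[i], L)
            d -= L * np.round(d / L)
            r2 = d @ d
            if r2 < substrate.r_in[i] ** 2:
                out[k] = "intra"
                break
            if r2 < substrate.r_out[i] ** 2:
                out[k] = "myelin"
                break
    return out


# -- presets ---------------------------------------------------------------

#: §-style presets: inner-radius gamma laws for the two axon calibres, with
#: outer = inner / g under the default dialect.  The alternative dialect
#: samples the outer law directly.
PRESETS = {
    "large_axons": {
        "inner": GammaRadiusParams(a=3.11, b=0.86),
        "outer": GammaRadiusParams(a=3.01, b=1.63),
    },
    "small_axons": {
        "inner": GammaRadiusParams(a=5.69, b=0.17),
        "outer": GammaRadiusParams(a=5.73, b=0.23),
    },
}

DENSITY_FVF = {"high": 0.7, "low": 0.4}
G_RATIO_DEFAULT = 0.75


def make_preset_substrate(
    preset: str,
    density: str,
    seed: int,
    L: float = 200.0,
    g: float = G_RATIO_DEFAULT,
    dialect: str = "printed_moments",
    d_in0: float = 2.0,
    d_ex0: float = 1.0,
    max_iter: int = 2000,
) -> Substrate:
    """Build one of the four canonical substrates (axon calibre × density).

    ``dialect`` resolves the two published parametrisations of the radius
    law: ``printed_moments`` (default) samples inner radii from the inner
    gamma law and scales outward by 1/g, which reproduces the quoted outer
    mean/variance to ~1%; ``printed_ab`` samples outer radii from the outer
    (a, b) directly.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options {sorted(PRESETS)}")
    if density not in DENSITY_FVF:
        raise ValueError(f"unknown density {density!r}; options {sorted(DENSITY_FVF)}")
    target_fvf = DENSITY_FVF[density]
    rng = np.random.default_rng(seed)
    if dialect == "printed_moments":
        law = PRESETS[preset]["inner"]
        mean_r2_out = (law.a * (law.a + 1) * law.b**2) / g**2
    elif dialect == "printed_ab":
        law = PRESETS[preset]["outer"]
        mean_r2_out = law.a * (law.a + 1) * law.b**2
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    # oversample by 30% so the packer can truncate largest-first
    n_est = int(np.ceil(1.3 * target_fvf * L**2 / (np.pi * mean_r2_out)))
    r = sample_radii(law, n_est, rng)
    r_out = r / g if dialect == "printed_moments" else r
    return pack_substrate(
        r_out,
        g,
        L,
        target_fvf,
        rng,
        max_iter=max_iter,
        d_in0=d_in0,
        d_ex0=d_ex0,
        seed=seed,
    )
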