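"""Time-dependent perpendicular diffusivity and kurtosis excess.

From the unwrapped perpendicular displacements Δx(t), Δy(t) of a walker
ensemble, the apparent perpendicular diffusivity is

    D⊥(t) = E[Δx² + Δy²] / (4 t)

and the direction-averaged perpendicular kurtosis excess is

    K⊥(t) = (1/2π) ∫₀^{2π} K[Δx cosφ + Δy sinφ] dφ

with K[·] the kurtosis-excess operator (m₄/m₂² − 3, central moments).
K⊥ = 0 for Gaussian diffusion, −0.5 in the long-time limit for a single
cylinder (uniform confinement), and > 0 for mixtures of pore sizes.

The long-time tortuosity approximation for the extra-axonal space is
D_lim = (1 − FVF)·D_ex,0; simulated long-time D_ex,⊥ generally sits above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import DisplacementSeries

__all__ = [
    "TimeMetricSeries",
    "perpendicular_diffusivity",
    "perpendicular_kurtosis",
    "tortuosity_limit",
    "aggregate_over_seeds",
    "compute_metrics",
    "long_time_value",
]


@dataclass
class TimeMetricSeries:
    """D⊥(t) and K⊥(t) for one compartment, per seed and seed-aggregated."""

    times: np.ndarray  # (n_t,) ms
    d_perp: np.ndarray  # (n_seeds, n_t)
    k_perp: np.ndarray  # (n_seeds, n_t)
    compartment: str
    seeds: list = field(default_factory=list)

    @property
    def d_mean(self) -> np.ndarray:
        return self.d_perp.mean(axis=0)

    @property
    def d_sd(self) -> np.ndarray:
        return self.d_perp.std(axis=0, ddof=1) if len(self.d_perp) > 1 else np.zeros_like(self.d_mean)

    @property
    def k_mean(self) -> np.ndarray:
        return self.k_perp.mean(axis=0)

    @property
    def k_sd(self) -> np.ndarray:
        return self.k_perp.std(axis=0, ddof=1) if len(self.k_perp) > 1 else np.zeros_like(self.k_mean)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table {compartment, seed, t_ms, D_perp, K_perp}."""
        rows = []
        for s in range(self.d_perp.shape[0]):
            seed = self.seeds[s] if s < len(self.seeds) else s
            rows.append(
                pd.DataFrame(
                    {
                        "compartment": self.compartment,
                        "seed": seed,
                        "t_ms": self.times,
                        "D_perp": self.d_perp[s],
                        "K_perp": self.k_perp[s],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def perpendicular_diffusivity(ds: DisplacementSeries) -> np.ndarray:
    """Empirical D⊥ at each sample time: mean of (Δx²+Δy²)/(4t).

    Times equal to zero are returned as NaN (the definition divides by t).
    """
    if ds.dx.shape[0] < 100:
        warnings.warn(
            f"only {ds.dx.shape[0]} walkers; D_perp estimate will be noisy",
            stacklevel=2,
        )
    msd = np.mean(ds.dx**2 + ds.dy**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = msd / (4.0 * ds.times)
    d[ds.times == 0] = np.nan
    return d


def perpendicular_kurtosis(ds: DisplacementSeries, n_phi: int = 64) -> np.ndarray:
    """Direction-averaged kurtosis excess of the projected displacement.

    For each angle φ on a uniform grid over [0, 2π), project the 2-D
    displacement onto (cosφ, sinφ), take the kurtosis excess of the
    projection (biased moment-ratio estimator, central moments), and
    average over φ.  For a uniform periodic grid the trapezoidal rule
    reduces to the plain mean over grid points.
    """
    if n_phi < 8:
        raise ValueError("n_phi must be >= 8")
    if ds.dx.shape[0] < 500:
        warnings.warn(
            f"only {ds.dx.shape[0]} walkers; 4th-moment estimate unreliable",
            stacklevel=2,
        )
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    cosphi = np.cos(phi)[:, None]  # (n_phi, 1)
    sinphi = np.sin(phi)[:, None]
    n_t = ds.dx.shape[1]
    out = np.empty(n_t)
    for j in range(n_t):
        proj = cosphi * ds.dx[:, j] + sinphi * ds.dy[:, j]  # (n_phi, n_w)
        proj = proj - proj.mean(axis=1, keepdims=True)
        m2 = np.mean(proj**2, axis=1)
        m4 = np.mean(proj**4, axis=1)
        if np.any(m2 == 0):
            raise ZeroDivisionError(
                f"zero-variance projection at time index {j}; kurtosis undefined"
            )
        out[j] = np.mean(m4 / m2**2 - 3.0)
    return out


def tortuosity_limit(fvf: float, d_ex0: float) -> float:
    """Long-time extra-axonal perpendicular diffusivity: (1 − FVF)·D_ex,0."""
    if not 0 <= fvf <= 1:
        raise ValueError(f"fvf must be in [0, 1], got {fvf}")
    if d_ex0 <= 0:
        raise ValueError(f"d_ex0 must be > 0, got {d_ex0}")
    return (1.0 - fvf) * d_ex0


def compute_metrics(
    series: list[DisplacementSeries], n_phi: int = 64
) -> TimeMetricSeries:
    """Per-seed D⊥(t), K⊥(t) from displacement series of one compartment."""
    comp = {s.compartment for s in series}
    if len(comp) != 1:
        raise ValueError(f"mixed compartments {comp}; compute per compartment")
    times = series[0].times
    for s in series[1:]:
        if not np.allclose(s.times, times):
            raise ValueError("mismatched time grids across seeds")
    d = np.vstack([perpendicular_diffusivity(s) for s in series])
    k = np.vstack([perpendicular_kurtosis(s, n_phi=n_phi) for s in series])
    return TimeMetricSeries(
        times=times,
        d_perp=d,
        k_perp=k,
        compartment=comp.pop(),
        seeds=[s.seed for s in series],
    )


def aggregate_over_seeds(series: list[TimeMetricSeries]) -> TimeMetricSeries:
    """Stack per-seed metric series into one (pointwise mean/sd available)."""
    times = series[0].times
    comp = series[0].compartment
    for s in series[1:]:
        if not np.allclose(s.times, times):
            raise ValueError("mismatched time grids")
        if s.compartment != comp:
            raise ValueError("mismatched compartments")
    return TimeMetricSeries(
        times=times,
        d_perp=np.vstack([s.d_perp for s in series]),
        k_perp=np.vstack([s.k_perp for s in series]),
        compartment=comp,
        seeds=[sd for s in series for sd in (s.seeds or [None])],
    )


def long_time_value(times: np.ndarray, values: np.ndarray, n_last: int = 3) -> float:
    """Long-time level as the mean over the last ``n_last`` sample points."""
    return float(np.mean(np.asarray(values)[..., -n_last:]))
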