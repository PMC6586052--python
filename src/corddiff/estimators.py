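"""Voxel-wise estimators: DTI, constrained-WLLS DKI and spherical-mean SMT.

Three clinically-established single-voxel analyses:

* **DTI** — weighted linear least squares on the log-signal, restricted to
  b = 0 and the low shell (where Gaussian behaviour is a fair
  approximation).  Axial/radial diffusivity are the largest eigenvalue and
  the mean of the two smaller ones of the macroscopic tensor.
* **DKI** — log-signal cumulant model
  ln S = ln S0 − b D(g) + (b²/6) V(g), with V(g) = MD²·W(g) the scaled
  kurtosis tensor (15 independent components), fitted by WLLS with linear
  inequality constraints on the directional apparent kurtosis
  K(g) = V(g)/D(g)² ∈ [0, K_max].
* **SMT (microscopic DT)** — per-shell direction averages, which for an
  axially-symmetric tensor depend only on (λ∥, λ⊥) through
  ε(b) = exp(−b λ⊥) √π erf(√(b Δλ)) / (2 √(b Δλ)), Δλ = λ∥ − λ⊥;
  the per-axon ("microscopic") tensor is recovered independently of the
  orientation distribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf

from .protocol import PGSEProtocol

__all__ = [
    "DTIFit",
    "DKIFit",
    "SMTFit",
    "fit_dti",
    "fit_dki",
    "spherical_mean",
    "fit_smt_micro",
    "smt_kernel",
]

# -- tensor index bookkeeping ----------------------------------------------

_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

_W_IDX = sorted({tuple(sorted(q)) for q in itertools.product(range(3), repeat=4)})
_W_MULT = np.zeros(len(_W_IDX))
for _q in itertools.product(range(3), repeat=4):
    _W_MULT[_W_IDX.index(tuple(sorted(_q)))] += 1.0


def _d_design(g: np.ndarray) -> np.ndarray:
    """(n, 6) rows of multiplicity-weighted g_i g_j for the 6 unique D comps."""
    cols = [g[:, i] * g[:, j] for i, j in _D_IDX]
    return np.stack(cols, axis=1) * _D_MULT


def _w_design(g: np.ndarray) -> np.ndarray:
    """(n, 15) rows of multiplicity-weighted g_i g_j g_k g_l products."""
    cols = [g[:, i] * g[:, j] * g[:, k] * g[:, l] for i, j, k, l in _W_IDX]
    return np.stack(cols, axis=1) * _W_MULT


def _vec_to_tensor(d6: np.ndarray) -> np.ndarray:
    t = np.zeros((3, 3))
    for v, (i, j) in zip(d6, _D_IDX):
        t[i, j] = t[j, i] = v
    return t


# -- DTI --------------------------------------------------------------------


@dataclass
class DTIFit:
    tensor: np.ndarray  # 3×3, μm² ms⁻¹
    s0: float
    eigenvalues: np.ndarray  # descending
    principal_direction: np.ndarray

    @property
    def ad(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def rd(self) -> float:
        return float(np.mean(self.eigenvalues[1:]))

    @property
    def md(self) -> float:
        return float(np.mean(self.eigenvalues))


def _wlls(X, y_log, y_lin):
    """OLS on the log-signal followed by one WLLS pass weighted by the
    squared predicted signals."""
    beta = np.linalg.lstsq(X, y_log, rcond=None)[0]
    w = np.exp(X @ beta) ** 2
    Xw = X * w[:, None]
    beta = np.linalg.solve(X.T @ Xw, Xw.T @ y_log)
    return beta


def fit_dti(
    signals: np.ndarray, protocol: PGSEProtocol, b_low_max: float = 1500.0
) -> DTIFit:
    """Weighted linear least-squares DTI on b = 0 plus the low shell only."""
    keep = protocol.bvals <= b_low_max
    y = np.asarray(signals, dtype=float)[keep]
    b = protocol.b_ms_um2[keep]
    g = protocol.bvecs[keep]
    pos = y > 0
    if (~pos).any():
        warnings.warn(f"excluding {int((~pos).sum())} non-positive signals", stacklevel=2)
    y, b, g = y[pos], b[pos], g[pos]
    if len(y) < 7:
        raise ValueError(f"only {len(y)} usable measurements; need >= 7")
    X = np.column_stack([np.ones(len(y)), -b[:, None] * _d_design(g)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient DTI design (too few directions)")
    beta = _wlls(X, np.log(y), y)
    tensor = _vec_to_tensor(beta[1:7])
    vals, vecs = np.linalg.eigh(tensor)
    order = np.argsort(vals)[::-1]
    return DTIFit(
        tensor=tensor,
        s0=float(np.exp(beta[0])),
        eigenvalues=vals[order],
        principal_direction=vecs[:, order[0]],
    )


# -- DKI --------------------------------------------------------------------


@dataclass
class DKIFit:
    tensor: np.ndarray
    v_tensor15: np.ndarray  # MD²·W components in _W_IDX order
    s0: float
    eigenvalues: np.ndarray
    principal_direction: np.ndarray
    constrained: bool
    constraint_feasible: bool

    def _d_of(self, g):
        g = np.atleast_2d(g)
        d6 = np.array([self.tensor[i, j] for i, j in _D_IDX])
        return _d_design(g) @ d6

    def _v_of(self, g):
        g = np.atleast_2d(g)
        return _w_design(g) @ self.v_tensor15

    def apparent_kurtosis(self, g: np.ndarray) -> np.ndarray:
        """Directional apparent kurtosis K(g) = V(g)/D(g)²."""
        return self._v_of(g) / self._d_of(g) ** 2

    @property
    def ad(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def rd(self) -> float:
        return float(np.mean(self.eigenvalues[1:]))

    @property
    def ak(self) -> float:
        return float(self.apparent_kurtosis(self.principal_direction[None, :])[0])

    @property
    def rk(self) -> float:
        return float(np.mean(self.apparent_kurtosis(_ring(self.principal_direction))))


def _ring(axis: np.ndarray, n: int = 32) -> np.ndarray:
    """n unit vectors evenly spaced on the circle orthogonal to ``axis``."""
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2)


def fit_dki(
    signals: np.ndarray,
    protocol: PGSEProtocol,
    k_max_scale: float | None = None,
) -> DKIFit:
    """Constrained WLLS DKI using all shells.

    The log-signal model is linear in [ln S0, 6 D comps, 15 V comps].  After
    an unconstrained WLLS pass the directional apparent kurtosis over the
    measured directions is checked against [0, K_max]; if violated, the
    WLLS quadratic objective is re-minimized under those linear constraints
    (D fixed from the first pass inside the constraint evaluation).  By
    default only the non-negativity bound is enforced; passing
    ``k_max_scale`` adds the upper bound K_max = scale/(b_max · D(g))
    (scale 3 forces monotone signal decay up to b_max, which also clips
    genuinely high axial kurtosis — hence opt-in).  If the constrained
    solve fails, the unconstrained fit is returned flagged infeasible.
    """
    y = np.asarray(signals, dtype=float)
    shells = protocol.shells()
    if len(shells) < 2:
        raise ValueError("DKI needs at least 2 nonzero shells")
    pos = y > 0
    if (~pos).any():
        warnings.warn(f"excluding {int((~pos).sum())} non-positive signals", stacklevel=2)
    y = y[pos]
    if len(y) < 22:
        raise ValueError(f"only {len(y)} usable measurements; need >= 22")
    b = protocol.b_ms_um2[pos]
    g = protocol.bvecs[pos]
    X = np.column_stack(
        [
            np.ones(len(y)),
            -b[:, None] * _d_design(g),
            (b[:, None] ** 2 / 6.0) * _w_design(g),
        ]
    )
    beta = _wlls(X, np.log(y), y)
    w = np.exp(X @ beta) ** 2

    dw = b > 0
    gd = g[dw]
    d_dirs = _d_design(gd) @ beta[1:7]
    d_dirs = np.maximum(d_dirs, 1e-6)
    b_max = b.max()
    if k_max_scale is None:
        k_max = np.full(len(gd), np.inf)
    else:
        k_max = k_max_scale / (b_max * d_dirs)
    A15 = _w_design(gd)
    v_dirs = A15 @ beta[7:]
    k_dirs = v_dirs / d_dirs**2
    feasible = True
    constrained = False
    if np.any(k_dirs < -1e-9) or np.any(k_dirs > k_max + 1e-9):
        constrained = True
        Xw = X * np.sqrt(w)[:, None]
        yw = np.log(y) * np.sqrt(w)

        def obj(bt):
            r = Xw @ bt - yw
            return 0.5 * r @ r

        def grad(bt):
            return Xw.T @ (Xw @ bt - yw)

        cons = [
            {  # V(g) >= 0
                "type": "ineq",
                "fun": lambda bt: A15 @ bt[7:],
                "jac": lambda bt: np.c_[np.zeros((len(gd), 7)), A15],
            },
        ]
        if np.isfinite(k_max).any():
            v_hi = k_max * d_dirs**2
            cons.append(
                {  # V(g) <= K_max D(g)²
                    "type": "ineq",
                    "fun": lambda bt: v_hi - A15 @ bt[7:],
                    "jac": lambda bt: -np.c_[np.zeros((len(gd), 7)), A15],
                }
            )
        res = minimize(obj, beta, jac=grad, method="SLSQP", constraints=cons,
                       options={"maxiter": 200})
        if res.success:
            beta = res.x
        else:
            feasible = False
            warnings.warn(
                "constrained DKI solve failed; returning unconstrained fit",
                stacklevel=2,
            )
    tensor = _vec_to_tensor(beta[1:7])
    vals, vecs = np.linalg.eigh(tensor)
    order = np.argsort(vals)[::-1]
    return DKIFit(
        tensor=tensor,
        v_tensor15=beta[7:],
        s0=float(np.exp(beta[0])),
        eigenvalues=vals[order],
        principal_direction=vecs[:, order[0]],
        constrained=constrained,
        constraint_feasible=feasible,
    )


# -- SMT --------------------------------------------------------------------


def spherical_mean(
    signals: np.ndarray, protocol: PGSEProtocol, min_dirs: int = 6
) -> tuple[np.ndarray, np.ndarray]:
    """Per-shell direction-averaged signal normalized by S0.

    Returns (bvals_s_mm2, means).  S0 is the mean b = 0 signal.
    """
    y = np.asarray(signals, dtype=float)
    b0 = protocol.bvals == 0
    if not b0.any():
        raise ValueError("no b=0 measurements for normalization")
    s0 = float(np.mean(y[b0]))
    shells = protocol.shells()
    if not shells:
        raise ValueError("no nonzero shells")
    out_b, out_m = [], []
    for bs in shells:
        m = np.isclose(protocol.bvals, bs, atol=1.0)
        if m.sum() < min_dirs:
            raise ValueError(f"shell b={bs} has {int(m.sum())} dirs; need >= {min_dirs}")
        out_b.append(bs)
        out_m.append(float(np.mean(y[m])) / s0)
    return np.array(out_b), np.array(out_m)


def smt_kernel(b_ms_um2, lam_par, lam_perp):
    """Spherical mean of an axisymmetric tensor signal.

    ε(b) = exp(−b λ⊥) √π erf(√(b Δλ)) / (2 √(b Δλ)) with Δλ = λ∥ − λ⊥;
    the Δλ → 0 limit exp(−b λ∥) is handled by series continuation.
    """
    b = np.asarray(b_ms_um2, dtype=float)
    x = b * (lam_par - lam_perp)
    out = np.empty_like(np.broadcast_arrays(b, x)[0], dtype=float)
    x = np.broadcast_to(x, out.shape).copy()
    small = np.abs(x) < 1e-8
    with np.errstate(invalid="ignore"):
        sx = np.sqrt(np.where(small, 1.0, x))
        out = np.sqrt(np.pi) * erf(sx) / (2.0 * sx)
    out = np.where(small, 1.0 - x / 3.0, out)
    return np.exp(-b * lam_perp) * out


@dataclass
class SMTFit:
    lam_par: float  # μAD
    lam_perp: float  # μRD
    rss: float


def fit_smt_micro(
    shell_means: np.ndarray,
    bvals_s_mm2: np.ndarray,
    ceiling: float = 3.2,
) -> SMTFit:
    """Least-squares microscopic tensor from per-shell spherical means.

    Grid search over (λ∥, λ⊥/λ∥) then bounded refinement; enforces
    0 ≤ λ⊥ ≤ λ∥ ≤ ceiling.
    """
    e = np.asarray(shell_means, dtype=float)
    b = np.asarray(bvals_s_mm2, dtype=float) * 1e-3
    if len(e) < 2:
        raise ValueError("SMT fit needs >= 2 nonzero shells")
    if np.any(e > 1.0 + 1e-9):
        warnings.warn("spherical means > 1 after normalization; clamping", stacklevel=2)
        e = np.minimum(e, 1.0)

    def rss(lam_par, frac):
        pred = smt_kernel(b, lam_par, frac * lam_par)
        return float(np.sum((pred - e) ** 2))

    lp_grid = np.linspace(0.05, ceiling, 40)
    fr_grid = np.linspace(0.0, 1.0, 21)
    best = min(
        ((rss(lp, fr), lp, fr) for lp in lp_grid for fr in fr_grid),
        key=lambda t: t[0],
    )

    from scipy.optimize import least_squares

    res = least_squares(
        lambda th: smt_kernel(b, th[0], th[1] * th[0]) - e,
        x0=[best[1], best[2]],
        bounds=([1e-4, 0.0], [ceiling, 1.0]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    lam_par, frac = res.x
    rss_aniso = float(np.sum(res.fun**2))
    # the (λ∥, λ⊥) surface is nearly flat along Δλ near isotropy: prefer the
    # exactly-isotropic solution when it explains the data equally well
    res_iso = least_squares(
        lambda th: smt_kernel(b, th[0], th[0]) - e,
        x0=[max(lam_par, 1e-3)],
        bounds=([1e-4], [ceiling]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    rss_iso = float(np.sum(res_iso.fun**2))
    if rss_iso <= rss_aniso + 1e-12:
        d_iso = float(res_iso.x[0])
        return SMTFit(lam_par=d_iso, lam_perp=d_iso, rss=rss_iso)
    return SMTFit(
        lam_par=float(lam_par),
        lam_perp=float(frac * lam_par),
        rss=rss_aniso,
    )
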