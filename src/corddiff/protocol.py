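"""Clinical multi-shell, multi-Δ PGSE protocol description.

The emulated acquisition is a pulsed-gradient spin-echo (PGSE) cervical-cord
protocol: for each gradient separation Δ ∈ {29, 52, 76} ms one two-shell
block of 6 interleaved b = 0, 20 directions at b = 711 s mm⁻² and 40
directions at b = 2855 s mm⁻², all with gradient duration δ = 22 ms
(66 measurements per block, 198 in total).  Direction sets are generated by
electrostatic-repulsion optimization on the sphere with antipodal symmetry.

Δ is recorded per measurement and used directly as the regressor in the
time-dependence statistics; the standard effective diffusion time Δ − δ/3
is provided for reporting against simulation time axes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PGSEProtocol",
    "build_protocol",
    "repulsion_directions",
    "effective_diffusion_time",
    "DEFAULT_DELTAS",
    "DEFAULT_SHELLS",
]

DEFAULT_DELTAS = (29.0, 52.0, 76.0)  # gradient separation Δ, ms
DEFAULT_DELTA_SMALL = 22.0  # gradient duration δ, ms
DEFAULT_SHELLS = ((711.0, 20), (2855.0, 40))  # (b s mm⁻², n directions)
DEFAULT_N_B0 = 6


def effective_diffusion_time(Delta: float, delta: float) -> float:
    """Standard PGSE effective diffusion time Δ − δ/3 (ms)."""
    return Delta - delta / 3.0


def repulsion_directions(n: int, rng: np.random.Generator, n_iter: int = 2000) -> np.ndarray:
    """Electrostatic-repulsion direction set with antipodal symmetry.

    Minimizes Σ 1/|x_i − x_j|² over both each pair and its antipode by
    projected gradient descent on the sphere from a random start.
    Returns (n, 3) unit vectors.
    """
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    lr = 0.02
    for _ in range(n_iter):
        force = np.zeros_like(x)
        for sign in (1.0, -1.0):
            diff = x[:, None, :] - sign * x[None, :, :]  # (n, n, 3)
            d2 = np.sum(diff**2, axis=-1) + 1e-9
            np.fill_diagonal(d2, np.inf)
            force += np.sum(diff / d2[..., None] ** 1.5, axis=1)
        # cap the largest move to keep the descent stable near close pairs
        norms = np.linalg.norm(force, axis=1, keepdims=True)
        force = force / np.maximum(norms.max(), 1.0)
        x_new = x + lr * n * force
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        x = x_new
    return x


@dataclass
class PGSEProtocol:
    """Per-measurement gradient table: b, direction, Δ, δ."""

    bvals: np.ndarray  # (n,) s mm⁻²
    bvecs: np.ndarray  # (n, 3) unit (zero rows for b = 0)
    Delta: np.ndarray  # (n,) ms
    delta: np.ndarray  # (n,) ms

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.Delta = np.asarray(self.Delta, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        n = len(self.bvals)
        if not (self.bvecs.shape == (n, 3) and len(self.Delta) == n == len(self.delta)):
            raise ValueError("inconsistent protocol array lengths")
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b_ms_um2(self) -> np.ndarray:
        """b-values in ms μm⁻² (internal unit system)."""
        return self.bvals * 1e-3

    @property
    def deltas_present(self) -> np.ndarray:
        return np.unique(self.Delta)

    def block(self, Delta: float) -> "PGSEProtocol":
        """Sub-protocol at one gradient separation."""
        m = np.isclose(self.Delta, Delta)
        if not m.any():
            raise ValueError(f"no measurements at Delta={Delta}")
        return PGSEProtocol(self.bvals[m], self.bvecs[m], self.Delta[m], self.delta[m])

    def block_indices(self, Delta: float) -> np.ndarray:
        return np.flatnonzero(np.isclose(self.Delta, Delta))

    def shells(self, tol: float = 1.0) -> list[float]:
        """Distinct nonzero b-values (s mm⁻²)."""
        bs = self.bvals[self.bvals > tol]
        out: list[float] = []
        for b in np.sort(bs):
            if not out or abs(b - out[-1]) > tol:
                out.append(float(b))
        return out


def build_protocol(
    deltas=DEFAULT_DELTAS,
    delta_small: float = DEFAULT_DELTA_SMALL,
    shells=DEFAULT_SHELLS,
    n_b0: int = DEFAULT_N_B0,
    rng: np.random.Generator | None = None,
) -> PGSEProtocol:
    """Assemble the multi-Δ two-shell protocol.

    Each Δ block interleaves ``n_b0`` b = 0 measurements among the shells
    and reuses the same repulsion-optimized direction sets across blocks
    (gradient strength, not direction, changes with Δ in the emulated
    acquisition).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not shells:
        raise ValueError("need at least one shell")
    for Delta in deltas:
        if Delta <= delta_small:
            raise ValueError(f"Delta={Delta} must exceed delta={delta_small}")
    dir_sets = {n_dirs: repulsion_directions(n_dirs, rng) for _, n_dirs in shells}
    bvals, bvecs, Dl, dl = [], [], [], []
    for Delta in deltas:
        # interleave b=0 measurements evenly through the block
        block_b, block_v = [], []
        for b, n_dirs in shells:
            for v in dir_sets[n_dirs]:
                block_b.append(b)
                block_v.append(v)
        n_dw = len(block_b)
        stride = max(1, n_dw // n_b0)
        out_b, out_v = [], []
        k = 0
        for i, (b, v) in enumerate(zip(block_b, block_v)):
            if i % stride == 0 and k < n_b0:
                out_b.append(0.0)
                out_v.append(np.zeros(3))
                k += 1
            out_b.append(b)
            out_v.append(v)
        while k < n_b0:
            out_b.append(0.0)
            out_v.append(np.zeros(3))
            k += 1
        bvals.extend(out_b)
        bvecs.extend(out_v)
        Dl.extend([Delta] * len(out_b))
        dl.extend([delta_small] * len(out_b))
    return PGSEProtocol(
        np.array(bvals), np.array(bvecs), np.array(Dl), np.array(dl)
    )
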