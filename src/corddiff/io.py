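"""Standard-format I/O: FSL bval/bvec gradient tables and NIfTI-1 volumes.

The bval file is one row of N b-values (s mm⁻²); the bvec file is three
rows of N components with unit columns for b > 0.  Pulse timings (Δ, δ)
cannot be carried by bval/bvec and live in a JSON sidecar
``{"Delta_ms": [...], "delta_ms": [...], ...}`` next to the table.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .protocol import PGSEProtocol

__all__ = [
    "write_gradient_table",
    "read_gradient_table",
    "write_volume",
    "read_volume",
]


def write_gradient_table(protocol: PGSEProtocol, prefix, extra_sidecar: dict | None = None) -> None:
    """Write ``<prefix>.bval``, ``<prefix>.bvec`` and ``<prefix>.json``."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), protocol.bvals[None, :], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), protocol.bvecs.T, fmt="%.9f")
    sidecar = {
        "Delta_ms": protocol.Delta.tolist(),
        "delta_ms": protocol.delta.tolist(),
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def read_gradient_table(prefix) -> PGSEProtocol:
    """Read an FSL-dialect table (plus JSON timing sidecar) back in."""
    prefix = Path(prefix)
    bvals = np.atleast_2d(np.loadtxt(prefix.with_suffix(".bval")))
    if bvals.shape[0] != 1:
        raise ValueError(f"bval must be a single row, got shape {bvals.shape}")
    bvals = bvals[0]
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise ValueError(f"bvec must be 3 rows, got shape {bvecs.shape}")
    if bvecs.shape[1] != len(bvals):
        n_mismatch = bvecs.shape[1]
        raise ValueError(
            f"bvec has {n_mismatch} columns but bval has {len(bvals)} entries"
        )
    sidecar_path = prefix.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        Delta = np.asarray(sidecar["Delta_ms"], dtype=float)
        delta = np.asarray(sidecar["delta_ms"], dtype=float)
    else:
        Delta = np.full(len(bvals), np.nan)
        delta = np.full(len(bvals), np.nan)
    return PGSEProtocol(bvals, bvecs.T, Delta, delta)


def write_volume(path, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 5.0)) -> None:
    """Write a 3D/4D array as NIfTI-1 (measurement along the 4th axis)."""
    affine = np.diag([*voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_volume(path) -> np.ndarray:
    """Load a NIfTI volume as a float array."""
    return np.asarray(nib.load(str(path)).get_fdata())
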