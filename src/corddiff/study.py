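"""Orchestration of the in-silico compartment study.

One study run repeats, for a number of random seeds, the full chain
substrate packing → walker seeding → random walk → time-dependent D⊥/K⊥,
then aggregates the per-seed metric curves.  Each seed re-instantiates both
the cylinder positions and the walker positions, so the seed spread
captures substrate-realization variability (which dominates the
intra-axonal kurtosis for heavy-tailed radius distributions) as well as
walker sampling noise.

The full-scale profile is 11 seeds × 4·10³ walkers per compartment,
4·10⁴ steps over 75 ms in a 200 μm box; reduced profiles (fewer seeds,
walkers, steps, smaller boxes) are used for routine testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import default_sample_times, run_dynamics, seed_walkers
from .metrics import TimeMetricSeries, aggregate_over_seeds, compute_metrics
from .substrate import make_preset_substrate

__all__ = ["CompartmentStudy", "run_compartment_study"]


@dataclass
class CompartmentStudy:
    intra: TimeMetricSeries | None
    extra: TimeMetricSeries | None
    mean_fvf: float
    mean_awf: float
    preset: str
    density: str
    d_in0: float
    d_ex0: float


def run_compartment_study(
    preset: str,
    density: str,
    n_seeds: int = 11,
    n_intra: int = 4000,
    n_extra: int = 4000,
    n_steps: int = 40000,
    duration: float = 75.0,
    sample_times: np.ndarray | None = None,
    L: float = 200.0,
    d_in0: float = 2.0,
    d_ex0: float = 1.0,
    base_seed: int = 0,
    n_phi: int = 64,
    dialect: str = "printed_moments",
) -> CompartmentStudy:
    """Run the seed-replicated Monte Carlo study for one substrate type.

    Returns seed-aggregated D⊥(t), K⊥(t) per requested compartment (a
    compartment is skipped when its walker count is 0) plus the mean
    achieved volume fractions over the seed substrates.
    """
    if sample_times is None:
        sample_times = default_sample_times(duration)
    per_seed: dict[str, list] = {"intra": [], "extra": []}
    fvfs, awfs = [], []
    for s in range(n_seeds):
        seed = (base_seed * 1000 + s) % (2**31 - 1)
        sub = make_preset_substrate(
            preset, density, seed=seed, L=L, d_in0=d_in0, d_ex0=d_ex0,
            dialect=dialect,
        )
        fvfs.append(sub.fvf)
        awfs.append(sub.awf)
        rng = np.random.default_rng([seed, 17])
        ens = seed_walkers(sub, n_intra, n_extra, rng)
        for series in run_dynamics(
            sub, ens, duration, n_steps, sample_times=sample_times, seed=seed
        ):
            per_seed[series.compartment].append(
                compute_metrics([series], n_phi=n_phi)
            )
    return CompartmentStudy(
        intra=aggregate_over_seeds(per_seed["intra"]) if per_seed["intra"] else None,
        extra=aggregate_over_seeds(per_seed["extra"]) if per_seed["extra"] else None,
        mean_fvf=float(np.mean(fvfs)),
        mean_awf=float(np.mean(awfs)),
        preset=preset,
        density=density,
        d_in0=d_in0,
        d_ex0=d_ex0,
    )
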