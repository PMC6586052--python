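# corddiff

**Diffusion-time dependence in spinal-cord white matter, end to end on
synthetic data.**

Clinical diffusion MRI of the spinal cord probes water displacement over
tens of milliseconds. Whether the popular voxel metrics (DTI/DKI
diffusivities and kurtosis, spherical-mean "microscopic" tensors,
two-compartment model parameters) depend on the chosen diffusion time — and
whether that dependence survives spinal-cord noise levels — matters for
anyone comparing protocols or modelling axon calibre. `corddiff` implements
the complete in-silico machinery for that question:

1. **Substrates** — periodic 2-D cross-sections of impermeable parallel
   cylinders (axons with myelin annuli), gamma-distributed radii, packed to
   a target fibre volume fraction (FVF). With g-ratio g, the MR-visible
   axonal water fraction is `AWF = g²·FVF / (1 + (g²−1)·FVF)`.
2. **Spin dynamics** — Monte Carlo random walks with fixed-length steps
   `ℓ = √(4·D₀·dt)` and specular reflection at membranes; intra-axonal
   walkers confined, extra-axonal walkers in the periodic box.
3. **Time-dependent metrics** — perpendicular diffusivity
   `D⊥(t) = E[Δx²+Δy²]/(4t)` and direction-averaged kurtosis excess
   `K⊥(t) = (1/2π)∫ K[Δx cosφ + Δy sinφ] dφ`, per compartment, with seed
   replication; the tortuosity reference `D_lim = (1−FVF)·D_ex,0`.
4. **Signal synthesis** — cumulant signals
   `S⊥ ∝ exp(−b·D⊥ + b²·D⊥²·K⊥/6)` per compartment, and a Rician-noise
   study of the percentage signal change between diffusion times at SNR 10.
5. **Synthetic voxel study** — a 3-subject, two-ROI cohort of multi-shell,
   multi-Δ PGSE datasets (6×b=0, 20 dirs at b=711 s mm⁻², 40 dirs at
   2855 s mm⁻², Δ ∈ {29, 52, 76} ms, δ = 22 ms) generated from a
   two-compartment stick/zeppelin model with Δ-linear parameter drift,
   written as NIfTI + FSL bval/bvec.
6. **Voxel estimators & statistics** — WLLS DTI (low shell), constrained
   WLLS DKI, spherical-mean microscopic tensor (SMT), Zeppelin-Stick vs
   Zeppelin-Zeppelin maximum likelihood with a voxel-wise likelihood-ratio
   test, and hierarchical dm/dΔ slope estimation with percentage-change
   conversion.

## Worked example

```python
import numpy as np
from corddiff.study import run_compartment_study
from corddiff.signals import build_signal_grid, delta_signal_study

st = run_compartment_study(
    "large_axons", "high", n_seeds=5, n_intra=2000, n_extra=2000,
    n_steps=20000, duration=75.0, sample_times=[25, 30, 75], L=100.0,
    d_in0=2.0, d_ex0=1.0, base_seed=1,
)
print(f"FVF={st.mean_fvf:.3f} AWF={st.mean_awf:.3f}")
i = 1  # t = 30 ms
d, k = st.intra.d_mean[i], st.intra.k_mean[i]
b = 2.5  # 2500 s mm^-2
att = 100 * (1 - np.exp(-b * d + b**2 * d**2 * k / 6))
print(f"D_in(30ms)={d:.3f} um^2/ms  K_in(30ms)={k:.2f}  attenuation={att:.1f}%")
```

prints (seed 1):

```
FVF=0.705 AWF=0.573
D_in(30ms)=0.167 um^2/ms  K_in(30ms)=0.73  attenuation=32.7%
```

i.e. at FVF 0.7 the packed substrate reproduces the closed-form AWF of
0.57, the large-axon intra-axonal space is strongly restricted by 30 ms
(apparent D⊥ ~ 0.19 μm² ms⁻¹, leptokurtic K⊥ > 0 from the radius
distribution), and the intra-axonal perpendicular signal at b = 2500 s mm⁻²
is attenuated by roughly a third of its b = 0 level — large axons are far
from "stick-like" at clinical diffusion times.

A command-line interface mirrors the stages
(`corddiff make-substrate | run-walkers | compute-metrics | synth-signals |
noise-study | gen-voxels | fit-maps | compare-models | timedep-stats`);
run `corddiff --help`.

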