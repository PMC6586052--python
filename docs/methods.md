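# Methods

## Scope and model

`corddiff` studies how restricted water diffusion perpendicular to axons
produces diffusion-time dependence in spinal-cord white-matter MRI, and
whether that dependence is measurable with a clinically feasible protocol.
Everything runs on synthetic data; the package contains both the generator
(substrates, random walks, voxel datasets) and the analysis (metrics,
signals, estimators, statistics).

### Substrates

White matter is a periodic box `[0, L)²` of impermeable parallel cylinders.
Each myelinated axon is two concentric circles: inner radius `r_in = g·r_out`
with g-ratio `g = 0.75`. Outer/inner radii follow gamma laws; two calibres
are built in:

| preset | inner law (a, b) | E[R_in] | density presets |
|---|---|---|---|
| `large_axons` | (3.11, 0.86 μm) | 2.66 μm | FVF 0.7 ("high"), 0.4 ("low") |
| `small_axons` | (5.69, 0.17 μm) | 0.97 μm | same |

Two parametrisations of the large-axon law circulate that are mutually
inconsistent at the percent level; the default dialect
(`printed_moments`) samples the **inner** law above and scales by `1/g`,
which reproduces the quoted outer mean/variance (3.51 μm, 4.07 μm²) to ~1%.
The alternative `printed_ab` samples the outer law (3.01, 1.63 μm)
directly. Radii below `r_min = 0.1 μm` are rejected and resampled so no
pore is smaller than a few walker steps.

Packing selects radii in sampling order (preserving the size distribution)
until the target FVF ± 0.02 is reached, then places them largest-first:
random sequential addition while it succeeds, then random placement of the
remainder followed by pairwise overlap-repulsion relaxation under the
periodic minimum image. FVF 0.7 exceeds the RSA jamming density, hence the
relaxation stage. **Clearance:** packing runs on radii inflated by 4%, so
neighbouring walls never touch. This is deliberate: in a 2-D cross-section,
tangent disks seal the extra-cellular space into closed pockets and drive
its long-time diffusivity to zero, whereas real fibre bundles keep sheaths
separated by extra-cellular matrix and the observed long-time `D_ex,⊥`
stays *above* the tortuosity reference `(1−FVF)·D_ex,0`. A few percent of
wall-to-wall gap is the smallest intervention that keeps every throat open;
the achieved FVF is computed from the true radii and is unaffected.

A 200 μm box at FVF 0.7 yields ≈565 large-axon or ≈4400 small-axon
cylinders; cylinder counts are stochastic outcomes, the FVF tolerance is
the contract.

### Spin dynamics

Walkers take fixed-length, uniformly oriented 2-D steps `ℓ = √(4·D₀·dt)`
(Camino-style), with specular reflection at every membrane crossing,
possibly multiple per step; the z-component is decoupled for straight
parallel cylinders and is not simulated. Myelin is MR-invisible: nothing is
seeded there and both faces reflect, so compartments never exchange.
Intra-axonal walkers are seeded area-weighted across inner disks and each
interacts only with its own cylinder; extra-axonal walkers move through the
periodic box (cell-list neighbour search, displacement unwrapping).
Intrinsic diffusivities default to `D_in,0 = 2`, `D_ex,0 = 1 μm² ms⁻¹`
(the "fast intra-axonal water" scenario); both are parameters.

Fixed-length stepping preserves the uniform equilibrium density (verified
by a χ² test on an equal-area radial histogram after ~10⁶ reflective
steps) and converges to Brownian statistics well below the default
4·10⁴ steps per 75 ms. If `ℓ` exceeds half the smallest inner radius a
warning is raised.

### Time-dependent metrics

Per compartment and seed: `D⊥(t) = E[Δx² + Δy²]/(4t)` and the
direction-averaged kurtosis excess of the projected displacement,
`K⊥(t) = (1/2π)∫ K[Δx cosφ + Δy sinφ] dφ`, evaluated on a uniform φ-grid
(`n_phi = 64`; for a smooth 2π-periodic integrand the trapezoid rule on a
periodic grid is spectrally accurate, and reduces to the plain grid mean).
The kurtosis estimator is the population moment ratio `m₄/m₂² − 3` with no
small-sample correction — at ≥10³ walkers its bias is negligible against
the seed-to-seed spread. Long-time values are reported as the mean over the
last three sample points (no extrapolation). Oracles: free diffusion gives
`D⊥ = D₀`; a single cylinder gives `E[Δx²+Δy²] → r²` and `K⊥ → −0.5`
(difference of two uniform disk points has projected `m₄/m₂² = 2.5`); an
equal-weight Gaussian mixture with variances 1 and 9 gives `K⊥ = 1.92`.

A realisation note: the long-time intra-axonal `K⊥` of a gamma radius
mixture is dominated by the few largest axons (it involves sixth moments of
the radius law), so single-substrate values scatter widely (± ~0.5 across
seeds for large axons). All headline quantities therefore average the
cumulants over seed-replicated substrates, each seed re-instantiating both
cylinders and walkers — this is also why the study design replicates seeds
in the first place.

### Signals and the noise study

Compartment signals use the second-order cumulant form
`S⊥(t,b) = f · exp(−b·D⊥(t) + b²·D⊥²(t)·K⊥(t)/6)` with `f = AWF` (intra)
or `1 − AWF` (extra), built from **seed-averaged** cumulants, so
`S_tot(t,0) = 1`. b-values are converted internally to ms μm⁻²
(1000 s mm⁻² = 1 ms μm⁻²). Whenever the quartic term exceeds the Gaussian
term the expansion is flagged, never silently returned.

The detectability study corrupts `S_tot(t,b)` and `S_tot(t_ref,b)`
(`t_ref = 25 ms`, the shortest clinically plausible diffusion time)
independently 500 times with Rician noise at σ = 1/SNR (SNR 10 at b = 0)
and summarises `ΔS = 100·(S̃(t) − S̃(t_ref))/S̃(t_ref)`. Two intervals are
reported deliberately: the 2.5–97.5 percentile band of the noise draws
(what a single voxel can show — it crosses zero even when the true change
is large) and an order-statistic 95% CI of the median (whether the change
is detectable *on average*). Under the default conditions the large-axon
substrates give a median increase of ~20–25% at t = 75 ms, b = 2500 s mm⁻²
with a median CI excluding zero, while the small-axon change is a few
percent with a per-draw band straddling zero.

### Synthetic voxel cohort

The voxel generator emulates the *statistical structure* of a small
cervical-cord cohort, not its anatomy: 3 subjects; an 8×8×4 voxel grid
whose central block is split into "motor" and "sensory" ROI labels with
pure-noise background; per-voxel two-compartment axially-symmetric truths
(`v_s ~ U(0.3, 0.7)`, `D_s,∥ ~ U(1.5, 2.5)`, `D_z,∥ ≤ D_s,∥`,
`D_z,⊥ ≤ D_z,∥`, stick `D_s,⊥ = 0` by default, fibre directions within ~5°
of the slice normal); Δ-linear parameter drift injected per ROI (defaults:
negative diffusivity slopes, e.g. −2.88·10⁻³ μm² ms⁻² on `D_z,⊥`); Rician
noise at SNR 10. The protocol matches the emulated acquisition: per
Δ ∈ {29, 52, 76} ms, 6 interleaved b = 0, 20 directions at 711 s mm⁻² and
40 at 2855 s mm⁻², δ = 22 ms; directions from an electrostatic-repulsion
optimiser with antipodal symmetry. Δ itself (not the effective time
Δ − δ/3) is the regressor downstream; the mapping is provided for
reporting. What the generator does **not** emulate: orientation dispersion
(optional, off by default), intra-compartment kurtosis, T2/TE effects,
motion, partial volume — so passing tests demonstrate estimator
correctness under the stated model, not robustness to real-cord confounds.

Noise handling mirrors a clinical pipeline: σ is estimated per subject by
the method of moments on pooled b = 0 repeats (`E[M²] = S² + 2σ²`,
`E[M⁴] = S⁴ + 8σ²S² + 8σ⁴` ⇒ `σ̂² = (μ̂₂ − √(2μ̂₂² − μ̂₄))/2`), SNR as
`mean(b0)/σ̂`, and magnitudes are corrected as `ŝ = √(max(m² − 2σ̂², 0))`
before model fitting. Pooling matters: a per-voxel σ̂ from 6 repeats is so
noisy that it visibly inflates the likelihood-ratio test's false-positive
rate, while the pooled estimate restores the expected conservative
behaviour.

### Voxel estimators

*DTI* uses b = 0 and the low shell only (departures from Gaussianity grow
with b): WLLS on the log-signal (OLS pass, then one reweighting by squared
predicted signals). *DKI* uses all shells with the linear model
`ln S = ln S₀ − b·D(g) + (b²/6)·V(g)`, `V(g) = MD²·W(g)` (15 components);
after the unconstrained WLLS pass the directional apparent kurtosis
`K(g) = V(g)/D(g)²` over the measured directions is constrained to
`[0, 3/(b_max·D(g))]` via an SLSQP quadratic re-solve when violated (the
constraint dialect is a recorded choice; the bound form follows common
constrained-DKI practice). Axial kurtosis is `K` along the principal
eigenvector; radial kurtosis is the mean over a 32-point orthogonal ring.
*SMT* fits the axisymmetric spherical-mean kernel
`ε(b) = exp(−bλ⊥)·√π·erf(√(bΔλ))/(2√(bΔλ))` to per-shell direction
averages (grid init, bounded local refinement, series continuation at
`Δλ → 0`), recovering the microscopic tensor independent of orientation.

### Two-compartment models and the LRT

Zeppelin-Stick and Zeppelin-Zeppelin share the forward model

    S = S₀·(v_s·e^{−b(D_s,⊥+(D_s,∥−D_s,⊥)(g·n)²)} + (1−v_s)·e^{−b(D_z,⊥+(D_z,∥−D_z,⊥)(g·n)²)})

with ordering `0 ≤ D_s,⊥ ≤ D_z,⊥ ≤ D_z,∥ ≤ D_s,∥ ≤ 3.2 μm² ms⁻¹` (fast
intra-axonal water) and `D_s,⊥ = 0` for ZepStick. The fibre direction is
fixed from the DTI principal eigenvector; fitting is per-Δ-block, two-stage
(ordered coarse grid, then L-BFGS-B under a smooth reparametrisation:
logit for `v_s`, nested sigmoid ratios for the diffusivities; S₀ profiled
out analytically under the Gaussian likelihood). The default likelihood is
Gaussian on bias-corrected magnitudes with σ profiled (fitting a per-voxel
fixed σ̂ from few repeats destabilises the LRT); a Rician likelihood with
explicit σ is available. ZepZep is warm-started from the embedded ZepStick
solution, guaranteeing nesting monotonicity up to optimiser tolerance. The
LRT statistic `2(ℓ₁−ℓ₀)` (clamped at 0) is referred to χ²₁ with α = 0.05;
since the null pins `D_s,⊥` to a boundary this is conservative (measured
type-I error ~1–2% at SNR 10), and the 50:50 χ²₀/χ²₁ mixture is available
behind a flag, off by default.

### Slope statistics

Long-format voxel metrics are regressed on Δ. Default `two_stage`
estimator: per-voxel OLS slopes, pooled as the grand mean with a
t-interval over subject means (3 subjects ⇒ t₂) — closed-form, exactly
calibrated under the null when subject means are exchangeable.
`mixed_ml` fits the three-level random-intercept/random-slope model
(subject level) with a voxel variance component by ML via statsmodels.
Slopes convert to percentages as `100·(dm/dΔ·47 ms)/baseline` with the
baseline taken as the ROI-wise median of the Δ = 29 ms map. The in-vivo
coefficient tables that motivate the default drift magnitudes are
real-data quantities; here they serve as injected truths and sign/magnitude
plausibility references only.

## Problem sizes

The library defaults mirror the full-scale study (200 μm boxes, 11 seeds ×
4·10³ walkers per compartment, 4·10⁴ steps over 75 ms); reproducing the
full diffusivity/kurtosis/signal curves at that scale is supported but
takes hours on one CPU. The test suite and the acceptance script use
reduced profiles chosen so every targeted quantity is statistically stable
at a few minutes' total runtime: single-cylinder kurtosis with 1.2–2·10⁴
walkers × 10⁴ steps; the large-axon attenuation with 5–6 substrate seeds ×
2.2–2.5·10³ intra-axonal walkers (≥10⁴ walkers total) in the full 200 μm
box; compartment studies for the tortuosity and noise checks with 3 seeds ×
1.5·10³ walkers per compartment, 2·10⁴ steps, in 50–100 μm boxes (still
≥150 cylinders, so finite-box effects stay below the seed spread).

## Known limitations

- 2-D geometry: no undulation, beading, dispersion, or permeable membranes;
  no parallel-direction restriction (axial time-dependence seen in vivo is
  outside the model).
- The cumulant signal form degrades at `b²D²K/6 ≳ bD`; flagged, not fixed.
- The packing clearance (4%) is a modelling choice, not a measured
  quantity; extra-cellular long-time diffusivity depends on it.
- NODDI and two-compartment SMT metrics appearing in the in-vivo tables are
  produced by external toolboxes and are not implemented; their names
  appear only in documentation.
- The LRT's χ²₁ reference is deliberately conservative at the boundary
  null; power figures should be read accordingly.
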