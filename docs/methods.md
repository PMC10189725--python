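# Methods

## Model

A drying droplet of a suspension-concentrate formulation is modelled as a
uniform saturated disk of radius `r_dep` in permanent contact with a
homogeneous cuticle slab of thickness `z_max`. Within the slab the dissolved
active ingredient obeys Fick's second law; every boundary except the contact
disk is zero-flux. The saturated-disk condition rests on two observations
built into the deposit arithmetic: the aqueous diffusion zones of
neighbouring deposited particles overlap within seconds
(`t = x_sep²/D_aq ≈ 3 s` for 17 µm spacing), making the concentration under
the footprint uniform, and the coffee-ring rim (≈90% of the deposited mass)
acts as a reservoir that sustains saturation after dry-down. The zero-flux
("wax reservoir") condition encodes the lipophilicity of the compound: no
escape to air, no partitioning into the aqueous sub-cuticle. Both boundary
conditions are held for all times; no boundary switching is implemented.

Nondimensionalising lengths by `r_dep`, time by `t_ref = r_dep²/D_cut` and
mass by `m_ref = c_sat_cut·r_dep³` leaves a single parameter, the relative
thickness `Z_max = z_max/r_dep`. Concentrations are carried in ppm read as
mass per volume (g m⁻³ ≡ mg L⁻¹), consistent with a cuticle density near
1 g cm⁻³; this convention is what makes `m_ref` dimensional.

Four closed forms bound the solution and are reconstructed from the standard
chronoamperometric literature (the disk problem is mathematically identical
to diffusion-limited current at a microdisk electrode):

* **Cottrell**: `dM/dT = A_d/√(πT)`, `A_d = π` — planar diffusion, the
  universal short-time limit.
* **Shoup–Szabo**: `dM/dT = 4·[0.7854 + 0.8862 τ^-1/2 + 0.2146
  exp(-0.7823 τ^-1/2)]` with `τ = 4T` — disk into a half space; the
  thick-cuticle envelope, tending to the steady-state disk rate 4.
* **Crank plane sheet**: flux density at the saturated face of a slab with
  an impermeable back, as two co-convergent series (theta series for
  `T < Z_max²`, eigenmode series for `T > Z_max²`; ties go to the first).
  Truncation: next term below 1e-12 of the partial sum, 10 000-term cap.
* **Cylinder**: `dM/dT = A_c·φ(T)`, `A_c = 2πZ_max`, with `φ` the uniformly
  valid short/long-time approximation for the flux density from a saturated
  unit cylinder, `φ = 2e^{-0.05√(πτ)}/√(πτ) + 1/ln(5.2945 + 0.7493√τ)`,
  `τ = 4T`. After longitudinal saturation the rim is the only remaining
  uptake route, and the thin slab seen from the rim is exactly the exterior-
  of-cylinder problem.

Because the source equations could not be transcribed directly, each
reconstruction is validated in the test suite against an independent
numerical oracle: the 2D simulator at `Z_max = 10` for Shoup–Szabo (≤1%
over `T ∈ [1e-4, 1e2]`), the 1D plane-sheet solver for Crank (≤0.5%), and a
1D radial exterior-diffusion solver for the cylinder form (≤2% over
`T ∈ [1e-3, 1e3]`). The time variable is the deposit scaling `T` everywhere;
literature forms using `τ = 4Dt/a²` are converted internally.

**Composite thin-cuticle curve.** For `Z_max ≤ 0.05` the full curve can be
estimated without simulation. The pointwise maximum of the Crank and
cylinder rates undershoots the simulator by up to 50% in the crossover
window `T ~ 2–3 Z_max²`, because there the longitudinal (under-disk) and
radial (rim) channels *both* carry flux. Their sum is used instead: it
reduces to each limit where the other vanishes, overestimates at short
times only by the relative rim share ~`2 Z_max` (<10% inside the validity
bound), and tracks the simulator within 3.9% everywhere at `Z_max = 0.01`.

**Pathway criterion.** `G = (D_cut·c_sat_cut)/(D_aq·c_sat_aq)` compares the
transport capacity of the direct (particle-contact) and indirect
(dissolution + aqueous diffusion) routes; `G < 1` labels indirect dominance.
This product-ratio form matches the symbols the criterion is stated with,
but the original derivation was not available for transcription; the
function's docstring flags that it should be re-verified before quantitative
use.

## Numerical method

Vertex-centred finite volumes on a tensor-product `(R, Z)` grid, marched
with backward Euler (all double precision). Design choices that matter:

* **Deficit formulation.** The solver evolves `u = 1 - C`. The uptake rate
  is then the discrete boundary influx `Σ g_e u_e` over disk-adjacent edges
  — free of floating-point cancellation even when the rate has decayed ten
  orders of magnitude, which a `ΔM/ΔT` estimate is not. The discrete
  identity `Σ V(1-u) = ∫flux dT` holds to solver precision and is checked
  every run (hard failure above 1%); an independent centred-difference
  `dM/dT` estimate must agree with the flux wherever the rate is significant.
* **Mass accounting.** `M(T)` is the cumulative influx plus the control
  volume of the saturated Dirichlet surface cells. Counting those cells as
  saturated from the start matches the continuum (their charging time is
  `O(dz²)`) and makes `M` second-order accurate; omitting them leaves an
  `O(dz)` deficit that dominates grid-convergence error.
* **Grid.** Radial spacing `h_min = min(Z_max/4, 1e-3)` at the edge
  singularity `(R=1, Z=0)`, expanding geometrically (factor 1.12) toward the
  axis and the outer boundary `R_max = 1 + 6√T_max` (zero-flux; the front
  cannot reach it). Z layers are uniform (`n_z = 24` default) when that
  resolves the first output's diffusion length `√T_min/8`, otherwise graded
  geometrically from the surface — a uniform grid at large `Z_max` would
  need thousands of layers. The node at exactly `(R=1, Z=0)` is saturated.
* **Time stepping.** Log-spaced schedule (default 40 steps/decade) starting
  two decades before the first output time so the impulsive start has
  healed. A second march with halved steps and safeguarded pointwise
  extrapolation (Richardson; on by default) removes the leading `O(dT)`
  error. The plane-sheet mode additionally caps the step at `1e-4·Z_max²`:
  resolving the exponential saturation decay to ~0.3% requires `λ·dT` small
  against the slowest eigenmode `λ = π²/(4Z_max²)`, which a purely
  geometric schedule violates.
* **Linear solver.** Sparse LU with one iterative-refinement pass (default)
  or ILU-preconditioned BiCGSTAB. The residual contract (1e-10) is enforced
  as the normwise backward error `‖r‖/(‖A‖‖x‖+‖b‖)`; the naive `‖r‖/‖b‖`
  is unattainable at large `dT` because evaluating the residual itself
  rounds at `‖A‖‖x‖·ε`.

Problem sizes: the oracle comparisons run on 2 000–8 000 unknowns and a few
hundred to ~1e5 (1D, capped) time steps; each completes in seconds to tens
of seconds on one CPU. Grid convergence (doubling `n_z`, halving `h_min`)
moves the final mass by well under 0.5%.

## Parameter inference

`fit_uptake` minimises `Σ w_i (mass_TL_i − n·m_ref·M(t_i/t_ref))²` over
`(log t_ref, log m_ref)` with scipy's trust-region-reflective bounded least
squares. The master curve enters only through log-log interpolation (end
slopes extrapolated, which is exact in the Cottrell regime), so it is
simulated once per `Z_max` and purely rescaled during optimisation — the
model is self-similar in the two scales. Initialisation is a 60-point grid
search over `log t_ref` with the closed-form optimal `m_ref` at each
candidate; convergence onto a search bound is an error, and data spanning
less than a decade in time triggers a warning. Residuals are unweighted by
default (per-point weights optional). Standard errors come from the
linearised covariance `s²(JᵀJ)⁻¹` in log-parameter space; confidence
intervals are formed on the log scale (respecting positivity) and mapped
back. `D_cut = r_dep²/t_ref` and `c_sat_cut = m_ref/r_dep³` inherit the
relative standard errors. The fitted mass is the leaf-extract compartment
summed over the droplet array; droplets ≥3 mm apart are treated as
diffusionally independent, so array mass is `n` times one deposit.

## Synthetic data

The generator emulates the destructive-sampling droplet-array design used
to calibrate the model: each record is an independent leaf carrying 20
droplets of 0.2 µL at 375 ppm (1.5 µg applied), sampled once; two recovered
compartments (surface wash LW, leaf extract TL) close to the applied dose
in expectation; 2 batches × 3 replicates per time point; sample times dense
in the first hour and sparse to 24 h, mirroring the fast-then-slow uptake
shape. Noise is multiplicative lognormal with unit mean and CV 0.10 by
default, applied independently per compartment — a noise model chosen to
approximate replicate scatter, since only standard errors were reported.
One integer seed fixes the output bit for bit.

What the generator does **not** emulate — and hence what passing tests do
not establish about laboratory data: droplet evaporation hydrodynamics and
the coffee-ring flow field; timing uncertainty at short exposure times;
between-leaf or between-variety biological variability; recovery losses in
the extraction chemistry; any departure of real noise from lognormal
multiplicativity. Parameter-recovery results (noiseless recovery to <1%,
95%-CI coverage ≥90/100 at 10% noise, median `|ΔD_cut|/D_cut ≈ 6%`)
quantify the inference machinery under the stated noise model, not assay
accuracy in the field. Likewise, the published-operating-point check uses a
synthetic stand-in generated at the published parameters because the
original raw assay tables are not redistributable.

## Known limitations

* Constant contact radius and a permanently saturated disk: systems where
  dry-down precedes longitudinal saturation with sparse interior deposits
  and no sustaining film would need a time-dependent boundary.
* The cuticle is a homogeneous slab: cuticular pegs (locally deeper
  cuticle between epidermal cells) add uptake volume that the model folds
  into an effective `c_sat_cut`, biasing it high.
* `K_cw` and the `G` criterion need the aqueous solubility `c_sat_aq`,
  which the package treats strictly as user input.
* The cylinder closed form is one published approximation contract-checked
  at the 2% level, not a series solution; inside that band any equivalent
  approximation is interchangeable.
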