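# Methods

`dtjsub` reconstructs the scalar scale parameter η linking a tissue's
anisotropic electrical conductivity tensor to its water diffusion tensor,

    C(r) = η(r) · D(r),

from a single injected-current MREIT measurement: the z-component Bz of the
magnetic flux density induced by a weak (tDCS-level, 1–2 mA) current, plus a
DTI-derived diffusion tensor field.  The model rests on the two-phase
effective-medium result that conductivity and water diffusion share
eigenvectors, with η absorbing the extracellular ion concentration and
mobility; `sen_torquato_eigenvalues` implements the underlying eigenvalue
relation, whose small-intracellular-diffusivity limit is the linear law
above.

## Units

Diffusivities are stored in mm²/s, η in S·s/mm³, so conductivity in SI is
`C[S/m] = 1e3 · η · D`.  With white-matter diffusivities (λ = (1.7, 0.3,
0.3)·10⁻³ mm²/s) and η ≈ 0.5–1, mean conductivities land in the 0.4–1.6 S/m
range typical of brain tissue, which is why η values of order one are the
natural working scale.  Grid spacings are mm; all PDE and Biot-Savart
arithmetic converts to meters internally.  Bz is in Tesla (nT-range values
for 2 mA injections), currents in A, current densities in A/m².

## Forward model

The conduction problem ∇·(C∇u) = 0 with prescribed outward normal current
density g on the boundary (uniform over each electrode patch, total signed
flux zero) is discretized by cell-centered finite volumes on the regular
grid.  The face-normal tensor coefficient is harmonically averaged (exact
for 1-D piecewise-constant profiles, robust across discontinuities); the
cross-term coefficient is arithmetically averaged and multiplied by the
face-averaged tangential derivative, giving a compact multi-point flux
stencil that conserves flux exactly.  The singular Neumann system is solved
with a gauge-augmented sparse LU factorization plus iterative refinement
(unknown counts at desk scale are ≤ a few 10⁴, where a direct solve is both
faster and more reliable than an iterative one); the relative residual is
checked against a 10⁻¹⁰ default tolerance and the zero-mean gauge is applied
afterwards.  An incompatible montage (non-conserved flux) is rejected before
the solve.

Currents are carried in two representations: exactly conservative face
fluxes (the solver stencil's own fluxes, whose per-cell divergence vanishes
to solver tolerance) and cell-centered components J = −C∇u using masked
central differences.  The cell-centered form is what the Ohm's-law update
consumes — with it, the true η is an exact fixed point of the update; the
face-flux form is what conservation checks and cross-representation current
comparisons use (`face_averaged_components`).

## Bz synthesis and the z-invariant regime

Bz at the slab mid-plane is the Biot-Savart integral of the in-plane current,
with the z-integral over the slab thickness carried out analytically and the
in-plane integral over each source voxel by 3×3 midpoint subsampling.  Inside
a z-invariant current distribution the in-plane Laplacian of Bz equals
μ0(∂Jx/∂y − ∂Jy/∂x); this identity — checked by
`bz_laplacian_consistency` — is what makes the projected-current recovery
exact in 2-D, and it holds only when the slab is long compared to the field
of view.  The packaged validation studies therefore use a slab 10× the
in-plane extent (1600 mm for a 160 mm field of view), i.e. the long-cylinder
regime the 2-D theory assumes.  A thin slab (the scanner's 5 mm slice) can be
simulated by passing `slab_thickness_mm`, but then Bz is a nonlocal functional
of the current and the 2-D recovery degrades — that is a physical property of
the thin-slice geometry, not an implementation artifact.

Bz can be sampled at voxel centers or at cell corners ("nodes", the dual
grid).  The stream-function solve is node-based, so the pipeline reconstructs
Bz on the node grid: with co-registered samples the projected current is
recovered to a few tenths of a percent, whereas resampling cell-centered Bz
to nodes costs accuracy at the domain boundary where the field kinks.  The
MR phase encoding is sampling-agnostic (it maps any Bz array through the
complex signal model and back).

## MR measurement model

Each echo acquires S^l = S·exp(iγ TE_l Bz) plus i.i.d. circular complex
Gaussian noise; the reference S⁰ has no current-induced phase.  Bz per echo
is atan2 of the phase-difference product divided by γTE_l; zero-magnitude
voxels are masked.  tDCS-level fields are a few nT, far below the wrap
limit at multi-gradient-echo times, so no unwrapping is attempted and a wrap
is a hard error naming the offending voxel.  Echoes are combined with
per-voxel inverse-variance weights w_l ∝ (TE_l·|S^l|)², the minimum-variance
convex combination under the per-echo phase-noise model (the combination
rule's published details live in an inaccessible reference; inverse-variance
weighting is the standard stand-in and satisfies the intended optimality in
Monte-Carlo checks).  The noise level of the combined Bz follows
sd ∝ 1/(T_c·|S^c|), exposed as `noise_sd_model` for choosing simulation
noise levels.

## DWI model and tensor fit

Single-shell signals ρ_j = ρ₀·exp(−b·g_jᵀDg_j) with
b = γ²δ²G²(Δ−δ/3) (SI, converted to s/mm²), Rician noise.  The tensor is
fitted per voxel by ordinary least squares on ln(ρ_j/ρ₀) — the minimal
estimator the mono-exponential model admits — then projected to SPD by
flooring eigenvalues at 10⁻⁶ of the largest (downstream steps invert D).
Direction generators: the classic 6-direction dual-axis scheme and a seeded
electrostatic-repulsion scheme for N directions (default 32 at
b = 800 s/mm², the regime where the measured ADC is dominated by fast,
predominantly extracellular diffusion).

## Projected current density

From the homogeneous reference solve (J⁰, Bz⁰; J⁰ is independent of the
reference conductivity because the Neumann data fix the current), the
recoverable part of the true current is Jᵖ = J⁰ + ∇̃⊥ψ, where ψ solves the
2-D Poisson problem ∇̃²ψ = ∇²(Bz−Bz⁰)/μ0 with ψ = 0 on the boundary.
Subtracting Bz⁰ removes the harmonic background (the printed form with ∇²Bz
alone differs only by a harmonic part absorbed by the boundary condition)
and cancels the discretization error shared by the two Biot-Savart
syntheses.  ψ lives on grid nodes; the correction's face fluxes are pure
node differences, so Jᵖ is exactly conservative and carries exactly the
electrode boundary flux.  For noisy data a Gaussian pre-smoothing of the Bz
difference (default off; 1 voxel recommended at realistic noise) regularizes
the double differentiation.  When the true current is in-plane and
z-invariant and Bz is noise-free, Jᵖ reproduces J to < 1% in L2 on 64²
grids — the identifiable content of a single Bz component.

## Scale-parameter reconstruction

The iteration alternates the forward solve with conductivity ηⁿD and the
neighborhood-weighted Ohm's-law update

    ηⁿ⁺¹ = − ⟨J⟩·⟨∇uⁿ⟩ / ( ⟨D∇uⁿ⟩·⟨∇uⁿ⟩ ),

with similarity weights w_i ∝ exp(−h·|S(r_i)−S(r)|) over an N×N in-plane
search window built from the MR magnitude image.  The printed update mixes
the center-voxel gradient into the numerator; the implementation defaults to
the weighted-average form in both numerator and denominator, which makes the
true η an exact fixed point (the literal center-gradient variant is
available via `center_gradient=True`).  Defaults follow the in-vivo
protocol for noisy data (5×5 window, h = 0.1, two passes —
`RunConfig.animal_study_preset()`); the zero-noise validation studies use a
singleton window, since the neighborhood averaging exists to suppress noise
and only blurs interfaces when there is none.

Voxels whose update denominator falls below 10⁻⁶ of its in-mask median are
masked and filled from the nearest valid voxel; η is clipped to
[10⁻³, 10³]×anchor.  Stopping: n_max (default 10) or mean relative change
< 10⁻³.

Three structural properties are enforced by tests rather than assumed:

* **Fixed point.** With the true potential and the consistent current, the
  singleton update returns η exactly (machine precision).
* **Scale ambiguity.** The data determine η only up to a global factor
  (scaling η scales u inversely and leaves J unchanged), so every iterate is
  exactly proportional to the initialization's scale.  The anchor is the
  assumed background conductivity σ₀: η⁰ = σ₀ / (1e3·mean trace(D)/3).
  Reported η values are relative to this anchor.
* **Energy identity.**  The convergence argument rests on the identity
  ∫(ηⁿ⁺¹−η)(1+ηⁿ⁺¹/η)(D∇uⁿ)·∇uⁿ = ∫(ηⁿ−η)(D∇uⁿ)·(∇uⁿ+∇u), valid when the
  update matches the current as a vector (−ηⁿ⁺¹D∇uⁿ = J).
  `convergence_identity` checks the discrete two sides with ηⁿ⁺¹ entering
  through that defining relation ((ηⁿ⁺¹)²(D∇uⁿ)·∇uⁿ = J·D⁻¹J); what remains
  to be verified discretely is the integration-by-parts step, i.e. the
  conservation structure of the two forward solves, and it holds to well
  under 2% on every iterate of the noise-free runs.  The projection update
  itself satisfies the vector condition only up to the misalignment angle
  between D∇uⁿ and J, which is what the companion angle map diagnoses.

**Convergence behavior worth knowing.**  The update corrects η through the
component of the current transversal to ∇uⁿ.  Consequences, all visible in
the tests: conductivity variation purely along the current path is invisible
to a single injection (the normal current is continuous across such
profiles — the reason the isotropic single-current problem is
under-determined); a resistive inclusion contracts quickly (error ≈ (1/3)ⁿ in
the cylindrical model) while a conductive one converges several times more
slowly; and fibers aligned with the current make the anisotropy itself
irrelevant to the data.  The packaged study conditions are chosen inside the
identifiable regime: a transverse full-edge montage (complete current
coverage), a 2:1 *resistive* inclusion, and fiber orientations transversal
to the injection in the seeded comparison family.  With those conditions the
full chain recovers η to < 5% relative RMSE on sensitivity-masked voxels
(above the 10th percentile of |⟨J⟩·⟨∇uⁿ⟩|) within 5 iterations at zero
noise.

## Companions

* **Two-current direct method.**  With an assistant injection, the curl-free
  condition on −η∇u = D⁻¹Jᵖ gives a per-voxel 2×2 system for ∇ln η̃, solved
  where the two transformed currents are transversal (determinant above
  10⁻³ of the median magnitude scale; near-parallel currents on most of the
  domain raise a rank-deficiency error) and integrated globally by
  least squares (LSQR on the masked gradient operator), anchored by its
  mean.  On a smooth exponential η̃ phantom the recovery is ~1% of the
  ln-range.
* **Isotropic J-substitution baseline.**  The same loop with D = I.  On
  anisotropic phantoms its Ohm's-law residual stagnates above the
  tensor variant's — the quantitative expression of the interface-mismatch
  argument (the normal component of Jᵖ is continuous across an η interface
  while that of D⁻¹Jᵖ jumps).
* **Angle map.**  α = arccos[(D∇uⁿ)·∇u / (‖D∇uⁿ‖‖∇u‖)] in degrees, masked
  where either vector vanishes; large angles mark voxels where the update is
  poorly determined, and reconstruction error concentrates at low
  |⟨J⟩·⟨∇uⁿ⟩|.

## Synthetic phantoms

The generator produces smooth fiber fields (parallel bundles or concentric
arcs; prolate white-matter-like eigenvalues (1.7, 0.3, 0.3)·10⁻³ mm²/s,
FA ≈ 0.7, by default, with optional seeded angular jitter) and η maps that
are piecewise constant (background plus disk inclusions), optionally with a
Gaussian partial-volume blur at inclusion edges (`edge_smooth`, in voxels)
mimicking how MRI-derived parameter maps actually look, or smooth
exponentials for the two-current studies.  Everything is deterministic given
(spec, seed).  What the phantoms do not emulate: realistic head anatomy and
compartments, electrode-skin contact impedance, EPI distortions and k-space
effects, multi-compartment or non-Gaussian diffusion, genuinely 3-D current
paths.  Passing tests therefore demonstrate the correctness and internal
consistency of the algorithm chain in its identifiable 2-D regime, not
in-vivo accuracy.

## Problem sizes and numerical defaults

The validation studies run on 64×64 grids (160 mm field of view, 2.5 mm
voxels), one disk inclusion, 2 mA injection — sizes at which every stage
solves in well under a second and the whole chain in ~2 s, so the complete
study family (ten seeded phantoms plus Monte-Carlo noise sweeps) remains a
desk-scale computation.  Solver tolerance 10⁻¹⁰ (relative residual);
Biot-Savart quadrature 3×3 subsamples; stream-function solve node-based with
zero Dirichlet data; eigenvalue floor 10⁻⁶ relative; all Monte-Carlo loops
and generators take explicit seeds.

## Known limitations

* Single-slice 2-D model only; the optional thin-slab Bz synthesis exists
  but the recovery theory (and accuracy) belongs to the long-slab regime.
* The global η scale is anchored, not measured (inherent to one injection).
* Reconstruction quality degrades where the current misses the domain or the
  fibers align with it; the sensitivity and angle maps flag those regions
  but do not repair them.
* The energy-identity check validates the conservation structure of the
  implementation, not convergence of the projection update from arbitrary
  starts, which the method does not guarantee.
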