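# dtjsub — anisotropic conductivity tensor imaging from tDCS currents

Weak direct currents (1–2 mA) injected through surface electrodes, as in
transcranial direct current stimulation (tDCS), induce a magnetic flux
density inside the head whose z-component **Bz** an MRI scanner can measure
(MREIT).  `dtjsub` reconstructs the tissue's **anisotropic electrical
conductivity tensor** from a *single* such injection by coupling it to
diffusion-tensor MRI: conductivity and water diffusion share eigenvectors in
a two-phase medium, so

&nbsp;&nbsp;&nbsp;&nbsp;**C**(r) = η(r) · **D**(r),

with **D** the water diffusion tensor and η a positive scalar field (the
*scale parameter*, physically tied to the extracellular ion concentration).
The package implements the diffusion-tensor J-substitution algorithm that
recovers η, together with the complete simulation chain needed to generate
its inputs and validate it at desk scale:

* voxel grids, electrode montages, and seeded synthetic phantoms
  (fiber-like **D** fields, η maps);
* an anisotropic finite-volume Neumann solver for ∇·(η**D**∇u) = 0 and its
  conservative current density **J** = −η**D**∇u;
* Biot-Savart synthesis of Bz and multi-echo MR phase encoding/decoding
  (Bz^l = atan2(α^l, β^l)/(γ TE_l), inverse-variance echo combination,
  sd(Bz) ∝ 1/(T_c|S^c|) noise law);
* DWI simulation and log-linear tensor fitting
  (ρ_j = ρ₀e^{−b g_jᵀDg_j}, b = γ²δ²G²(Δ−δ/3));
* projected current density **J**ᵖ = **J**⁰ + ∇̃⊥ψ from measured Bz via the
  2-D Poisson problem ∇̃²ψ = ∇²(Bz−Bz⁰)/μ0;
* the iterative update
  η^{n+1} = −⟨**J**ᵖ⟩·⟨∇u^n⟩ / (⟨**D**∇u^n⟩·⟨∇u^n⟩)
  with similarity-weighted neighborhoods, alternated with forward solves;
* companions: the two-current direct method
  (∇ln η̃ × (**D**⁻¹**J**ᵖ) = ∇×(**D**⁻¹**J**ᵖ)), the isotropic
  J-substitution baseline, the velocity/electric-field angle map
  α = cos⁻¹[(**D**∇u^n)·∇u/‖**D**∇u^n‖‖∇u‖], and the mean conductivity
  ĉ = (C₁₁+C₂₂+C₃₃)/3.

It is aimed at people developing or stress-testing conductivity-imaging
methods who want a small, fully seeded, fully synthetic test bench — no
scanner data required.  See `docs/methods.md` for the model, its
assumptions, and what the phantom studies do and do not demonstrate.

## Worked example

Run the default zero-noise study — a 64×64 phantom (160 mm field of view)
with concentric white-matter-like fibers, a 2:1 resistive η inclusion, and a
2 mA transverse injection — and reconstruct η from the simulated Bz:

```bash
dtjsub simulate --out demo/
```

which prints (and writes to `demo/metrics.json`):

```json
{
  "eta_rel_rmse_sens": 0.0387823326715879,
  "eta_rel_rmse_all": 0.056726780024402255,
  "jp_rel_l2_error": 0.002619995641501414,
  "dtj_final_residual": 0.008931709322239346,
  "dtj_iterations": 5,
  "bz_range_nT": 0.8576618147419581,
  "iso_final_residual": 0.015129254983535147
}
```

Reading these numbers: the 2 mA injection induces a Bz spanning ~0.9 nT
(the sub-nT-to-nT range that makes MREIT phase measurements noisy in
practice); the projected current recovered from that Bz matches the true
in-plane current to 0.26 % in L2; five substitution passes bring η to 3.9 %
relative RMSE on sensitivity-masked voxels (5.7 % over the whole domain,
dominated by the low-sensitivity corners a single injection cannot
determine); and the isotropic baseline's Ohm's-law residual (1.5 %) stays
above the tensor method's (0.9 %) because a scalar conductivity cannot
reproduce an anisotropic current pattern.  `demo/` also receives the η, Jᵖ,
conductivity-tensor, mean-conductivity and angle-map volumes (NIfTI), the
per-iteration history (`history.tsv`), and the exact configuration
(`config.yaml`).

The same pipeline is available as a library:

```python
from dtjsub import RunConfig, run_pipeline
result = run_pipeline(RunConfig(recon_n_max=5))
print(result["metrics"]["eta_rel_rmse_sens"])   # 0.0387...
```

Other subcommands: `dtjsub reconstruct-jp` (Bz volume → projected current),
`dtjsub reconstruct` (Bz + tensor volume → η, **C**, ĉ),
`dtjsub fit-dti` (DWI magnitudes → tensor), `dtjsub compare` (method
comparison table).  `RunConfig.animal_study_preset()` selects the in-vivo
protocol settings (5×5 search neighborhood, h = 0.1, two passes, diagonal
injection).

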