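# solnmr

Quantitative analysis of solution-NMR protein data, packaged as a tested
Python library: backbone ¹⁵N relaxation, residual dipolar coupling (RDC)
alignment tensors, structural-ensemble precision, and one-site ITC binding
thermodynamics — plus synthetic-data generators that make every stage
runnable and testable without external downloads.

It is written for structural biologists and NMR spectroscopists who have
per-residue peak-intensity tables, RDC tables, integrated injection heats
or multi-model coordinate bundles and want the standard derived quantities
with honest error estimates.

## What it computes

**Relaxation** (`solnmr.relax`). Monoexponential fits of intensity decays
give R₁ and R₁ρ; the rotating-frame rate is offset-corrected via
R₂ = (R₁ρ − R₁ sin²θ)/cos²θ, θ = arctan(Ω_N/γ_N B₁). The heteronuclear NOE
is I_sat/I_ref. The rotational correlation time τ_c comes from numerically
inverting the rigid-rotor model-free ratio R₂/R₁ on the trimmed ordered
region, and residues are classified as rigid / fast (NOE < 0.8) /
exchange (elevated R₂) / both / broadened-missing. Per-residue
I_bound/I_free titration profiles are supported.

**RDC tensors** (`solnmr.rdc`). The Saupe order tensor is the linear
least-squares (SVD) solution of D_i = v_iᵀS v_i over N–H bond vectors;
reported as axial magnitude D_a, rhombicity R = D_r/D_a ∈ [0, 2/3], Euler
angles, bootstrap errors, and the R-factor
100·√(⟨(D_obs−D_calc)²⟩ / 2⟨D_obs²⟩) %.

**ITC** (`solnmr.itc`). One-site Wiseman isotherms with Origin-compatible
dilution bookkeeping, nonlinear (n, K_D, ΔH) fitting with multi-start
initialisation and c-value diagnostics, dilution-blank subtraction, and the
exact identities ΔG = RT ln K_D and −TΔS = ΔG − ΔH.

**Ensembles** (`solnmr.ensemble`). Kabsch superposition (reflections
excluded), coordinate precision as mean RMSD to the iteratively refined
mean structure, per-residue RMSD profiles, and restraint-count accounting.

**Synthetic data** (`solnmr.synth`). Seeded generators for decays (from
Lipari–Szabo spin parameters), couplings, thermograms and ensembles; the
generators write the same TSV/PDB formats the analysis reads (`solnmr.io`),
and `solnmr.pipeline.run_pipeline` runs all stages end to end into a
reproducible output bundle with a manifest.

## Worked example

```python
from solnmr import (InjectionSchedule, enhancement_factor, fit_one_site,
                    simulate_itc, thermodynamics)

sched = InjectionSchedule(n_injections=20, injection_volume=2.0,
                          cell_volume=200.0, cell_conc=50.0,
                          syringe_conc=500.0, temperature=298.15)
exp = simulate_itc(n=1.0, kd=4.8e-6, dh=-11.5, sched=sched,
                   noise_sd=0.05, seed=4)
fit = fit_one_site(exp, seed=4)
print(f"n = {fit.n:.2f}, KD = {fit.kd*1e9:.0f} nM, dH = {fit.dh:.1f}, "
      f"dG = {fit.dg:.1f}, -TdS = {fit.tds_neg:.1f} kcal/mol")
```

prints

```
n = 1.00, KD = 4710 nM, dH = -11.5, dG = -7.3, -TdS = 4.2 kcal/mol
```

— a 1:1, enthalpy-driven (ΔH = −11.5 kcal/mol) binder with micromolar
affinity recovered from a 20-injection thermogram carrying 0.05 μcal noise;
the positive −TΔS says the entropy opposes binding. Comparing against a
tight 0.6 nM mode, `enhancement_factor(fit.kd, 0.6e-9)` ≈ 7850-fold.

The `examples/` directory holds one narrative script per capability
(`relaxation_rates.py`, `rdc_tensor_fit.py`, `itc_one_site.py`,
`ensemble_precision.py`, `full_pipeline.py`); each builds a small synthetic
input, runs the analysis and prints what the numbers mean. For instance
`python examples/relaxation_rates.py` fits 20 residues and reports
`tau_c = 6.20 ns from 15 rigid residues` along with a per-residue
rate/NOE/label table.

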