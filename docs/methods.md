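# Methods

`solnmr` implements the quantitative analyses that accompany a solution-NMR
structure-and-dynamics study of a small protein: backbone ¹⁵N relaxation,
residual dipolar coupling (RDC) alignment-tensor fitting, structural-ensemble
precision statistics, and one-site isothermal titration calorimetry (ITC).
Every analysis has a matching synthetic-data generator so the pipeline can be
exercised, tested and benchmarked without external data.

## Backbone relaxation

### Rate extraction

Peak intensities over a relaxation delay series are fit to the two-parameter
monoexponential I(t) = I₀·exp(−R·t) by nonlinear least squares
(`scipy.optimize.curve_fit`, log-linear slope as the starting rate). Rate
uncertainties come from Monte Carlo resampling: 200 synthetic series (the
count is an argument) are drawn from the fitted curve with the stated
intensity noise and refit, and the standard deviation of the refit rates is
reported. Resampling was preferred over covariance-matrix linearisation
because the delay lists in common use are sparse (7–8 points) and strongly
non-uniform, where the linearised error is optimistic.

Default delay lists mirror standard practice for a small protein:
10–1500 ms for R₁ and 0–96 ms for R₁ρ.

### Offset correction

R₂ is derived from the rotating-frame rate via
R₂ = (R₁ρ − R₁·sin²θ)/cos²θ with tilt angle θ = arctan(Ω_N/γ_N·B₁), where Ω_N
is the ¹⁵N resonance offset and γ_N·B₁ the spin-lock field strength, both in
Hz and both user inputs (per-residue offsets default to 0, in which case the
correction is the identity). The correction refuses tilt angles within
numerical reach of 90°, where cos²θ underflows and the corrected rate is
meaningless. Uncertainties propagate in quadrature.

### Heteronuclear NOE

NOE = I_sat/I_ref with quadrature error propagation. A reference intensity
within 3σ of zero makes the ratio undefined and is rejected rather than
returned. The conventional rigidity criterion NOE ≥ 0.8 (at high field, for
a protein-sized tumbler) is the default threshold used by both the dynamics
classifier and the ordered-region trim.

### Rotational correlation time

τ_c is estimated from the trimmed mean R₂/R₁ ratio of rigid residues.
The estimator numerically inverts (Brent root-finding, bracket 0.2–100 ns)
the rigid isotropic model-free ratio R₂(τ_c)/R₁(τ_c) — which is strictly
increasing in τ_c over the slow-tumbling range — at the configured field,
rather than using the closed-form √(6·R₂/R₁ − 7)/(2ω_N) approximation. Full
inversion makes the forward-simulate → estimate round trip exact for rigid
spins; the closed form is provided as a cross-check (`method="approx"`, which
agrees with the inversion to better than 10% in the 3–12 ns range).

"Ordered region" trimming: residues with NOE < 0.8 (flexible) or with R₂
outside median ± 1.5×IQR (exchange-broadened or otherwise outlying) are
excluded before averaging. When NOE data are absent the trim falls back to
the R₂ criterion alone. The ratio method assumes isotropic overall tumbling
and is insensitive to the uniform S² scaling of rigid residues; residual
sensitivity to internal motion remains — rates generated at S² = 0.87 with
τ_e = 50 ps invert ~1.5% below the generator's τ_c, inside the 2% band the
round-trip is specified to hold.

### Dynamics classification

Each residue receives exactly one label: `fast` if NOE < 0.8, `exchange`
if R₂ exceeds the trimmed-core mean by more than k·sd (k = 1.5 by default;
no standard numeric criterion exists, and 1.5 sd trades ~7% false positives
on rigid residues for sensitivity to moderate Rex), `both` if both hold,
`broadened/missing` if the amide carries no observables (missing amides are
carried as explicit gap records, never dropped), else `rigid`.

### Model-free forward model (simulator side)

The generator produces (R₁, R₂, NOE) from the two-timescale Lipari–Szabo
spectral density J(ω) = (2/5)[S²τ_c/(1+(ωτ_c)²) + (1−S²)τ/(1+(ωτ)²)],
τ⁻¹ = τ_c⁻¹ + τ_e⁻¹, with dipolar and axially symmetric CSA contributions
and Rex added to R₂ only. Constants: r_NH = 1.02 Å, Δσ(¹⁵N) = −172 ppm,
γ_H/γ_N = −9.8656, all in `solnmr.constants`. The analysis side never fits
per-residue S²/τ_e/Rex — rates are interpreted through thresholds and the
τ_c estimator only. Note the NOE's strong sensitivity to τ_e: a 6.2 ns
tumbler with S² = 0.87 has NOE ≈ 0.86 at τ_e = 0 but ≈ 0.74 at τ_e = 50 ps
at 800 MHz, so "rigid" fixtures intended to pass the 0.8 screen use
τ_e ≤ 20 ps.

## RDC alignment tensor

Couplings are modelled as the quadratic form D_i = v_iᵀ·S·v_i with S the
traceless symmetric order tensor in coupling units (Hz) and v_i the unit
N–H bond vector. Fitting solves the linear system over the five independent
components by SVD-based least squares; the design matrix must have rank 5,
otherwise the geometry is degenerate and the fit refuses with the rank found.

Eigenvalues are ordered |S_zz| ≥ |S_yy| ≥ |S_xx|; D_a = S_zz/2 and the
rhombicity R = (S_xx − S_yy)/(1.5·S_zz) = D_r/D_a ∈ [0, 2/3], made
non-negative by relabelling the x/y axes. This definition is the one
consistent with the principal-frame form
D = D_a[(3cos²θ − 1) + (3/2)·R·sin²θ·cos2φ].

The quality statistic is the R-factor
R = 100·√(⟨(D_obs − D_calc)²⟩ / (2⟨D_obs²⟩)) %, normalised so that an
uninformative fit (D_calc ≡ 0) scores √½ ≈ 70.7%. Alternative
normalisations (e.g. by the powder-average of the fitted tensor) exist in
the literature; the definition is isolated in one function so it can be
swapped. Errors on D_a and R come from a nonparametric bootstrap over
records (500 resamples by default, seeded).

When an ensemble is supplied, bond vectors are taken from the first model
by default (configurable); fitting against each model and pooling is left
to the caller.

## Ensemble precision

Superposition is the Kabsch algorithm (SVD of the cross-covariance with the
determinant sign correction, so reflections are never returned). Ensemble
precision iteratively superposes all models onto their mean structure until
the mean shifts by < 10⁻⁶ Å and reports mean ± sd of per-model RMSDs to the
mean over the selection. Backbone means N, Cα, C′ (carbonyl O excluded);
both the atom set and the metric are arguments, and a mean-pairwise-RMSD
alternative is available (it runs ~√2 larger than RMSD-to-mean for Gaussian
scatter — the two conventions are not interchangeable when comparing to
published precision numbers, which rarely state which was used).

Per-residue RMSD profiles use one global superposition (optionally over a
stated core selection) and then read per-residue deviations without
refitting, so mobile segments register against the common core.

Restraint accounting is a plain tally: NOE + dihedral (φ/ψ/χ) + hydrogen
bond + RDC, and a per-residue density rounded only at report time.

## One-site ITC

The forward model is the total-heat (Wiseman) isotherm: after injection i
the cumulative heat content is Q_i = ΔH·V₀·[complex]_i with [complex]_i the
closed-form root of the one-site binding quadratic at the current total
concentrations, and the measured differential heat is
ΔQ_i = Q_i − Q_{i−1} + (v_i/V₀)(Q_i + Q_{i−1})/2, the last term accounting
for complex displaced from the constant active volume V₀ during the
injection. Totals follow the Origin-compatible dilution convention (cell
species scaled by (1 − dV/2V₀)/(1 + dV/2V₀), titrant accumulating to
X₀·(dV/V₀)·(1 − dV/2V₀)) so fitted parameters are comparable to
instrument-software output. The convention is validated rather than
trusted: the test suite checks the closed form against a per-injection
numerical equilibrium solve (agreement ≪ 0.1%) and checks energy
conservation against an independent discrete mole tracker that expels,
injects and re-equilibrates step by step while tracking displaced complex
(heat sum within 0.5%).

V₀ defaults to 200 μL (nominal active volume of a small-cell titration
calorimeter) and is configurable. Dilution blanks are subtracted
elementwise when supplied; first-injection exclusion is available but off
by default for synthetic data.

Fitting minimises squared residuals over (n, log KD, ΔH) with
`scipy.optimize.least_squares`, multi-start: ΔH from the early plateau of
the per-mole heats, n from the molar ratio at the steepest descent, KD from
the slope there, plus four jittered restarts; the best SSR wins. Standard
errors come from the Jacobian at the optimum. Fits with
c = [cell]/KD outside [1, 10⁵] are returned with an `ill_conditioned` flag
and a warning, never suppressed — sub-nM constants measured at tens of μM
cell concentration are extrapolations and should be labelled as such.

ΔG = RT·ln KD (R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K for 25 °C) and
−TΔS = ΔG − ΔH hold exactly on every fit object (enforced at construction);
rounding to the customary 1 decimal happens only at report time. The
affinity-enhancement factor between two binding modes is the plain KD ratio.

## Synthetic-data generators

The generators emulate the statistical structure the analyses assume:
monoexponential decays with i.i.d. Gaussian intensity noise; couplings from
a known tensor with Gaussian noise; one-site thermograms at a stated
schedule (defaults: 20 × 2 μL of 500 μM titrant into 50 μM cell material at
25 °C, matching a typical small-protein experiment); ensembles of models
scattered isotropically and per-residue around a helical mean conformation,
then hit with random rigid motions so the analysis must actually superpose.
All take explicit seeds; there is no global random state, and fixed-seed
outputs are byte-reproducible.

They deliberately do not emulate: spectral processing artefacts (intensities
are generated directly, never FIDs), correlated or intensity-dependent
noise, anisotropic overall tumbling, intermediate-exchange line-shape
effects, or realistic protein covalent geometry (the ensemble template is an
idealised five-atom residue). Tests passing on synthetic data therefore
demonstrate correctness of the estimators under the stated noise model, not
robustness to every pathology of real spectra.

Peak-intensity noise levels are not calibrated to any instrument; defaults
(e.g. 1–2% of I₀) are configurable arguments.

## Problem sizes and determinism

Test-suite and acceptance-script problem sizes are desk scale by design:
20-residue rate sets, 79-coupling tensor fits, 20-injection thermograms,
20-model ensembles — enough for every estimator to reach its asymptotic
behaviour while keeping a full run in seconds. Deterministic stages are
byte-reproducible under a fixed config; the pipeline manifest echoes every
constant, threshold and seed used in a run.

## Known limitations

- No per-residue model-free fitting (S², τ_e, Rex) and no CPMG/R₁ρ
  dispersion analysis; rates are interpreted through thresholds.
- τ_c assumes isotropic tumbling; anisotropic diffusion tensors are out of
  scope.
- The RDC module fits a tensor to a fixed structure; it does not refine
  coordinates against couplings or predict alignment from molecular shape.
- The ITC module covers a single class of identical sites; competitive and
  ternary models are out of scope.
- Published coordinate-precision and RDC R-factor values for a given
  deposited ensemble can only be reproduced from those deposited data;
  the synthetic round trips verify the estimators, not the deposition.
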