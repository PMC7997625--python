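# Methods

## Equilibrium model and conventions

Speciation is computed from overall (cumulative) formation constants
β_mlh for m M + l L + h H ⇌ MₘLₗH_h, written from the free metal ion and
the fully deprotonated ligand.  All constants are conditional on the
working medium (here 0.15 mol L⁻¹ NaCl): activities are identified with
concentrations, pH means −log₁₀[H⁺] (the glass electrode is treated as
standardized on the concentration scale), and no activity-coefficient or
ionic-strength model is applied.  Negative proton coefficients denote
hydroxo species; the hydroxide ion (0,0,−1) with log β = −pKw is always
implied and may not be declared, so a "water-only" model is a valid
strong-acid/strong-base system.

Analytical (total) concentrations use the same reference forms.  For a
ligand whose fully protonated form carries n_H protons (n_H = 4 for DMSA:
two thiols, two carboxylates), the total proton concentration of a
solution prepared from the neutral acid, HCl and NaOH is

    C_H = n_H·C_L + C_HCl − C_NaOH,

which may be negative in excess base.  Temperatures are discrete keys of
the constant tables; requesting an absent temperature is an error rather
than an interpolation, because the packaged constants exist only at
288.15, 298.15, 310.15 and 318.15 K.

pKw in 0.15 mol L⁻¹ NaCl is a required model input (it is not derivable
from the formation constants).  The packaged sets use the conditional
literature value 13.75 at 298.15 K and the pure-water temperature trend
shifted by the same offset at the other temperatures (14.10, 13.37,
13.15).  The synthetic-data generator treats whatever pKw is configured
as ground truth, so all recovery tests are self-consistent regardless of
this choice.

## Speciation solver

The mass-balance system (one equation per component; the proton balance
includes −[OH⁻]) is solved by Newton–Raphson iteration on the natural
logarithms of the free component concentrations, which enforces
positivity.  Per iteration the full Newton step is solved from the normal
matrix NᵀDN (N the stoichiometric matrix over all species including the
free forms, D the diagonal of species concentrations), clipped to two
decades per component, and halved (up to 50 times) until the scaled
residual norm decreases.  Iteration stops when the maximum relative
residual falls below 10⁻¹³ or the log-step below 10⁻¹²; convergence is
accepted only if every component balance closes to 10⁻¹⁰ relative.
Residuals are scaled by max(|total|, Σ|ν|c, 10⁻¹⁵) so that zero-total
cases (pure water) remain well-defined.  The default start is
free = total (10^−pKw/2 for the proton when its total is non-positive);
a short ladder of alternative proton starts covers stiff cases, and all
titration-style loops warm-start each point from the previous solution.
Components with zero totals (other than the proton) are dropped from the
system together with every species containing them.

## Thermodynamics

ΔG = −RT ln10·log β with R = 8.314 J mol⁻¹ K⁻¹.  ΔH comes from an
unweighted ordinary-least-squares van't Hoff line of ln β against 1/T
(ΔCp = 0 over the 30 K window), reported with the regression standard
error; TΔS = ΔH − ΔG is an identity of each emitted record.  With the
packaged four-temperature series this reproduces the ligand-protonation
enthalpies within their stated uncertainties (23.3, 40.1, 65.2, 57.0
kJ mol⁻¹ for HL…H4L against 22±3, 40±3, 65±2, 57±3), while the complex
(MLHᵢ) enthalpies computed this way differ systematically by ≈5 kJ mol⁻¹
from the tabulated −20/−32/−50 kJ mol⁻¹ (we obtain −15.4/−36.9/−44.6).
A two-parameter unweighted fit of the MLHᵢ series cannot reach those
values; since the original fitting procedure (weighting, software) is not
specified, the discrepancy is documented rather than tuned away, and only
the protonation rows are treated as reproducible.

## Sequestering ability

χ(pL) is evaluated in the analytic trace limit: the free ligand
concentration [L] comes from the ligand-only speciation at the fixed pH
and total C_L = 10^−pL, and χ = S/(1 + S_side + S) with
S = Σ β₁₁ᵢ[L][H]ⁱ.  This is independent of C_M by construction and agrees
with brute-force speciation at C_M = 10⁻¹² mol L⁻¹ to better than 10⁻⁶
(tested).  It requires every complex to be mononuclear in the metal;
polynuclear species raise an error.  Metal side reactions (hydrolysis,
medium binding) are supplied as extra species lines because their
constants come from independent determinations and are not part of the
packaged sets — consequently the package's parameter-free pL0.5 for
As(III)–DMSA at pH 7.4 / 310.15 K is 5.02, a no-side-reaction value.
pL0.5 is located by Brent bisection of χ(pL) = 0.5 (xtol 10⁻¹⁰) with the
bracket extended up to 10 log units beyond the grid, and cross-checked by
a least-squares fit of the base-10 Boltzmann sigmoid
χ = 1/(1 + 10^(pL−pL0.5)) (unit asymptotes); for multi-complex systems
the curve is not an exact sigmoid and the two values are only required to
agree to ~0.1.  pL0.5 is conventionally reported to two decimals.

## Synthetic titrations

The generator mirrors the experimental workflow the packaged constants
came from: 25 mL of ligand (+ metal) fully protonated with HCl in
0.15 mol L⁻¹ NaCl, titrated with standard NaOH so that the simulated pH
sweeps 2–10.5.  Default study conditions, chosen once: potentiometry at
C_L = 1–2 mmol L⁻¹, C_HCl = 8 mmol L⁻¹, equimolar metal where present,
0.1 mol L⁻¹ titrant in ≥50 steps; spectrophotometry at
C_M = 0.05 mmol L⁻¹, C_L = 0.1 mmol L⁻¹ over 200–350 nm.  The electrode
follows E = E⁰ + s·log₁₀[H⁺] + ja[H⁺] + jb[OH⁻] with the theoretical
Nernst slope s = RT ln10/F by default and junction coefficients
defaulting to 0 (they are refinable but no reference values exist).
Noise defaults to the instrument precisions, σ_E = 0.15 mV and
σ_v = 0.003 mL; the volume error perturbs the *delivered* volume before
speciation while the nominal schedule is recorded, so it propagates into
the emf like a real buret error.  Absorbances obey Beer–Lambert
additivity over a 1 cm path with Gaussian-band molar-absorptivity
fixtures (real DMSA band shapes are not transcribed anywhere; the bands
are synthetic by construction).  One integer seed expands into
independent substreams for emf, volume and absorbance noise; seed = None
gives a bit-stable noiseless dataset.  Dilution bookkeeping conserves
component moles to 10⁻¹² relative.

What the generator does **not** emulate: CO₂ ingress, electrode drift,
junction-potential curvature, temperature gradients, or spectral baseline
error.  Passing recovery tests therefore demonstrate the correctness and
calibration of the estimator under the stated noise model, not robustness
to systematic experimental artefacts.

## Refinement

Potentiometric refinement minimizes Σ wᵢ(E_obs − E_calc)² by Gauss–Newton
with Levenberg damping; the inner loop re-solves speciation at every
titration point (warm-started per point across evaluations).  Jacobians
are central finite differences (step 10⁻⁴ on log β and pKw, 10⁻³ mV on
E⁰, relative 10⁻⁴ on concentrations).  Weights propagate the instrument
precisions, wᵢ = 1/(σ_E² + (∂E/∂v)ᵢ²σ_v²), with ∂E/∂v estimated from the
observed curve (unit weights are available).  Damping guarantees a
monotone objective; convergence requires a relative objective change
below 10⁻¹⁰ with a maximum parameter update below 10⁻⁶ (an update below
10⁻⁸, or a numerically-exact fit, also terminates).  Standard deviations
come from the inverse normal matrix — recomputed at the optimum and
inverted by eigendecomposition — scaled by σ_fit = √(obj/(n−p)); a
numerically singular direction raises an identifiability error naming the
parameter.  Joint refinement over several titrations shares the
thermodynamic parameters and keeps E⁰ and analytical concentrations per
dataset.

Spectrophotometric refinement uses variable projection: for each trial
constant set the species concentration matrix follows from mass balance
and the molar absorptivities from a linear least-squares solve per
wavelength; the nonlinear search runs over the constants only.  Fitted
absorptivities are unconstrained, with a warning if any come out
negative.  Profiles established independently (typically the ligand
species, from a ligand-only titration) can be supplied as known and are
subtracted rather than fitted — mirroring the two-stage experimental
practice.  This matters: with all eight DMSA-system profiles free, the
common mode of the three complex constants is nearly unidentifiable at
the UV-cell concentrations (the metal stays >97 % complexed), and the fit
degenerates; with ligand profiles known, the constants are recovered with
standard deviations of ~0.06–0.12 log units at σ_A = 0.002.

Model selection refines each candidate against the shared datasets and
ranks by σ_fit; candidates within 1 % relative are treated as ties and
ordered by species count (simplicity), and species whose maximum
formation never exceeds 1 % of the total metal are flagged negligible.
Both thresholds are package defaults chosen from standard speciation
practice; neither has a reference value.

## Numerical and design notes

* The packaged As(III)–DMSA constants imply that MLH3 exceeds MLH2
  pointwise below pH ≈ 4.1 (their concentration ratio is 10^(4.10−pH));
  MLH2's prevalence is therefore assessed as the largest grid-averaged
  metal fraction over pH 2–10.5, under which it dominates unambiguously.
* Distribution diagrams propagate solver failures with the offending pH
  attached.  Fractions of a component are normalized over the species
  that contain it, free reference form included, and sum to 1 within
  10⁻⁹.
* The spectral refinement flags over-proposed species by their maximum
  formation fraction (<1 %) or an exploding standard deviation; rank
  deficiency worse than that (more absorbing species than points or
  wavelengths) is rejected up front.
* Study sizes used by the test suite: 51-point titrations, 100 seeded
  replicates for the potentiometric coverage study, 5 for the
  spectrophotometric one, 31 wavelengths × 25 points for spectra.
* Known limitations: no polynuclear or mixed-ligand species beyond the
  config grammar, no ionic-strength extrapolation, no competition between
  multiple ligands or metals in one solution, no Bayesian uncertainty.
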