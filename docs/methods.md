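# Methods

## Model

The duplex is reduced to one effective particle per base pair (bp) with
two degrees of freedom: the twist angle φₙ about the helix axis and the
radial displacement ρₙ = rₙ − R₀. Bases sit on a cylinder at
(rₙ cos φₙ, rₙ sin φₙ, cφₙ) with pitch parameter c = h₀/θ₀, so the rise
is slaved to the twist and the helical geometry is preserved by
construction. The complementary base mirrors the reference base with
ρ̄ₙ = λₙρₙ (fixed pair centre of mass), λₙ = mₙ/m̄ₙ ≥ 1.

Potentials (PDB family):

- Morse H-bond stretching, argument (α/2)(1+λ)ρₙ — the full pair
  opening; depth D = 0.15 eV, width α = 5 Å⁻¹, shared by GC and AT (one
  effective Morse potential for both pair types).
- Stacking U_S = (1/8)Σ k_S[1 + e^{−(b/2)u⁺}](u⁻)² with
  u^± = (1+λₙ)ρₙ ± (1+λₙ₊₁)ρₙ₊₁; the exponent placement (b/2 on u⁺, the
  global 1/8) was chosen so the linearized radial equation carries the
  μ = (1+λ)²/λ-weighted frequencies; it is corroborated by the
  finite-difference Hessian bridge below.
- Backbone U_B = (k_B/2)Σ[(d − l₀)² + (d̄ − l₀)²] on the exact
  inter-base distance of both strands.

The equilibrium frame (c, ξ, l₀, f₀, g₀, l_B, a_B, b_B) is derived at
full floating-point precision from (θ₀, h₀, R₀) only. Published
constants that were printed after intermediate rounding (l_B 8.575 vs
8.580 here; q* 2.732 vs 2.738; χ 2.92 vs 3.04) are reproduced within
the rounding, and comparisons use correspondingly widened tolerances;
derived constants never inherit print rounding.

## Phonons and dynamics

Linearizing the canonical equations gives the twist equation driven by
(1+λ)ρ differences through 1/l_B and the radial equation driven by φ
differences through a_B, with characteristic frequencies
ω_φ² = (2k_B/M)[f₀/(ξl₀)]², ω_H² = Dα²/2M, ω_S² = k_S/M and the coupled
combinations ω_φρ, ω_φS, ω_HS (ω_HS² = μ(ω_H² + 2ω_S²) exactly). The
helical-wave ansatz φₙ, ρₙ ∝ e^{i(ωt−nqξ)} produces a 2×2 secular
problem whose determinant gives both branches in closed form.

Numerical choices:

- The simulator integrates the *linearized* system (the object of the
  dispersion analysis); the nonlinear potentials are kept separately
  and used for validation. Forces and the Hessian of the nonlinear
  potentials are obtained by central finite differences (gradient step
  10⁻⁶, Hessian step 10⁻⁵ in nm/rad) from the clean potential
  expressions rather than hand-expanded force formulas.
- RK4 with a fixed step, default dt = 1 fs ≈ 1/450 of the fastest
  period (τ_HS ≈ 0.45 ps); a norm check every 1000 steps aborts on
  instability or non-finite fields. Periodic boundary is the default
  (it matches the Bloch analysis); free ends drop the wrap-around
  couplings and are for qualitative runs only.
- Helical-wave initial conditions realize the real part of the complex
  eigenvector, phases fixed so φ is cosine-like at t = 0, site 0.
  Acoustic modes are scaled to the twist amplitude φ₀ = 0.14 rad,
  optical modes to the radial amplitude ρ₀ = 0.05 nm (the eigenvector
  is radial-dominated there by roughly two orders of magnitude).
- The Hessian bridge Bloch-transforms the site-0 coupling blocks of the
  mass-weighted (M ξ² for twist, Mλ for radial) finite-difference
  Hessian on a periodic ring and diagonalizes per commensurate q. The
  resulting normal modes agree with the analytic branches to ~10⁻⁸
  relative: the dispersion depends only on the product of the two cross
  couplings, which is exactly symmetric for any Hamiltonian-derived
  system, so the asymmetric split of the coupling between the two
  linearized equations cancels.
- Codon residuals evaluate the triplet collective equations with
  second time derivatives by central differences; the expected residual
  scale is (ω dt)²/12 ≈ 10⁻⁵ at dt = 1 fs, well under the 10⁻⁴
  acceptance threshold.

Problem sizes: dispersion checks use rings of 16–48 sites; the long
mode-preservation run uses a 300-bp ring for 10⁵ RK4 steps (100 ps);
spectral recovery uses 48 bp × 16384 steps at 4 fs (FFT resolution
0.015 THz). These sizes resolve every feature the analytic theory
predicts while keeping runs interactive.

## Charge transfer

The π–π hopping decays with the squared chord distance between
attachment points, t = t₀[1 − (η̄/d²)·chord²] with η̄ = 1 + |η_ppπ|/η_ppσ
= 1.429. The reference distance d in the prefactor is identified with
the equilibrium inter-base distance l₀ — the only reading under which
the equilibrium and small-twist limits follow from the general form.
Under a synchronized helical wave of amplitude A₀² = φ₀² + (ρ₀/R₀)² ≈
0.022 the hopping becomes site-independent, t(q) = t₀[1 − 4χA₀²
sin²(qξ/2)] with 4χA₀² ≈ 0.27, so the channel never closes.

The sugar-phosphate groups are decimated exactly (uniform backbone
on-site energy γ, counterion condensation argument), producing the
energy-dependent on-site term ε_XY(E) = 2[t_P² + a_XY(E−γ) +
b_XY(E−γ)²]/(E−γ), a_XY = ε_X + ε_Y, b_XY = (ε_X² + ε_Y²)/2t_P². The
band defaults use the pair coefficients (a_GC = 16.6 eV, b_GC = 30.9;
a_AT = 17.4 eV, b_AT = 33.6) directly rather than individual base
energies, which are only known as literature ranges; this makes the
published band quantities reproducible without a within-range choice.
The interstrand hopping t⊥ is stored in the registry but unused: its
insertion point in the first renormalization step is not defined
unambiguously, and the band results do not involve it.

Eliminating E from E = ε_XY(E) + t(q)(1 + 2cos κh₀) yields an explicit
quadratic whose closed-form roots are used everywhere (no fixed-point
iteration); the transfer-matrix route (unimodular M(E,q), M^N via the
Chebyshev three-term recurrence, stable in both the oscillatory and
hyperbolic regimes) is kept as an independent cross-check.

Two conventions deserve note. First, the labelling of the two band
widths W± is ambiguous in the literature table this model reproduces;
recomputation matches the printed values with the labels attached to
{wider, narrower}, so results report the ordered pair (the wider band
is the lower one here). Second, the reported gap E_g(0, q) is the
*direct* separation of the two roots at κ = 0 — where it is largest —
not the indirect band-to-band minimum (which occurs at κh₀ = π and is
~26 meV for polyG-polyC); the closed-form gap expression and the
printed tables are only consistent under the direct-gap reading. The
generalization t₀ → t(q) inside that expression reproduces the printed
E_g(0, q*) column and is adopted.

## What the generator emulates

Inputs are synthetic by design: homopolymer, Bernoulli-random or
FASTA-derived GC/AT sequences, and plane-wave or random small initial
states. They emulate the *study conditions* of the model — ideal
B-form geometry, two bp species distinguished only by mass ratio, small
oscillations at ambient-temperature amplitudes (φ₀ = 0.14 rad,
ρ₀ = 0.05 nm). They do not emulate sequence-dependent stacking
parameters, solvent friction or thermal (Boltzmann) ensembles,
denaturation bubbles, or disorder in the backbone energies; passing
tests therefore certify the internal consistency of the helicoidal
model and its published numbers, not agreement with experiment on real
heterogeneous DNA.

## Known limitations

- Harmonic/linearized dynamics only; the nonlinear potentials enter
  solely through equilibrium curvature checks.
- The printed characteristic-frequency table is internally consistent
  with an effective pair mass ≈ 635.5 amu rather than the quoted
  M = 653.5 amu (invert ω_S² = k_S/M); this package uses the quoted M,
  landing ~1.5% below the printed frequencies, and compares at 2.5%.
- No transport observables (transmission, I–V, conductance), no
  polaron self-trapping, no localization from sequence disorder.
- γ-dependence: within the quoted backbone-energy range the gap closes
  already near γ ≈ 0.36 eV (semimetal beyond), so the semiconducting
  regime studied here is the γ ≈ 0 corner.
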