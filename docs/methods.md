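# Methods

## Scope and model

`cgfep` implements the desk-scale machinery of coarse-grained alchemical
free-energy perturbation (CG-FEP) for protein–lipid binding: a bead-level
energy model with an alchemical coupling coordinate, a Metropolis Monte
Carlo sampler, the standard free-energy estimator family (EXP, BAR, MBAR,
TI), WHAM reconstruction of one-dimensional potentials of mean force,
thermodynamic-cycle bookkeeping for relative binding free energies (ΔΔG),
binding-site trajectory analysis, and Hill-equation dose–response fitting.

The target application is the kind of study in which an inositol
phospholipid (PIP₂) bound to an inward-rectifier potassium channel is
alchemically transformed into related species (PI4P, PI, PC, short-tail
diC8-PIP₂), in both the bound site and bulk membrane, to obtain
ΔΔG = ΔG_bound − ΔG_bulk; and in which point mutations (e.g. E179K, K67N)
are transformed in the presence and absence of the lipid.  Reproducing
microsecond membrane simulations of real channel structures is out of
scope; all quantitative validation runs on toy systems whose answers are
known analytically or by exhaustive enumeration.

## Energy model

Units are kJ/mol, nm, elementary charges and kelvin throughout; reduced
potentials are energies divided by kT with kB = 0.0083144626 kJ/mol/K.
The default temperature is 323 K (kT ≈ 2.6856 kJ/mol).

* **Nonbonded terms.** Lennard-Jones 12-6 with Lorentz–Berthelot
  combination, and Coulomb interactions screened by a uniform relative
  dielectric of 15 (the common coarse-grained force-field convention).
  Orthorhombic periodic boxes with the minimum-image convention; no cutoff
  and no long-range electrostatics correction at toy scale.
* **Alchemical coupling.** Each bead carries A- and B-end-state parameters.
  Charges interpolate linearly, q(λ) = (1−λ_coul)·qA + λ_coul·qB, with no
  soft core.  Lennard-Jones interactions of pairs whose vdW end states
  differ use the Beutler soft-core form with effective separation
  r_eff⁶ = α σ_sc⁶ (1−λ)^p + r⁶ and α = 0.5, σ_sc = 0.3 nm, p = 1.  The
  pair energy is the two-end combination
  (1−λ_vdw)·U_sc(A; soften=λ_vdw^p) + λ_vdw·U_sc(B; soften=(1−λ_vdw)^p),
  which reduces exactly to the plain A (B) potential at λ_vdw = 0 (1).
  Soft-core softening applies **only** to pairs whose Lennard-Jones
  parameters differ between end states: charge-only perturbations keep
  their full repulsive core at every window, which both avoids bare-charge
  overlap and keeps intermediate windows of a charge-scaling leg physically
  identical in their vdW interactions.
* **λ schedule.** Two legs: λ_coul is swept over a linear grid 0…1 first
  (vdW untouched), then λ_vdw is swept at λ_coul = 1.  Removing charges
  before cores prevents Coulomb singularities.  The default grid is 11
  points per leg (0, 0.1, …, 1.0) with the shared (1, 0) midpoint counted
  once, i.e. 21 distinct windows; the count is configurable.
* **Bonded terms.** Harmonic bonds and an optional elastic network.  A
  topology may interpolate bond parameters linearly in λ_vdw; this is how
  the harmonic-dimer spring transformation runs through the same pipeline
  as nonbonded transformations.
* **Flat-bottom restraint.** Zero inside radius d₀, ½k(d−d₀)² beyond,
  acting between the centroids of two bead groups (lipid phosphate vs
  protein backbone).  Defaults d₀ = 0.8 nm and k = 1000 kJ/mol/nm².  The
  source protocol mentions both a 6 Å selection radius and an 8 Å
  activation distance; we read the 8 Å figure as the flat radius and expose
  both as configuration.

## Sampling

Equilibrium samples come from single-bead Metropolis Monte Carlo with
Gaussian displacement proposals: only equilibrium averages enter FEP
estimators, so a dynamical integrator, thermostat and barostat are
unnecessary at this scale.  Acceptance follows min(1, e^(−Δu)).  Proposal
widths are chosen per fixture for acceptance rates around 40–60 %.  Each
trajectory uses one named NumPy generator with an explicit seed; identical
seeds give bitwise-identical trajectories.  Saved frames after a 10 %
equilibration fraction are optionally subsampled at the statistical
inefficiency g of the potential-energy series (autocorrelation sum
truncated at its first non-positive term, stride ⌈g⌉), so estimator inputs
are approximately independent.

Cross-evaluation re-scores every saved frame under every window's reduced
potential to build the u_kn matrix MBAR consumes; the row belonging to a
trajectory's own window reproduces its recorded potential series exactly
(identical code path), which is asserted, not assumed.

## Estimators

* **MBAR** is solved by self-consistent iteration of
  f_k = −ln Σ_n exp(−u_kn)/Σ_j N_j exp(f_j − u_jn), initialized at
  f_k = 0, tolerance 1e−8 kT on the maximum change, at most 10 000
  iterations, anchored to f_0 = 0.  The asymptotic covariance is the
  pseudo-inverse of the Fisher information of the equivalent
  multinomial-logistic ("reverse logistic regression") model.  EXP and BAR
  follow the standard Zwanzig and Bennett forms, the latter solved by
  bracketed root finding with the classical asymptotic variance;
  degenerate overlap is flagged rather than silently reported.  TI uses
  trapezoidal quadrature of ⟨∂u/∂λ⟩; a matrix-based variant approximates
  the derivative by central differences of neighbouring windows' energies,
  which is exact when u is linear in the path coordinate (interpolated
  charges and bonds) and a controlled approximation otherwise.
* **Weighted samples.** EXP, BAR and MBAR accept per-sample weights.
  Feeding every configuration of a discrete system with its exact
  Boltzmann weight turns the estimators into exact partition-function
  machines — the package's primary correctness oracle (agreement to
  < 1e−6 kT is enforced in tests).
* **Uncertainties.** The primary error bar everywhere is the SEM across
  independent replicas (n = 3 by default), with estimator asymptotic
  errors reported as secondary, following the convention of the
  experimental literature this mirrors.
* **WHAM** iterates the standard coupled histogram equations on a uniform
  grid whose spacing matches the umbrella spacing (0.02 nm, i.e. 0.2 Å),
  tolerance 1e−10 on window free energies, and anchors the profile minimum
  to exactly zero.  With all umbrella constants zero it reduces to plain
  histogram inversion (tested).  Per-bin uncertainties come from a
  Bayesian bootstrap: 200 rounds of Dirichlet(1,…,1) weights over windows,
  SE = per-bin SD across rounds, seed-reproducible.  Note that anchoring
  shifts a flat noisy profile upward by the deepest noise excursion, so
  flatness is judged about the profile mean.

## Thermodynamic cycles and transformations

ΔΔG = mean(bound) − mean(bulk) with errors combined in quadrature.
Stepwise decompositions (e.g. PIP₂ → PI4P → PI → PC) are checked against
the direct transformation: the discrepancy must fall within a configurable
multiple (default 3) of the combined error.  Lipid and residue
transformations are expressed as name-keyed bead edit lists diffed from
small editable parameter tables; because edits are keyed by bead name, the
union of stepwise edit lists equals the direct edit list by construction.
The PI → PC headgroup swap is represented as ring beads to dummies plus a
choline bead appearing; the published mapping is graphical only and the
table is user-overridable.  diC8 tail truncation keeps two beads
(≈ eight carbons) per tail.

## Toy fixtures: what they emulate and what they do not

* `harmonic_dimer` — one bead on a 1-D spring, k: 1 → 4, kT = 1;
  Δf = ½ ln 4 ≈ 0.6931 kT by the Gaussian partition function.  The mobile
  bead moves only along x so the analytic reference has exactly one degree
  of freedom.
* `discrete_two_state` — two configurations with u_A = (0, 1) and
  u_B = (2, 2) kT; Δf = ln(Z_A/Z_B) ≈ 1.6201 kT by enumeration.
* `lj_fluid_box` — a small periodic LJ fluid with one particle decoupled
  through the soft-core path; no closed form, used for cross-estimator
  consistency.
* `toy_receptor_site` — a frozen cage of 14 positively charged beads (cube
  corners plus face centers, so the pocket is genuinely enclosed) around a
  mobile "lipid" bead of charge −2 e in a 3 nm box, bound by roughly
  35 kT; the bulk leg is the same lipid among neutral solvent beads.  The
  stepwise path passes through a −1 e intermediate.  Cycle closure is
  exact by construction (shared end states), making this the desk-scale
  analogue of a stepwise-vs-direct consistency check on a real channel.

These fixtures reproduce the *statistical* structure of the production
protocol (windows, replicas, restraints, estimators), not the physics of a
crowded membrane: there is no bilayer, no conformational gating, no slow
collective motion, and the samplers equilibrate in thousands rather than
millions of steps.  Passing tests therefore demonstrate correctness of the
estimators and bookkeeping, not force-field accuracy on real channels.

## Dose–response analysis

The modified Hill equation I/I_c = a + (1−a)/(1 + ([X]/IC50)^h) is fitted
by least squares in log10-concentration space (IC50 parameterized as
log10 IC50; bounds h > 0, a ∈ [0, 1]; SEs by the delta method).  The
control current is the mean of the bracketing control measurements; an
unbracketed control is accepted with a mandatory warning because channel
rundown is then unaccounted for.  Worked examples regenerate noiseless
curves from the published fits (IC50 = 81 µM/h = 0.96; 1.7 mM/1.13;
55 µM/0.61; 3.3 mM/1.6) and recover the parameters to machine precision;
`a` is pinned to 0 except for the variant reported not to close fully at
saturating blocker.  One construct's IC50 is printed as 55 µM in one
passage and 54 µM in another; the first occurrence is used.

## Numerical choices and problem sizes

Validation problem sizes were chosen so the whole suite runs on a single
CPU in minutes: 50 000 MC samples per window for the harmonic recovery
(11 windows), 4 000–5 000 samples per window across 11 windows and three
replicas for the receptor cycle, 2 000–3 000 samples per umbrella window
for WHAM.  Statistical assertions use 3× the combined standard error;
exact oracles use 1e−6 kT.  Degenerate inputs (constant series, empty
windows, non-overlapping histograms, zero mobile beads, underdetermined
fits) raise errors or mandatory warnings rather than returning silently.

## Known limitations

* The sampler moves one bead at a time; systems with many coupled mobile
  beads decorrelate slowly, and no cluster or hybrid moves are provided.
* MBAR uses plain self-consistent iteration; poorly overlapping windows
  converge slowly (they are flagged, and the overlap matrix is available).
* The matrix-based TI derivative inherits a discretization bias on paths
  where u is nonlinear in λ; use more windows or the exact per-window
  derivative when that matters.
* The CG parameter tables cover only the species and residues needed by
  the shipped transformations; they are data, not a force field.
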