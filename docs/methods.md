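# Methods

This note documents the models implemented in `ligscreen`, the defaults and
units they use, what the synthetic fixtures do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Units and constants

One consistent unit system is used throughout: Å (length), kcal·mol⁻¹
(energy), amu (mass), ps (time), elementary charge, Kelvin. Fundamental
constants are absorbed into four conversions (`ligscreen.constants`):
k_B = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, the Coulomb prefactor
k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², ħ = 1.5179×10⁻² kcal·ps·mol⁻¹, and
1 kcal·mol⁻¹ = 418.4 amu·Å²·ps⁻². Keeping the system closed means every
formula below has a closed-form oracle in the same units.

## Docking stage

The pair score follows the classic empirical hybrid form: two Gaussians of
the surface distance d (widths 0.5 Å and 2 Å, the second offset by 3 Å), a
quadratic repulsion for d < 0, a linear hydrophobic ramp (1 → 0 between
d = 0.5 and 1.5 Å) applied between hydrophobic-carbon pairs, and a linear
hydrogen-bond ramp (1 → 0 between d = −0.7 and 0 Å) between donor/acceptor
pairs. Default weights (−0.0356, −0.00516, 0.840, −0.0351, −0.587) and the
8 Å cutoff are the published values for this functional form; all are
config-overridable. The cutoff is applied to the surface distance.

Ligands are rigid bodies. Torsional flexibility and the rotatable-bond
penalty are deliberately omitted: rigid-body poses exercise the full scoring
function while keeping the optimiser six-dimensional. The global search is
an iterated local search — random perturbation of the incumbent inside the
search box, Nelder–Mead simplex refinement (a derivative-free local
minimiser; the contract is only "reaches a local minimum", which the
brute-force grid test verifies), accept on improvement, ties keep the first
pose. Default 8 restarts; deterministic per seed. Out-of-box centroids are
pulled back by a quadratic penalty during minimisation and clipped on
output.

Docking atom types are assigned from elements and bonds: carbon bonded only
to carbon/hydrogen → hydrophobic; nitrogen with attached hydrogen → donor;
oxygen → acceptor, or donor-acceptor when it carries a hydrogen; everything
else (including unknown elements) → other. The assignment is total and
deterministic.

## MM/GBSA stage

**MM terms.** Harmonic bonds k(r−r₀)² and angles k(θ−θ₀)², cosine dihedrals
k(1+cos(nφ−δ)); Lennard-Jones 12-6 in the Rmin convention
(Rmin_ij = R_i + R_j, ε_ij = √(ε_iε_j)), Coulomb k_e·q_iq_j/r with interior
dielectric 1; 1-2 and 1-3 pairs excluded. When a structure arrives without
a force field, `equilibrium_bond_params` turns its bond list into stiff
springs (default 300 kcal·mol⁻¹·Å⁻²) at the observed lengths — a declared
stand-in for real bonded parameters on toy systems.

**Polar solvation.** Screened Still generalized-Born energy,
G_polar = −(k_e/2) Σ_iΣ_j D_ij q_iq_j/g_ij with
g_ij = √(r² + α_iα_j e^(−r²/4α_iα_j)), D_ij = 1 − e^(−κg_ij)/ε_s, the double
sum including i = j. The Born-ion limit −(k_e/2)(1−1/ε_s)/α is exact by
construction and is the primary oracle. Effective radii use
Hawkins–Cramer–Truhlar pairwise descreening integrals with the
Onufriev–Bashford–Case tanh rescaling (coefficients 1.0, 0.8, 4.85) and no
per-element screening factors. The stored `gb_radius` is interpreted as the
intrinsic (already offset) descreening radius, so an isolated atom's
effective radius equals its `gb_radius` exactly; the bundled element table
stores Bondi-like values minus the conventional 0.09 Å offset. The Debye
parameter is the monovalent-salt form κ² = 8π·k_e·n/(ε_s·k_B·T) with n the
ion number density; no empirical κ rescaling is applied. Defaults:
ε_s = 78.5, zero ionic strength, T = 300 K.

**Nonpolar solvation.** γ·A_SA with γ = 0.005 kcal·mol⁻¹·Å⁻² (configurable)
and a Shrake–Rupley surface area on LJ radii with a 1.4 Å probe. The sphere
quadrature is a deterministic golden spiral, 960 points per atom by default
(≤ 1% error on an isolated sphere, < 0.5% change on doubling).

**Entropy.** Quasiharmonic: frames are Kabsch-superposed onto the first
frame (receptor α-carbon selection for receptor-containing systems, all
heavy atoms for ligand-only systems; selections of < 3 atoms fall back to
translation-only with a warning), the 3N×3N coordinate covariance is
mass-weighted, and each eigenvalue λ gives a mode ω = √(k_BT/λ) whose
entropy is the quantum-harmonic-oscillator expression
S/k_B = u/(e^u−1) − ln(1−e^(−u)), u = ħω/k_BT. Eigenvalues below
10⁻⁸ amu·Å² are discarded and counted; alignment legitimately leaves up to
six, and rank-deficient covariances (fewer frames than degrees of freedom)
more — a soft warning, not an error. For the complex, all atoms (ligand
included) enter the covariance after receptor-only alignment.

**Binding.** Three independent trajectories (complex, receptor, ligand) per
the 2N+1 protocol; ΔG⁰ = G_C − G_R − G_L with per-term decomposition
(ΔE_MM, ΔG_polar, ΔG_nonpolar, −TΔS) that sums to ΔG⁰ exactly. The first
10% of frames are discarded as equilibration (configurable). The
single-trajectory MM/GBSA shortcut is deliberately not used.

## FEP stage

The coupled potential is U(λ, λ_r) = U_intra + (1−λ)·U_elec,inter +
(1−λ)·U_LJ,softcore(λ) + λ_r·U_restraints with the β-softcore form
t = 1/(α_sc·λ + (r/Rmin)⁶), α_sc = 0.5, which is the physical LJ at λ = 0,
zero at λ = 1, and finite at any overlap for λ > 0. The receptor is rigid;
its internal energy is a dropped constant. A search box confines the ligand
centroid (infinite energy outside) and defines the configuration volume
shared by the bound and unbound legs — because the unbound leg samples that
same volume, no standard-state correction is applied, and cycle results are
directly comparable to configuration-integral quadrature over the box (a
known limitation for absolute ΔG comparability to experiment).

Ensembles come from a Metropolis sampler standing in for an MD engine:
Gaussian per-dof moves (or rigid-body translation+rotation moves for
multi-atom ligands), mixed with a 10% probability of a uniform in-box
teleport of the ligand centroid — a symmetric kernel that keeps the
near-flat weakly-coupled windows mixing, where pure local moves are
diffusive. Per window: 20% equilibration, then strided frames; ΔUᵢ is
evaluated as U(λᵢ₊₁) − U(λᵢ) on the λᵢ ensemble (the standard convention),
and ΔGᵢ by log-sum-exp-stabilised Zwanzig averaging with a delta-method
standard error (frames treated as independent after striding, so the SE is
a lower bound under residual correlation).

The cycle has four simulated legs — restraint coupling in the bound state,
decoupling in the bound state (restraints on), decoupling in the unbound
state, restraint coupling in the unbound (decoupled) state — plus the
transfer of the non-interacting ligand, which contributes exactly zero.
Sign convention: ΔG_bind = −[ΔG(bound_restrain) + ΔG(bound_decouple) −
ΔG(unbound_decouple) − ΔG(unbound_restrain)], so deeper wells give more
negative ΔG_bind. Each leg runs forward and backward; the estimate is the
mean of (forward, −backward) and |forward + backward| is reported as
hysteresis. BAR/MBAR are deliberately not used — the design is plain
forward/backward exponential averaging. Defaults: uniform λ schedule for
decoupling; geometric schedule (first window 10⁻³) for restraint coupling,
because the restrained distribution narrows like λ_r^(−1/2) and uniform
windows overlap badly near zero coupling; restraint force constant
10 kcal·mol⁻¹·Å⁻². Distance restraints act between the ligand centroid and
the centroid of non-hydrogen anchor atoms (or a fixed anchor point in the
unbound state); RMSD restraints penalise shape change after optimal rigid
superposition.

## Screening pipeline

Stages rank ascending by their own score only (scores are never mixed
across stages); ties break lexicographically on ligand id. Any per-ligand
exception becomes a failure status (`failed_dock`/`failed_sim`); failed
ligands rank after every scored ligand, ordered by id, and are never
promoted. Defaults promote the top 100 to MM/GBSA and the top 15 to FEP,
matching a campaign where those cutoffs kept the compute budget fixed; toy
runs override them. Per-ligand seeds derive from the plan seed via CRC32 of
the ligand id, so reruns are byte-identical including CSV output.

## Enrichment benchmarking

Curves are cumulative active fractions on fractional axes in [0, 1], one
point per ligand, with an implicit (0, 0) start; the baseline is the
diagonal (expected random) or a seeded shuffle. The difference integral is
trapezoidal and exact for the piecewise-linear curves involved: a perfect
ranking with active fraction a integrates to (1−a)/2 against the diagonal.
Per-stage curves are computed within the set entering that stage, since the
random-pick probability changes at each promotion. The composition helper
quotes the random-pick percentage as actives/decoys (odds form, e.g.
1,395/35,750 → 3.90%), matching how screening-campaign compositions are
conventionally quoted.

## Synthetic fixtures

`synthkit` realises requested physical parameters directly rather than
sampling chemistry, so every downstream check has an oracle:

- **Pocket receptor** — ~20 carbon atoms on a 4.8 Å sphere with the polar
  cap removed (the pocket mouth) and 0.05 Å seeded jitter; search box of
  2.5 Å half-lengths at the cage centre. The radius is chosen so a 5-atom
  ligand star sits near surface-contact distance of the cage wall.
- **Ligand sets** — actives are 5-atom hydrophobic carbon stars, decoys
  smaller neon stars (docking type `other`, poorer steric fit). LJ epsilons
  are scaled so a 1-D scan of the pocket interaction energy hits the
  requested well depth exactly (pair ε ∝ √ε_ligand, so the scale factor is
  the squared depth ratio). Defaults: −8 kcal·mol⁻¹ actives, −2 decoys —
  a strong binder against weak non-binders on this energy scale.
- **Harmonic trajectories** — exact Boltzmann draws of independent per-dof
  oscillators (variance k_BT/k) about the input coordinates.
- **Gaussian ΔU samples** — seeded normal draws for the Zwanzig identity
  ΔG = μ − σ²/(2k_BT).
- **1-D dimer** — one fixed receptor atom, one ligand atom on the x-axis in
  [2.2, 10.2] Å with a single LJ pair (default depth −4 at 3.4 Å); the
  bound-state configuration integral is a 1-D quadrature, giving
  ΔG_bind = −k_BT ln(Z_bound/V_box) as an absolute oracle.

What the fixtures do **not** emulate: chemical valence and tautomers,
property-matched decoys, solvent friction and inertial dynamics, receptor
flexibility, and parameter heterogeneity of real force fields. Passing
tests therefore demonstrate the correctness of the estimators and the
pipeline logic, not predictive accuracy on real protein–ligand systems.

## Problem sizes and determinism

Default study sizes: 20-ligand screens (3 actives) with 120-frame MM/GBSA
trajectories and 6-window/600-step FEP in the pipeline; the standalone
dimer cycle uses 12 windows × 5000 steps and the oscillator check 10⁴
frames. These sizes put every Monte-Carlo check comfortably inside its
stated tolerance while keeping a full run in minutes on one core. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; generators and the pipeline are bit-reproducible
per seed.

## Known limitations

- Rigid ligands and receptor: no conformational strain anywhere.
- The GB κ convention is the unscaled monovalent form; some MD codes apply
  an empirical 0.73 factor — results at nonzero ionic strength differ
  accordingly.
- The quasiharmonic entropy assumes a Gaussian configurational density;
  multimodal trajectories overestimate entropy.
- FEP standard errors underestimate under residual chain correlation;
  hysteresis is the more honest convergence diagnostic.
- Absolute FEP ΔG values depend on the confinement volume in place of a
  standard-state correction.
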