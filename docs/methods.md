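# Methods

This note records the physical models, numerical choices and known limits of
the toolkit, in the spirit of a model-documentation page.

## Scope and data model

The toolkit starts where quantum chemistry ends: its inputs are ion
geometries (element, Cartesian coordinates in Å, partial charge in e),
per-conformer electronic energies, and a charge state. It does not generate
conformers, assign protonation sites, or run electronic-structure
calculations. The element registry is closed (H, C, N, O, S, He): buffer-gas
interaction parameters are element-keyed, so an unrecognized symbol is an
error rather than a silently wrong CCS. Conformer charge sums are checked
against the formal charge state with a 0.02 e tolerance — loose enough for
rounded population-analysis charges, tight enough to catch file mix-ups.

## Mason–Schamp conversions

Arrival time ↔ CCS conversions use the low-field Mason–Schamp relation with
the buffer-gas number density N at the drift-tube conditions,
Ω ∝ z e (k_B T)^(-1/2) (1/m_i + 1/m_b)^(1/2) / (K N). The textbook form
often carries 760/P and T/273.15 standardization factors together with the
number density at standard conditions; the two forms are algebraically
identical, and the implementation evaluates the reduced one. Unless
overridden, N follows the ideal-gas law from the stated pressure and
temperature, which keeps P and N mutually consistent by construction. A
sanity anchor: 25 ms arrival over 78 cm at 18 V/cm, 4 Torr, 298 K for a
322.5 Da singly charged ion gives 252.6 Å² (K₀ ≈ 0.84 cm²/V·s), typical of
a small tryptic peptide.

## Ion–gas interaction potential

The drift gas is a single isotropic polarizable site. For a probe at x,

V(x) = Σ_a ε_a [(r*_a/r_a)¹² − 2 (r*_a/r_a)⁶] − (k_C α/2) |Σ_a q_a r̂_a/r_a²|²,

in kcal/mol with k_C = 332.0637 kcal·Å/(mol·e²). N₂ is modeled with mass
28.0134 Da and polarizability 1.710 Å³; He (0.205 Å³) is included as a
validation gas. Per-element (ε, r_min) pairs live in a versioned parameter
file following the published trajectory-method N₂/He parameterization
lineage. The N₂ quadrupole and anisotropy are deliberately out of scope:
absolute agreement with production trajectory-method codes is therefore not
expected, and every accuracy claim in the test suite is made against
internal oracles (quadrature integrals, analytic limits), not against
external codes. Gradients are analytic and verified against central
differences at 1e-5 relative.

## Trajectory-method engine

Ω(1,1)(T) is computed as a thermal average of the momentum-transfer cross
section. Numerical choices:

- **Speed quadrature.** Substituting u = μg²/(2k_BT) makes the thermal
  weight exactly u² e^(−u); generalized Gauss–Laguerre (α = 2) nodes
  integrate it without further transformation. Default 20 nodes. The reduced
  mass μ enters the thermal weight; the scattering itself propagates a gas
  pseudo-atom of mass m_b in the frozen ion's potential (for peptide-sized
  ions μ ≈ m_b within a few percent).
- **Impact parameters.** b_max is found by a doubling-plus-bisection search
  for the smallest b with |χ| < 1e-3 rad at the lowest quadrature speed,
  probing several random approach directions; b is then sampled
  area-uniformly in [0, b_max], stratified in b² per speed node. The strata
  leave the marginal distribution uniform but cut the Monte-Carlo variance
  of Q(g) by an order of magnitude.
- **Orientations.** Uniform random approach directions (equivalent to
  uniform ion rotations). The configuration retains an `n_rotations` field
  for provenance compatibility, but with an isotropic single-site gas there
  is no potential to orientation-average, so it does not enter the
  computation.
- **Integrator.** Velocity Verlet with a per-trajectory adaptive step:
  free flight covers a fixed fraction of the distance to the nearest ion
  atom, a force-based term takes over near the ion, and a per-step
  energy-error check (5e-7 of the incoming kinetic energy) halves the step
  on violation. Because Verlet's energy error is oscillatory rather than
  secular, bounding the per-step change keeps the end-to-end drift well
  inside the 1e-4 relative guarantee; the worst drift over all trajectories
  is measured and reported in every result. Trajectories that fail to exit
  within the step budget are flagged as orbiting and enter the integrand as
  χ = π; results carry the orbiting fraction, with a warning above 1%.
- **Seeding.** One master seed spawns independent per-cycle streams
  (`numpy` SeedSequence), so results are bit-reproducible and growing
  n_cycles does not reshuffle earlier cycles. The CCS is the mean over
  cycles; the standard error is the between-cycle standard deviation over
  √n_cycles.
- **Canonicalization.** Geometries are recentred and rotated to principal
  axes with sign conventions fixed by coordinate skewness, so rigidly
  transformed inputs give identical results for a shared seed.

Defaults (10 cycles, 20 speed nodes, 500 draws per cycle and node, 298.0 K)
mirror the standard production configuration of high-performance
trajectory-method codes. Validation reduces these sizes (e.g. 5/16/400 for
the single-site oracle comparison) because the stratified sampler reaches
~0.1% standard error there, which is ample against the 1% test band.

The engine is validated three ways: (i) per-trajectory deflection angles
match an independent one-dimensional central-potential deflection integral
to ~1e-4 rad; (ii) the full Ω(1,1) for a neutral Lennard-Jones site matches
a dense deterministic double quadrature to ~0.1%; (iii) a steep repulsive
power-law core (r^(−300)) reproduces the hard-sphere limit πR² within 2%,
where R is the turning radius at the thermal energy scale (a pure 12-6
potential cannot reach this limit, as its core softens together with its
well when ε → 0).

## Projection approximation

Per-atom collision radii are r_min(element, gas)/2 plus a gas hard radius
(1.85 Å for N₂, 1.15 Å for He, recorded with the parameter table). Shadow
areas are Monte-Carlo integrated over a covering disc per orientation;
uncertainty is the spread over orientations. PA is charge-blind and serves
as a lower-fidelity cross-check: for ions with attractive wells the
trajectory method should and does exceed it.

## Ensemble reduction and Boltzmann weighting

Pairwise RMSD uses optimal proper rotation (SVD/Kabsch, no reflection) on
heavy atoms by default — hydrogen positions are the most basis-set-sensitive
part of a DFT geometry. The residual is evaluated from explicitly rotated
coordinates to avoid catastrophic cancellation for near-identical
structures. The affinity graph keeps each conformer's 15 nearest neighbours
(union-symmetrized) with Gaussian weights at kernel width = median retained
RMSD, and is partitioned by seeded Louvain modularity. The sparsification
matters: on a dense all-pairs affinity graph, modularity's resolution limit
merges small conformational families (recovering ~8 where 24 were planted
in a 1000-conformer pool), while the k-NN graph recovers planted partitions
exactly across the tested seed range. Each family is represented by its
medoid (the member minimizing summed RMSD to the rest).

Boltzmann weighting uses electronic energies only (no zero-point or thermal
corrections), a 3.0 kcal/mol window whose boundary is inclusive, and a
weighting temperature of 298.0 K (k_BT = 0.59219 kcal/mol) — the same
temperature as the collision-integral default; both are configurable.
Ensemble standard errors propagate as √(Σ w_i² se_i²), which assumes
independent member estimates (true here: members are computed with distinct
seeds).

## Reference data and evaluation rules

The packaged tables carry the experimental drift-tube CCS of 23 tryptic
peptides (3–14 residues, [M+H]⁺, N₂) and computed Boltzmann-weighted CCS at
five DFT levels. Only raw CCS values are stored; percent errors are always
recomputed, because one printed parenthetical in the source of the
uncorrected column (AWSVAR) is inconsistent with its own CCS cells (290.00
vs 255.70 is 13.4%, not 11.8%) — recomputing also reproduces the printed
column average of 8.8%. Means and standard deviations (sample, n−1) are
taken on unrounded errors; the 3% success classification alone evaluates
the error at the tables' printed one-decimal precision, which is required to
reproduce the published success counts (one best-variant error of 3.011%
prints as 3.0 and is counted a success). Variant selection breaks exact
ties toward the first-listed method; no ties occur in the shipped data.

## Synthetic fixtures

- **Polyglycine chains** are built from ideal internal coordinates (natural
  extension reference frame) with extended (φ = ψ = 180°) or α-helical
  (−57°, −47°) backbones; the extended form runs ≈3.63 Å per residue end to
  end. Protonation adds a third N-terminal hydrogen and smears +1 e evenly
  over the ammonium group (0.25 e on N and each H) — a documented toy
  scheme, explicitly not a population-analysis surrogate. Termini are
  role-annotated for the N-to-C compactness metric.
- **Toy ions** (single atom, rigid dimer, charged dipole probe) have exact
  coordinates for analytic oracle tests.
- **Planted ensembles** perturb one compact self-avoiding chain into k
  templates (resampled until all template pairs exceed the requested
  superposed-RMSD separation), jitter members around templates (member-to-
  template RMSD ≈ the requested within-spread, so member–member pairs sit
  near √2× that), hand every member a random rigid pose, and attach either
  iid U[0,6] kcal/mol energies or basin energies (cluster offset U[0,6] plus
  U[0,0.5] intra-cluster noise). Default scales (0.3–0.4 Å within, 2 Å
  between, ~40 heavy atoms) reflect what RMSD clustering of
  conformer-generator output for small peptides typically encounters.

What the synthetic fixtures do **not** emulate: real conformer ensembles
have continuous, anisotropic density between basins, correlated energy/
geometry structure, and hydrogen-bond-driven substates. Passing the planted-
partition tests therefore shows the clustering machinery is correct, not
that any particular resolution is optimal for a given real peptide.

## Known limitations

- Single-site isotropic N₂ (no quadrupole, no anisotropic polarizability):
  absolute TM values will deviate from production codes that include them;
  trends and all internally validated properties are unaffected.
- Classical trajectories only; no quantum or inelastic corrections.
- Boltzmann weighting ignores entropy (free-energy weighting is a non-goal).
- The Mulliken-style charge sensitivity of the TM is a feature of the model,
  not an endorsement of any particular charge scheme.
- Heavy-tailed Monte-Carlo variance for charged ions: close encounters with
  charged sites dominate the integrand's tail, so small sampling
  configurations carry standard errors of several percent. The reported
  between-cycle standard error tracks this honestly; tighten it by raising
  `n_mc_per_cycle`/`n_cycles`.
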