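# Methods

This note records the models, parameter choices and numerical decisions
behind `polyxtal`, and what the shipped toy systems do and do not probe.

## The alchemical path and its potential

The simulation state is one molecule (the asymmetric unit, Z′ = 1) with
Cartesian coordinates **x**, a unit cell, a space group, and a coupling
λ ∈ [0, 1].  The potential is

U(λ, **x**) = U_bonded(**x**) + U_intra(**x**) + U_inter(λ, **x**),

where the bonded terms (harmonic bonds k_b(b−b0)², harmonic angles
k_θ(θ−θ0)², cosine torsion series ΣA(1+cos(nφ−δ))) and the
intramolecular nonbonded interactions (1-2/1-3 excluded, 1-4 scaled by
0.5) are independent of λ: the λ = 0 endpoint is an intact molecule in
vacuum.  Only interactions between the asymmetric unit and its symmetry
mates and periodic images are alchemically scaled.

**Van der Waals.**  Buffered 14-7 form,
u(ρ) = ε (1.07/(ρ+0.07))⁷ (1.12/(ρ⁷+0.12) − 2) with ρ = r/r0
(arithmetic-mean r0, geometric-mean ε combination).  The softcore
substitutes ρ⁷ → α(1−λ)² + ρ⁷ inside the expression and multiplies by
λⁿ.  Defaults α = 0.7, n = 5.  This is a standard endpoint-correct
choice for alchemical vdW decoupling: at λ = 1 the plain potential is
recovered exactly; at λ = 0 the term vanishes with ∂U/∂λ = 0 (n ≥ 2);
at intermediate λ the r → 0 singularity is removed.  One consequence
worth knowing: at small λ the softcore-deformed well can turn a purely
repulsive contact weakly attractive (observed magnitude ~1e-4 ε-scale),
so U(λ) on a clashing state is monotone only beyond the
softcore-dominated region.

**Electrostatics.**  Damped-shifted-force (Wolf-style) point charges:
u(r) = Cq_iq_j[erfc(ar)/r − erfc(aR_c)/R_c + F_shift·(r−R_c)] with
damping a = 0.2 Å⁻¹ and the force-shift constant chosen so both the
energy and force vanish at the cutoff.  This surrogate replaces
reciprocal-space lattice summation; it is selectable off
(`use_electrostatics=False`).  Its own softcore replaces
r → √(r² + α_e(1−λ)²), α_e = 1 Å², and the pair carries the same λⁿ
prefactor.

**Cutoffs.**  12 Å with a quintic C¹ switching window over the final
1 Å, applied to both terms.  Cells thinner than twice the cutoff are
handled by summing over every periodic image within range (equivalent
to an internal minimum-image replication); there is no silent
truncation.  Because the image sum is exhaustive rather than folded,
the per-molecule energy of an ASU-symmetric evaluation, its P1
expansion and any supercell replication agree to machine precision —
the representation-equivalence tests assert 1e-6 kcal/mol across all
15 groups.

**Derivatives.**  The OST bias force on coordinates needs ∂²U/∂λ∂x and
the λ-force needs ∂²U/∂λ² (through ∂F_λ/∂λ).  All pair-term derivatives
(∂u/∂r, ∂u/∂λ, ∂²u/∂λ∂r, ∂²u/∂λ²) are generated symbolically from the
closed forms once per parameter set and evaluated as vectorized
expressions, so they are exact; the test suite confirms agreement with
central finite differences to 1e-6.

**Units.**  kcal/mol, Å, fs, amu, degrees, g/cm³, atm;
k_B = 1.987204×10⁻³ kcal/mol/K; 1 atm·Å³ = 1.4584×10⁻⁵ kcal/mol;
Coulomb constant 332.063713 kcal·Å/mol/e².

## Space groups

The 15 groups most frequent among deposited organic crystal structures
(P1, P1̄, P2₁, C2, Cc, P2/c, P2₁/c, C2/c, P2₁2₁2₁, Pca2₁, Pna2₁, Pbcn,
Pbca, Pnma, and the rhombohedral R3̄ in its hexagonal setting) are
stored as an internal table of general-position coordinate triplets,
parsed at import.  The table is validated once against an independent
symmetry library (gemmi) in the tests — operator-by-operator equality,
group closure, and multiplicity — so the package carries no runtime
symmetry dependency.  The stored CSD occurrence weights are approximate
percentages used only to order groups and apply the 0.5% search cutoff.
Only general positions are supported (no special Wyckoff sites, Z′ = 1).

Free lattice parameters per lattice system are derived from the
constraint sets: triclinic 6, monoclinic 4 ({a, b, c, β}; unique axis
b, α = γ = 90°), orthorhombic 3, tetragonal 2, rhombohedral 2,
hexagonal 2, cubic 1.  Published tabulations sometimes print 5 and 4
for monoclinic and orthorhombic by counting differently; this package
uses the constraint-implied counts throughout, and its barostat and
minimizer sample exactly these parameters.

## Orthogonal space tempering

The bias grid spans λ ∈ [0, 1] with 0.005-wide bins and an F_λ axis of
2 kcal/mol bins that starts at ±100 kcal/mol and doubles outward on
demand (expansion preserves deposited bias bit-exactly).  Hills are
2D Gaussians with widths equal to two bins (w₁ = 0.01, w₂ = 4 kcal/mol)
snapped to bin centers on deposition and truncated after five bins
during evaluation; evaluation is the smooth analytic sum, so the bias
energy and its partials are exact derivatives of each other.  The
initial hill height is 0.05 kcal/mol, deposited every 10 MD steps.

Transition tempering: the coverage statistic V(t) reduces the 2D
histogram to min over λ of the max over F_λ, and once V(t) exceeds
V_th = 1 kcal/mol, hills shrink as h(t) = h(t₀)·exp(−(V−V_th)/(ΔT·k_BT))
with ΔT = 2 k_BT — so the entire path must be lightly covered before
tempering begins, and hill heights are nonincreasing from then on.

The 1D bias is accumulated by thermodynamic integration:
per-λ-bin averages of F_λ are collected with reweighting factors
e^{βg_m} that undo the 2D bias, and
f_m(λ) = −∫₀^λ ⟨F_λ′⟩ dλ′ (trapezoid over bins, f_m(0) = 0).  The sign
makes f_m a bias that flattens the λ-marginal; the free-energy profile
estimate is −f_m.  Unvisited bins inherit the average of their nearest
visited neighbors.  On the analytic λ-well fixture (closed-form
ΔG = −3 kcal/mol behind a 5 kcal/mol barrier) the sampler recovers ΔG
to a few 1e-4 kcal/mol in 1.5×10⁵ steps and the biased λ-marginal is
uniform to within ~15%.

Multiple walkers are independent by default; their grids can be merged
additively from JSON checkpoints.

## NPT dynamics

Coordinates follow a BAOAB-splitting Langevin integrator (1 fs
timestep, 10 ps⁻¹ friction, both configurable).  λ is propagated as an
auxiliary Langevin particle through θ with λ = sin²θ: the mapping
bounds λ smoothly (dλ/dθ = sin 2θ vanishes at both endpoints, no
reflection logic), and the θ-force collects
∂U/∂λ + ∂bias/∂λ + (∂bias/∂F_λ)·∂²U/∂λ² by the chain rule.  The
fictitious θ-mass defaults to 5 amu·Å², which on the toy systems gives
λ round trips on the 10–100 ps scale.  With the bias disabled the
λ-propagator reproduces the Boltzmann distribution of a restraining
potential (checked against closed-form weights).

The Monte Carlo barostat attempts one move per MD step with probability
1/10 (a trial every 10 steps on average).  A move picks one free
lattice degree of freedom uniformly at random.  Axis moves change the
explicit-unit volume by ΔV = v_max(2x−1) (v_max = 1 Å³) by scaling the
chosen axis group (a single axis for triclinic/monoclinic/orthorhombic;
tied groups in tandem otherwise).  Angle moves change the chosen angle
group by a_max(2x−1) (a_max = 0.5°) and then rescale all lengths
uniformly so the volume is unchanged.  Constrained parameters are never
touched, so constraints hold exactly after any number of moves.
Acceptance uses ΔE = ΔU + pΔV − n_molecules·k_BT·ln(V′/V) on
asymmetric-unit volumes; proposals outside the density band
(0.75–1.6 g/cm³) are rejected before any energy evaluation.  The
ideal-gas stationary distribution π(V) ∝ Vⁿe^{−βpV} (mean
(n+1)k_BT/p) is the closed-form correctness check; the acceptance suite
verifies it to within three block-averaged standard errors.  Density
bounds also mean a walker initialized inside the band never leaves it.

Walkers start from a random cell and rigid-body placement: density
uniform in the band fixes the volume, free angles uniform in
[60°, 120°], free length ratios uniform in [0.7, 1.4] before scaling,
molecular orientation from a uniform random quaternion, fractional
center of mass uniform, λ = 0.  Snapshots are checked every 10 ps
(configurable) and saved when λ > 0.8 and the energy after a local
minimization to rms gradient 0.1 kcal/mol/Å lies within 10 kcal/mol of
the best minimized energy seen so far.

Search temperature and pressure default to 298.15 K and 1 atm; the
timestep and friction defaults are package choices, documented here
rather than inherited from any reference.

## Minimization

L-BFGS-B over the Cartesian coordinates plus the free lattice
parameters, using the same constrained parameterization as the
barostat (constraints preserved by construction).  Coordinate gradients
are analytic; lattice gradients use 5-point central differences of the
analytic energy (step 1e-4, relative), since an analytic cell gradient
is not needed anywhere else.  Invalid cells proposed by a line search
return a large penalty, and bounds keep lengths ≥ 0.8 Å and angles in
[20°, 160°].  Convergence is declared when the rms over all minimized
gradient components reaches the target; two presets are shipped,
"search" (0.1 kcal/mol/Å, used inside the walker) and "posthoc"
(0.03 kcal/mol/Å, the filtering criterion).  λ is forced to 1.

## Packing comparison and clustering

rmsd_N extracts, from each crystal, shells of the N molecules nearest a
central molecule (the crystal is expanded to P1 and replicated until
shells fit; the five lowest-Rg shells are kept as central-molecule
candidates).  Two shells are compared by prealigning on the central
molecule (Kabsch over heavy atoms), greedily matching the remaining
molecules by center-of-mass distance, and running a final Kabsch over
all matched heavy atoms; both greedy directions are evaluated, making
the result symmetric, and the minimum over candidate pairs is returned.
This is a documented simplification of packing-shell comparison
algorithms of the COMPACK family: it is validated by its contract
properties (identity, lattice-translation invariance, symmetry,
small-shell exhaustive-correspondence oracles), not by claimed
equivalence to any published implementation.  Hydrogens are excluded;
N defaults to 20.

Filtering keeps snapshots with density above 1.25 g/cm³ and minimized
energy within 10 kcal/mol of the most stable.  Clustering repeatedly
picks a random unclustered seed and absorbs everything within the
cutoff until all structures are assigned, restarts 1000 times, and
keeps the trial with the fewest clusters (ties: first occurrence under
the seeded order).  Two named cutoff presets exist, 0.5 Å (duplicate
removal) and 1.5 Å (coarse promotion-stage screening); the match
categories against a reference are ≤1.0 Å "match", ≤1.5 Å
"promotable", otherwise "miss".

## Toy systems: what they show and what they cannot

The fixtures define the package's study conditions:

* **LJ monatomic** (ε = 0.238 kcal/mol, r0 = 3.82 Å, mass 30 amu —
  argon-like well, mass chosen so close packing falls inside the
  density band at ~1.36 g/cm³).  One atom in P1 exercises the barostat,
  the walker and the end-to-end search; its global packing optimum is
  computable by brute force on a documented rhombohedral grid
  (a = b = c ∈ [3.40, 4.30] Å step 0.005; α = β = γ ∈ {55, 60, 65, 75,
  90, 109.47}°; degenerate points skipped), which contains the
  face-centered-cubic optimum (α = 60°) the continuum minimizer finds.
* **Rigid planar ring** (6 carbons, alternating ±0.15 e charges, bonds
  and angles at their construction equilibrium, no torsions): exercises
  bonded terms, electrostatics and all symmetry machinery with a
  molecule large enough to be orientation-sensitive.
* **Analytic λ-well** U(λ) = ΔG·λ²(3−2λ) + B·16λ²(1−λ)²: with no
  coordinate degrees of freedom its free-energy profile is U(λ)
  itself, so OST recovery can be checked against an exact closed form.

These fixtures deliberately omit features of real molecular crystals:
conformational flexibility coupled to packing, permanent multipoles and
polarization, competing near-degenerate polymorphs, and Z′ > 1.
Passing tests therefore demonstrate that the sampling, biasing,
barostat and reduction machinery are statistically and mechanically
correct, not that the surrogate force field ranks real polymorphs
accurately — force-field accuracy is exactly the part this package
replaces with a surrogate.  Problem sizes in the acceptance runs
(10⁵-trial barostat chains, ~10⁵-step OST runs, 1–2 walkers of
1.5–2×10⁴ steps) were chosen as the smallest that make the statistical
assertions sharp.

## Known limitations

* Z′ = 1 general positions only; 15 space groups, not 230.
* The surrogate omits multipoles, induced dipoles and reciprocal-space
  electrostatics; no bond–angle cross-terms or out-of-plane bending.
* rmsd_N's greedy correspondence can overestimate the true minimal
  rmsd for badly mismatched shells (it is exact on the fixtures'
  small-shell oracles and reliable for the near-duplicate regime the
  clustering cutoff operates in).
* The barostat assumes isotropic pressure; no constant-stress
  (cell-shear) dynamics.
* Quantum-chemical rescoring of survivors is out of scope.
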