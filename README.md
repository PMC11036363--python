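# polyxtal

Crystal polymorph search through an alchemical path that connects an
isolated vacuum molecule to a fully coupled molecular crystal inside the
NPT ensemble.

Organic molecules often crystallize in several distinct packings
(polymorphs), and which polymorph a drug substance adopts controls its
solubility and stability.  Exhaustively searching the packing landscape
is hard: candidate structures are separated by high barriers in both
molecular conformation and lattice geometry.  `polyxtal` implements a
search strategy built for this problem, at desk scale, for computational
chemists and method developers who want every stage of such a pipeline
as tested, composable Python:

* **Alchemical vacuum–crystal path.**  A coupling parameter λ scales the
  interactions between the asymmetric unit and its symmetry mates: at
  λ = 0 the molecule is an isolated vacuum molecule, at λ = 1 a fully
  interacting crystal.  Softcore potentials keep the path smooth and the
  endpoints exact.
* **Orthogonal space tempering (OST).**  A second-order generalized
  ensemble bias deposits repulsive 2D Gaussian hills over (λ, F_λ)
  with F_λ = ∂U/∂λ, flattening barriers both along the path and
  perpendicular to it.  Hill heights decay exponentially (transition
  tempering) once a coverage statistic V(t) = min_λ max_{F_λ} g_m
  exceeds a threshold; a 1D bias f_m(λ) is accumulated by thermodynamic
  integration of the biased ⟨F_λ⟩, and −f_m is the running estimate of
  the deposition free-energy profile ΔG(λ).
* **Lattice-constrained Monte Carlo barostat.**  Trial moves perturb one
  free lattice parameter at a time (ΔV = v_max(2x−1) for an axis,
  Δα = a_max(2x−1) for an angle, volume restored by uniform rescaling)
  and are accepted by the Metropolis rule on
  ΔE = ΔU + pΔV − n·k_B·T·ln(V′/V).  The constraints of all seven
  lattice systems (triclinic … cubic) hold exactly, by construction.
* **Space-group asymmetric-unit energetics.**  Energies, forces, ∂U/∂λ
  and ∂²U/∂λ∂x are evaluated for a single asymmetric unit interacting
  with its symmetry mates and periodic images; the per-molecule energy
  is identical to that of the expanded P1 crystal or any replicated
  supercell.  Fifteen space groups covering >0.5% of deposited CSD
  organic structures are shipped.
* **Candidate reduction.**  Snapshots (saved when λ > 0.8 and the
  locally minimized energy is within 10 kcal/mol of the best so far) are
  minimized, filtered by density (>1.25 g/cm³) and energy window
  (≤10 kcal/mol), compared by packing similarity rmsd_N (optimal
  superposition of N-molecule shells, N = 20 by default), and
  de-duplicated by iterative minimum-cluster-count clustering
  (0.5 Å cutoff, best of 1000 restarts).

The potential is a surrogate pairwise force field — buffered 14-7 van
der Waals with an alchemical softcore and damped-shifted-force point
charges — carrying the same alchemical and statistical machinery as a
polarizable-force-field implementation, at a cost that runs on one CPU.

## Worked example

Search the one-atom Lennard-Jones-like toy crystal in P1 and compare
against the brute-force lattice-grid optimum:

```
$ polyxtal make-fixtures fixtures
$ polyxtal thermodynamics-search fixtures/lj_monatomic.params \
      --space-group P1 --steps 12000 --seed 1 \
      --snapshot-stride-ps 0.5 --out search
walker 0: 11 snapshots, 1154/1164 barostat moves
wrote 11 snapshots to search

$ head -3 search/index.tsv
file    energy  density lam     step
snapshot_00000.cif      -1.8321481766168373     1.3625997526753906      0.8559515458977802      500
snapshot_00001.cif      -1.8321607094382444     1.3626281516032432      0.8934298044566781      2000

$ polyxtal minimize-crystals search/snapshot_00000.cif \
      --params fixtures/lj_monatomic.params --out min
snapshot_00000.cif      -1.832148       0.0001084       1.3626  ok
```

The walker starts from a random cell and rigid-body placement at λ = 0,
wanders to the coupled crystal under the OST bias, and saves candidate
packings; each index row holds the locally minimized energy (kcal/mol
per molecule), the density (g/cm³), the coupling at the time of saving,
and the MD step.  The snapshots here sit at −1.83215 kcal/mol with
density 1.363 g/cm³ — the face-centered-cubic packing.  The independent
check is an exhaustive scan of the rhombohedral lattice slice:

```python
>>> from polyxtal.fixtures import make_lj_monatomic, lattice_grid_minimum
>>> e, cell = lattice_grid_minimum(make_lj_monatomic())
>>> print(f"{e:.6f} kcal/mol at a={cell.a:.3f} Å, alpha={cell.alpha:.1f} deg")
-1.832160 kcal/mol at a=3.725 Å, alpha=60.0 deg
```

The search recovers the global minimum to better than 1e-5 kcal/mol.
`polyxtal filter`, `polyxtal superpose-crystals`, `polyxtal cluster` and
`polyxtal report` drive the downstream reduction stages; see
`polyxtal --help`.

## Layout

| module | contents |
| --- | --- |
| `polyxtal.cell` | triclinic cells, fractional↔Cartesian, minimum-image factors |
| `polyxtal.symmetry` | space-group operator table, lattice systems, free-parameter accounting |
| `polyxtal.topology` | molecule parameters and the plain-text parameter file |
| `polyxtal.crystal` | `CrystalState`, ASU↔P1↔supercell conversions, density |
| `polyxtal.energy` | surrogate potential, softcore alchemy, analytic λ-derivatives |
| `polyxtal.ost` | bias grid, hill deposition, tempering, coverage, 1D bias |
| `polyxtal.dynamics` | BAOAB Langevin + λ-dynamics, MC barostat, walkers |
| `polyxtal.minimize` | constrained local minimization of coordinates + lattice |
| `polyxtal.compare` | packing shells, rmsd_N, filtering, clustering, reports |
| `polyxtal.fixtures` | deterministic toy systems and analytic λ-potentials |
| `polyxtal.io`, `polyxtal.config`, `polyxtal.cli` | XYZ/CIF/TSV/TOML formats and the command line |
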