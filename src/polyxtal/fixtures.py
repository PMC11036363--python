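"""Deterministic toy systems exercising every stage of the pipeline.

These generators are first-class, tested code: they define the study
conditions for the statistical checks (barostat distributions, bias
convergence, end-to-end searches) without any external input.  All
parameters are fixed, documented values; regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell import UnitCell
from .crystal import CrystalState
from .energy import AlchemicalParams, total_potential
from .symmetry import get_space_group
from .topology import MoleculeTopology

__all__ = [
    "ToySystem",
    "AnalyticLambdaWell",
    "make_lj_monatomic",
    "make_rigid_ring",
    "make_analytic_lambda_well",
    "lattice_grid_minimum",
]


@dataclass
class ToySystem:
    """A generated toy molecule plus its documented reference values."""

    topology: MoleculeTopology
    description: str
    reference: dict = field(default_factory=dict)
    seed: int = 0

    def crystal(self, cell: UnitCell, space_group: str = "P1",
                lam: float = 1.0, coords: np.ndarray | None = None) -> CrystalState:
        if coords is None:
            ref = self.reference.get("coords")
            coords = ref.copy() if ref is not None else np.zeros((self.topology.n_atoms, 3))
        return CrystalState(self.topology, coords, cell,
                            get_space_group(space_group), lam)


def make_lj_monatomic(eps: float = 0.238, r0: float = 3.82,
                      mass: float = 30.0) -> ToySystem:
    """A single neutral van der Waals atom (argon-like well depth and size,
    mass chosen so close packing falls inside the 0.75-1.6 g/cm³ search
    band).  No bonded terms; 3 degrees of freedom."""
    top = MoleculeTopology(["Ar"], [mass], [eps], [r0], [0.0])
    return ToySystem(
        top,
        f"Lennard-Jones-like monatomic (buffered 14-7, eps={eps}, r0={r0})",
        reference={"eps": eps, "r0": r0, "mass": mass},
    )


def make_rigid_ring(n_atoms: int = 6, charge: float = 0.15,
                    bond_k: float = 400.0, angle_k: float = 80.0) -> ToySystem:
    """A planar ring with alternating point charges.

    Bond lengths and angles are at their equilibrium values in the
    construction geometry (bonded energy is exactly zero there); no
    torsion terms, so the fixture exercises electrostatics and vdW with
    torsions off.  `n_atoms` must be even for net neutrality.
    """
    if n_atoms % 2:
        raise ValueError("ring size must be even for a neutral molecule")
    radius = 1.4 / (2.0 * math.sin(math.pi / n_atoms))
    ang = 2.0 * math.pi * np.arange(n_atoms) / n_atoms
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                              np.zeros(n_atoms)])
    coords -= coords.mean(axis=0)
    b0 = float(np.linalg.norm(coords[0] - coords[1]))
    theta0 = math.degrees(math.pi * (n_atoms - 2) / n_atoms)
    charges = charge * np.where(np.arange(n_atoms) % 2 == 0, 1.0, -1.0)
    top = MoleculeTopology(
        ["C"] * n_atoms,
        np.full(n_atoms, 12.011),
        np.full(n_atoms, 0.10),
        np.full(n_atoms, 3.80),
        charges,
        bonds=[(i, (i + 1) % n_atoms, bond_k, b0) for i in range(n_atoms)],
        angles=[(i, (i + 1) % n_atoms, (i + 2) % n_atoms, angle_k, theta0)
                for i in range(n_atoms)],
    )
    sys = ToySystem(
        top,
        f"planar {n_atoms}-ring with alternating ±{charge} e charges",
        reference={"b0": b0, "theta0": theta0, "coords": coords},
    )
    return sys


@dataclass
class AnalyticLambdaWell:
    """A pure λ-potential with closed-form free-energy difference.

    U(λ) = ΔG·λ²(3−2λ) + B·16λ²(1−λ)²  — a smoothstep connecting 0 to
    ΔG with a barrier of height ≈ B at λ = 1/2.  Having no coordinate
    degrees of freedom, its free-energy profile equals U(λ) itself, so
    thermodynamic integration of ∂U/∂λ must recover ΔG exactly; it
    plugs into the λ-sampler in place of the crystal energy.
    """

    delta_g: float = -3.0  # kcal/mol
    barrier: float = 5.0  # kcal/mol

    def energy(self, lam: float) -> float:
        return self.delta_g * lam**2 * (3 - 2 * lam) + self.barrier * 16 * lam**2 * (1 - lam) ** 2

    def dU_dlam(self, lam: float) -> float:
        return (self.delta_g * 6 * lam * (1 - lam)
                + self.barrier * 32 * lam * (1 - lam) * (1 - 2 * lam))

    def d2U_dlam2(self, lam: float) -> float:
        return (self.delta_g * 6 * (1 - 2 * lam)
                + self.barrier * 32 * (1 - 6 * lam + 6 * lam**2))

    @property
    def closed_form_delta_g(self) -> float:
        return self.energy(1.0) - self.energy(0.0)


def make_analytic_lambda_well(delta_g: float = -3.0,
                              barrier: float = 5.0) -> AnalyticLambdaWell:
    """Analytic λ-well fixture (ΔG and barrier in kcal/mol)."""
    return AnalyticLambdaWell(delta_g, barrier)


def lattice_grid_minimum(
    system: ToySystem,
    a_grid: np.ndarray | None = None,
    alpha_grid: np.ndarray | None = None,
    params: AlchemicalParams | None = None,
) -> tuple[float, UnitCell]:
    """Brute-force global minimum of the monatomic P1 lattice energy over a
    documented rhombohedral grid (a = b = c, α = β = γ).

    The close-packed minima of a one-atom P1 crystal lie on this slice
    (face-centered cubic is a = b = c with 60° angles).  Default grid:
    a ∈ [3.40, 4.30] Å step 0.005, α ∈ {55, 60, 65, 75, 90, 109.47}°.
    Bit-exact under a fixed grid; geometrically degenerate grid points
    are skipped.
    """
    params = params or AlchemicalParams()
    if a_grid is None:
        a_grid = np.round(np.arange(3.40, 4.3001, 0.005), 6)
    if alpha_grid is None:
        alpha_grid = np.array([55.0, 60.0, 65.0, 75.0, 90.0, 109.47])
    best = (math.inf, None)
    coords = np.zeros((system.topology.n_atoms, 3))
    for alpha in alpha_grid:
        for a in a_grid:
            try:
                cell = UnitCell(a, a, a, alpha, alpha, alpha)
                st = CrystalState(system.topology, coords, cell,
                                  get_space_group("P1"), 1.0)
                e = total_potential(st, params).total
            except (ValueError, FloatingPointError):
                continue
            if e < best[0]:
                best = (float(e), cell)
    return best
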