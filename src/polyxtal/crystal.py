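"""Crystal states: an asymmetric unit plus cell, space group and coupling λ.

A `CrystalState` carries one molecule in the asymmetric unit (Z' = 1),
its Cartesian coordinates, the unit cell, the space group, and the
alchemical coupling λ in [0, 1] (0 = isolated vacuum molecule, 1 =
fully coupled crystal).  P1 expansions represent every molecule
explicitly; the per-molecule energy of the two representations is
identical (see the energy module).

Coordinates are Cartesian Å everywhere; fractional coordinates appear
only at conversion boundaries and are never wrapped during dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cell import UnitCell
from .symmetry import SpaceGroup, get_space_group
from .topology import MoleculeTopology

__all__ = ["CrystalState", "expand_to_p1", "replicate_cell", "count_dof"]

# amu/Å³ -> g/cm³
_DENSITY_FACTOR = 1.66053906892


@dataclass
class CrystalState:
    """One asymmetric unit in a space-group crystal at coupling λ."""

    topology: MoleculeTopology
    coords: np.ndarray  # (n_molecules * n_atoms, 3) Cartesian Å
    cell: UnitCell
    space_group: SpaceGroup
    lam: float = 1.0
    n_molecules: int = 1  # molecules carried explicitly (1 for an ASU state)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        expected = self.n_molecules * self.topology.n_atoms
        if len(self.coords) != expected:
            raise ValueError(
                f"coordinate count {len(self.coords)} != "
                f"{self.n_molecules} molecules x {self.topology.n_atoms} atoms"
            )
        if self.n_molecules != 1 and self.space_group.multiplicity != 1:
            raise ValueError("multi-molecule states must be in P1")

    @property
    def total_molecules(self) -> int:
        """Molecules in the full unit cell (explicit x symmetry multiplicity)."""
        return self.n_molecules * self.space_group.multiplicity

    @property
    def density(self) -> float:
        """Crystal density in g/cm³."""
        mass = self.topology.molecular_mass * self.total_molecules
        return _DENSITY_FACTOR * mass / self.cell.volume

    @property
    def asu_volume(self) -> float:
        """Volume per molecule (the asymmetric-unit volume), Å³."""
        return self.cell.volume / self.total_molecules

    def molecule_coords(self, m: int) -> np.ndarray:
        n = self.topology.n_atoms
        return self.coords[m * n:(m + 1) * n]

    def molecule_com(self, m: int) -> np.ndarray:
        x = self.molecule_coords(m)
        w = self.topology.masses / self.topology.molecular_mass
        return w @ x

    def copy(self) -> "CrystalState":
        return replace(self, coords=self.coords.copy())


def count_dof(state_or_n_molecules, n_atoms: int | None = None) -> int:
    """Coordinate degrees of freedom: 3 x total explicit atom count.

    Accepts a CrystalState (DoF of what is explicitly simulated — the ASU
    for a symmetry-bearing state, all molecules for a P1 state) or a
    (n_molecules, n_atoms) pair.
    """
    if isinstance(state_or_n_molecules, CrystalState):
        s = state_or_n_molecules
        return 3 * s.n_molecules * s.topology.n_atoms
    return 3 * int(state_or_n_molecules) * int(n_atoms)


def expand_to_p1(state: CrystalState, check_overlap: bool = True) -> CrystalState:
    """Expand a Z' = 1 symmetry-bearing state to an explicit P1 crystal.

    Each symmetry operator is applied in the fractional basis and mapped
    back to Cartesian; molecules are kept whole (no wrapping).  Molecule
    counts multiply by the group's general-position multiplicity.
    Overlapping images (closest intermolecular contact under 0.5 Å) are
    reported as a warning only — clashing states occur during the search.
    """
    if state.space_group.multiplicity == 1 and state.n_molecules >= 1:
        return state.copy()
    if state.n_molecules != 1:
        raise ValueError("expansion requires a single-molecule asymmetric unit")
    frac = state.cell.cart_to_frac(state.coords)
    blocks = []
    for op in state.space_group.operators:
        img = op.apply(frac)
        # translate the image molecule so its COM lies inside [0, 1)
        w = state.topology.masses / state.topology.molecular_mass
        com = w @ img
        img = img - np.floor(com)
        blocks.append(state.cell.frac_to_cart(img))
    coords = np.vstack(blocks)
    if check_overlap:
        # periodic minimum-image contact between the first molecule and
        # every symmetry mate
        f0 = state.cell.cart_to_frac(blocks[0])
        dmin = np.inf
        for m in range(1, len(blocks)):
            fm = state.cell.cart_to_frac(blocks[m])
            df = f0[:, None, :] - fm[None, :, :]
            df -= np.round(df)
            dc = state.cell.frac_to_cart(df.reshape(-1, 3))
            dmin = min(dmin, float(np.linalg.norm(dc, axis=1).min()))
        if dmin < 0.5:
            warnings.warn(
                f"overlapping symmetry images: closest contact {dmin:.3f} Å",
                stacklevel=2,
            )
    return CrystalState(
        topology=state.topology,
        coords=coords,
        cell=state.cell,
        space_group=get_space_group("P1"),
        lam=state.lam,
        n_molecules=state.space_group.multiplicity,
    )


def replicate_cell(p1_state: CrystalState, na: int, nb: int, nc: int) -> CrystalState:
    """Replicate a P1 crystal na x nb x nc, scaling the cell edges to match."""
    if min(na, nb, nc) < 1:
        raise ValueError("replication factors must be positive integers")
    if p1_state.space_group.multiplicity != 1:
        raise ValueError("replication requires a P1 input; expand first")
    vecs = p1_state.cell.lattice_vectors
    blocks = [
        p1_state.coords + ia * vecs[0] + ib * vecs[1] + ic * vecs[2]
        for ia in range(na)
        for ib in range(nb)
        for ic in range(nc)
    ]
    return CrystalState(
        topology=p1_state.topology,
        coords=np.vstack(blocks),
        cell=p1_state.cell.scaled((na, nb, nc)),
        space_group=p1_state.space_group,
        lam=p1_state.lam,
        n_molecules=p1_state.n_molecules * na * nb * nc,
    )
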