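"""Molecular topology: atoms, bonded terms and nonbonded parameters.

Units follow the molecular-mechanics convention used throughout the
package: kcal/mol, Angstroms, degrees, amu, elementary charges.
The plain-text parameter file format is documented in `read_parameters`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MoleculeTopology", "read_parameters", "write_parameters"]

PARAM_FILE_VERSION = "polyxtal-params 1"


@dataclass
class MoleculeTopology:
    """Atoms and force-field terms of one molecule (the asymmetric-unit content).

    Attributes
    ----------
    elements : list of str
        Element symbol per atom.
    masses, eps, r0, charges : (n,) arrays
        Atomic mass (amu), vdW well depth (kcal/mol), vdW minimum-energy
        diameter r0 (Å), partial charge (e).
    bonds : list of (i, j, k_b, b0)
        Harmonic bond i-j with force constant k_b (kcal/mol/Å², energy
        k_b·(b−b0)²) and equilibrium length b0 (Å).
    angles : list of (i, j, k, k_theta, theta0)
        Harmonic angle i-j-k, k_theta in kcal/mol/rad², theta0 in degrees.
    torsions : list of (i, j, k, l, terms)
        Cosine series: sum of A·(1 + cos(n·phi − delta)) over
        terms = [(A kcal/mol, n, delta degrees), ...].
    total_charge : int
        Declared integer net charge.
    """

    elements: list[str]
    masses: np.ndarray
    eps: np.ndarray
    r0: np.ndarray
    charges: np.ndarray
    bonds: list[tuple] = field(default_factory=list)
    angles: list[tuple] = field(default_factory=list)
    torsions: list[tuple] = field(default_factory=list)
    total_charge: int = 0

    def __post_init__(self) -> None:
        n = len(self.elements)
        for name in ("masses", "eps", "r0", "charges"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per atom")
        if abs(float(self.charges.sum()) - self.total_charge) > 1e-9:
            raise ValueError(
                f"net charge {self.charges.sum():.6g} does not match the "
                f"declared total {self.total_charge}"
            )
        for term in self.bonds + self.angles + self.torsions:
            idx = term[:2] if len(term) == 4 else term[:3] if len(term) == 5 else term[:4]
            for i in idx:
                if not 0 <= int(i) < n:
                    raise ValueError(f"bonded term references invalid atom index {i}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def molecular_mass(self) -> float:
        """Molecular mass in amu."""
        return float(self.masses.sum())

    @property
    def heavy_atom_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    def exclusion_scale(self) -> np.ndarray:
        """(n, n) intramolecular nonbonded scale factors.

        1-2 and 1-3 neighbors are excluded (0.0), 1-4 neighbors are
        half-scaled, all further pairs interact fully.  These factors apply
        only to intramolecular nonbonded interactions; symmetry-mate
        interactions are never excluded.
        """
        n = self.n_atoms
        scale = np.ones((n, n))
        np.fill_diagonal(scale, 0.0)
        adj = [set() for _ in range(n)]
        for i, j, *_ in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        for i in range(n):
            for j in adj[i]:
                scale[i, j] = 0.0
                for k in adj[j]:
                    if k != i:
                        scale[i, k] = scale[k, i] = 0.0
                        for l in adj[k]:
                            if l not in (i, j) and scale[i, l] == 1.0:
                                scale[i, l] = scale[l, i] = 0.5
        # re-zero 1-2/1-3 in case the 1-4 pass touched a ring closure
        for i in range(n):
            for j in adj[i]:
                scale[i, j] = 0.0
                for k in adj[j]:
                    if k != i:
                        scale[i, k] = scale[k, i] = 0.0
        return scale


def write_parameters(topology: MoleculeTopology, path) -> None:
    """Write the plain-text parameter file (see `read_parameters`)."""
    lines = [f"# {PARAM_FILE_VERSION}", f"total_charge {topology.total_charge}", "", "[atoms]"]
    lines.append("# element mass eps r0 charge")
    for i in range(topology.n_atoms):
        lines.append(
            f"{topology.elements[i]} {topology.masses[i]:.6f} {topology.eps[i]:.6f} "
            f"{topology.r0[i]:.6f} {topology.charges[i]:.8f}"
        )
    lines += ["", "[bonds]", "# i j k_b b0   (1-based indices)"]
    for i, j, kb, b0 in topology.bonds:
        lines.append(f"{i + 1} {j + 1} {kb:.4f} {b0:.6f}")
    lines += ["", "[angles]", "# i j k k_theta theta0"]
    for i, j, k, kt, t0 in topology.angles:
        lines.append(f"{i + 1} {j + 1} {k + 1} {kt:.4f} {t0:.6f}")
    lines += ["", "[torsions]", "# i j k l (amplitude periodicity phase)+"]
    for i, j, k, l, terms in topology.torsions:
        body = " ".join(f"{a:.4f} {int(n)} {d:.2f}" for a, n, d in terms)
        lines.append(f"{i + 1} {j + 1} {k + 1} {l + 1} {body}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameters(path) -> MoleculeTopology:
    """Read the whitespace-delimited parameter file.

    Sections ``[atoms]``, ``[bonds]``, ``[angles]``, ``[torsions]``;
    ``#`` starts a comment; atom indices are 1-based in the file.  The
    first non-blank line must be the versioned header.
    """
    with open(path) as fh:
        raw = fh.readlines()
    lines = []
    for ln, line in enumerate(raw, 1):
        body = line.split("#", 1)[0].strip() if not line.lstrip().startswith("#") else (
            line.lstrip()[1:].strip() if ln == 1 else ""
        )
        if ln == 1:
            header = line.lstrip().lstrip("#").strip()
            if header != PARAM_FILE_VERSION:
                raise ValueError(
                    f"{path}:1: expected header '# {PARAM_FILE_VERSION}', got {line.strip()!r}"
                )
            continue
        if body:
            lines.append((ln, body))

    section = None
    elements, masses, eps, r0, charges = [], [], [], [], []
    bonds, angles, torsions = [], [], []
    total_charge = 0
    for ln, body in lines:
        if body.startswith("["):
            section = body.strip("[]").lower()
            continue
        tok = body.split()
        try:
            if section is None and tok[0] == "total_charge":
                total_charge = int(tok[1])
            elif section == "atoms":
                elements.append(tok[0])
                masses.append(float(tok[1]))
                eps.append(float(tok[2]))
                r0.append(float(tok[3]))
                charges.append(float(tok[4]))
            elif section == "bonds":
                bonds.append((int(tok[0]) - 1, int(tok[1]) - 1, float(tok[2]), float(tok[3])))
            elif section == "angles":
                angles.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1,
                               float(tok[3]), float(tok[4])))
            elif section == "torsions":
                terms = [(float(tok[m]), int(tok[m + 1]), float(tok[m + 2]))
                         for m in range(4, len(tok), 3)]
                torsions.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1,
                                 int(tok[3]) - 1, terms))
            else:
                raise ValueError("line outside a recognized section")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: malformed parameter line: {body!r} ({exc})") from None
    return MoleculeTopology(
        elements, np.array(masses), np.array(eps), np.array(r0), np.array(charges),
        bonds, angles, torsions, total_charge,
    )
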