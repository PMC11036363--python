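"""Readers and writers: extended XYZ, CIF, snapshot index, similarity TSV.

All formats are plain text and round-trip the package's internal records
losslessly at float precision.  CIF files carry the cell, the symmetry
operator list and fractional atom sites (wrapped to [0, 1) on writing
only); extended XYZ carries Cartesian coordinates with a
``Lattice="ax ay az ..."`` header for P1 structures.
"""

from __future__ import annotations

import math
import re
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .cell import UnitCell
from .crystal import CrystalState
from .symmetry import get_space_group, parse_triplet
from .topology import MoleculeTopology

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_cif",
    "read_cif",
    "state_from_cif",
    "write_snapshot_index",
    "read_snapshot_index",
    "write_similarity",
    "read_similarity",
]

XYZ_VERSION = "polyxtal-xyz 1"


# ---------------------------------------------------------------------------
# extended XYZ


def write_xyz(path, frames, append: bool = False) -> None:
    """Write one or more frames of extended XYZ.

    Each frame is (elements, coords, cell_or_None, info_dict); info
    values are written as key=value in the comment line.
    """
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for elements, coords, cell, info in frames:
            coords = np.asarray(coords, dtype=float).reshape(-1, 3)
            fh.write(f"{len(coords)}\n")
            parts = [f'version="{XYZ_VERSION}"']
            if cell is not None:
                v = cell.lattice_vectors.ravel()
                parts.append('Lattice="' + " ".join(f"{x:.10g}" for x in v) + '"')
            parts.append("Properties=species:S:1:pos:R:3")
            for k, val in (info or {}).items():
                parts.append(f"{k}={val:.10g}" if isinstance(val, float) else f"{k}={val}")
            fh.write(" ".join(parts) + "\n")
            for el, xyz in zip(elements, coords):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def _cell_from_vectors(vecs: np.ndarray) -> UnitCell:
    a, b, c = (np.linalg.norm(v) for v in vecs)
    alpha = math.degrees(math.acos(np.dot(vecs[1], vecs[2]) / (b * c)))
    beta = math.degrees(math.acos(np.dot(vecs[0], vecs[2]) / (a * c)))
    gamma = math.degrees(math.acos(np.dot(vecs[0], vecs[1]) / (a * b)))
    return UnitCell(a, b, c, alpha, beta, gamma)


def read_xyz(path) -> list[tuple[list[str], np.ndarray, UnitCell | None, dict]]:
    """Read all frames of an extended-XYZ file."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected an atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        info: dict = {}
        cell = None
        for key, val in re.findall(r'(\S+?)=("[^"]*"|\S+)', comment):
            val = val.strip('"')
            if key == "Lattice":
                vecs = np.array([float(x) for x in val.split()]).reshape(3, 3)
                cell = _cell_from_vectors(vecs)
            elif key not in ("Properties", "version"):
                try:
                    info[key] = float(val)
                except ValueError:
                    info[key] = val
        elements, coords = [], []
        for ln in range(i + 2, i + 2 + nat):
            if ln >= len(lines):
                raise ValueError(f"{path}:{ln + 1}: truncated frame")
            tok = lines[ln].split()
            if len(tok) < 4:
                raise ValueError(f"{path}:{ln + 1}: malformed atom line {lines[ln]!r}")
            elements.append(tok[0])
            coords.append([float(t) for t in tok[1:4]])
        frames.append((elements, np.array(coords), cell, info))
        i += 2 + nat
    return frames


# ---------------------------------------------------------------------------
# CIF


def write_cif(state: CrystalState, path, name: str = "polyxtal") -> None:
    """Write a CIF with cell, symmetry operators and fractional atom sites.

    Fractional coordinates are wrapped into [0, 1) here (and only here).
    """
    cell = state.cell
    frac = cell.cart_to_frac(state.coords) % 1.0
    sg = state.space_group
    lines = [
        f"data_{name}",
        f"_cell_length_a {cell.a:.10f}",
        f"_cell_length_b {cell.b:.10f}",
        f"_cell_length_c {cell.c:.10f}",
        f"_cell_angle_alpha {cell.alpha:.10f}",
        f"_cell_angle_beta {cell.beta:.10f}",
        f"_cell_angle_gamma {cell.gamma:.10f}",
        f"_symmetry_space_group_name_H-M '{sg.symbol}'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    lines += [f"'{op.triplet}'" for op in sg.operators]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for k, (el, f) in enumerate(zip(
            state.topology.elements * state.n_molecules, frac)):
        lines.append(f"{el}{k + 1} {el} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cif(path) -> dict:
    """Parse a CIF into cell parameters, symmetry triplets and sites."""
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def num(tag):
        v = block.find_value(tag)
        if v is None:
            raise ValueError(f"{path}: missing {tag}")
        return float(gemmi.cif.as_number(v))

    cell = UnitCell(num("_cell_length_a"), num("_cell_length_b"),
                    num("_cell_length_c"), num("_cell_angle_alpha"),
                    num("_cell_angle_beta"), num("_cell_angle_gamma"))
    symbol = block.find_value("_symmetry_space_group_name_H-M")
    symbol = gemmi.cif.as_string(symbol) if symbol else "P1"
    triplets = [gemmi.cif.as_string(row[0])
                for row in block.find(["_symmetry_equiv_pos_as_xyz"])]
    elements, frac = [], []
    for row in block.find(["_atom_site_type_symbol", "_atom_site_fract_x",
                           "_atom_site_fract_y", "_atom_site_fract_z"]):
        elements.append(gemmi.cif.as_string(row[0]))
        frac.append([gemmi.cif.as_number(row[k]) for k in (1, 2, 3)])
    return {
        "cell": cell,
        "space_group": symbol.replace(" ", ""),
        "operators": [parse_triplet(t) for t in triplets],
        "elements": elements,
        "frac_coords": np.array(frac),
    }


def state_from_cif(path, topology: MoleculeTopology, lam: float = 1.0) -> CrystalState:
    """Rebuild a CrystalState from a CIF written by this package.

    The molecule topology is supplied separately (CIF carries no force
    field); sites must appear in topology atom order, repeated per
    explicit molecule.  Molecules split across the cell boundary by the
    fractional wrap are made whole again.
    """
    data = read_cif(path)
    cell = data["cell"]
    nat = topology.n_atoms
    frac = data["frac_coords"]
    if len(frac) % nat:
        raise ValueError(f"{path}: site count {len(frac)} is not a multiple "
                         f"of the topology's {nat} atoms")
    n_mol = len(frac) // nat
    coords = np.empty((len(frac), 3))
    for m in range(n_mol):
        f = frac[m * nat:(m + 1) * nat].copy()
        f -= np.round(f - f[0])  # unwrap against the first atom
        coords[m * nat:(m + 1) * nat] = cell.frac_to_cart(f)
    return CrystalState(topology, coords, cell,
                        get_space_group(data["space_group"]), lam,
                        n_molecules=n_mol)


# ---------------------------------------------------------------------------
# tabular records


def write_snapshot_index(snapshots, path, files=None) -> None:
    """Tab-separated index of snapshots (energy, density, λ, step, file)."""
    rows = []
    for k, s in enumerate(snapshots):
        rows.append({
            "file": files[k] if files else f"snapshot_{k:05d}.cif",
            "energy": s.energy,
            "density": s.density,
            "lam": s.lam,
            "step": s.step,
        })
    pd.DataFrame(rows, columns=["file", "energy", "density", "lam", "step"]) \
        .to_csv(path, sep="\t", index=False)


def read_snapshot_index(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"file", "energy", "density", "lam", "step"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: snapshot index missing columns {sorted(missing)}")
    return df


def write_similarity(matrix, path) -> None:
    """Similarity matrix as TSV with header labels."""
    from .compare import SimilarityMatrix

    if isinstance(matrix, SimilarityMatrix):
        values, labels = matrix.values, matrix.labels
    else:
        values = np.asarray(matrix)
        labels = [str(i) for i in range(len(values))]
    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


def read_similarity(path):
    from .compare import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(df.values, [str(c) for c in df.columns])
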