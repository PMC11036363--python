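"""Triclinic unit cells and fractional/Cartesian conversions.

Cell lengths are in Angstroms, angles in degrees.  The fractional-to-
Cartesian matrix follows the standard crystallographic convention: the
``a`` axis lies along Cartesian x, ``b`` in the xy plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["UnitCell", "cell_volume", "min_image_factors"]


@dataclass(frozen=True)
class UnitCell:
    """A triclinic unit cell (a, b, c in Å; alpha, beta, gamma in degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    matrix: np.ndarray = field(init=False, repr=False, compare=False)
    inv_matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180) degrees")
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        sg = math.sin(ga)
        # volume factor; negative/zero under the square root means a
        # geometrically impossible angle combination
        vfac = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vfac <= 0.0:
            raise ValueError("degenerate cell: angles do not define a positive volume")
        m = np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * math.sqrt(vfac) / sg],
            ]
        )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "inv_matrix", np.linalg.inv(m))

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (closed-form triclinic formula)."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
        return self.a * self.b * self.c * math.sqrt(
            1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        )

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lattice_vectors(self) -> np.ndarray:
        """Rows are the a, b, c lattice vectors in Cartesian Å."""
        return self.matrix.T.copy()

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix.T

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ self.inv_matrix.T

    def perpendicular_widths(self) -> np.ndarray:
        """Distance between opposite cell faces along each axis (Å).

        The width along axis i is V / |a_j x a_k|; it governs the minimum
        image convention (width must be at least twice the cutoff).
        """
        vecs = self.lattice_vectors
        vol = abs(np.linalg.det(vecs))
        widths = np.empty(3)
        for i in range(3):
            cross = np.cross(vecs[(i + 1) % 3], vecs[(i + 2) % 3])
            widths[i] = vol / np.linalg.norm(cross)
        return widths

    def scaled(self, factors) -> "UnitCell":
        """New cell with lengths multiplied per-axis; angles unchanged."""
        fa, fb, fc = factors
        return UnitCell(self.a * fa, self.b * fb, self.c * fc,
                        self.alpha, self.beta, self.gamma)


def cell_volume(cell: UnitCell) -> float:
    """Volume of a unit cell in Å³."""
    return cell.volume


def min_image_factors(cell: UnitCell, cutoff: float) -> tuple[int, int, int]:
    """Smallest replication factors satisfying the minimum image convention.

    Returns the per-axis integers (na, nb, nc) such that each perpendicular
    width of the replicated cell is at least twice the interaction cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    widths = cell.perpendicular_widths()
    return tuple(int(math.ceil(2.0 * cutoff / w - 1e-12)) for w in widths)
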