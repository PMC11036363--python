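"""Space-group symmetry operators for the polymorph search.

Ships the 15 most frequent space groups in the Cambridge Structural
Database (CSD) above a 0.5% occurrence cutoff, which is the standard
search list for Z' = 1 organic crystals.  Operators for the general
position are stored as an internal table of coordinate triplets and
parsed at import time; the table is validated against an external
symmetry library in the test suite, so there is no runtime dependency
on one.

The rhombohedral entry is R-3 in the hexagonal setting (18 general
positions); its cell obeys the hexagonal lattice-system constraints
(a = b, alpha = beta = 90 deg, gamma = 120 deg).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "SymmetryOperator",
    "SpaceGroup",
    "get_space_group",
    "available_space_groups",
    "count_lattice_dof",
    "LATTICE_SYSTEMS",
]

# Free lattice parameters per lattice system, as implied by the length
# and angle constraint sets the Monte Carlo barostat maintains:
#   triclinic     none / none                 -> a b c alpha beta gamma
#   monoclinic    none / alpha = gamma = 90   -> a b c beta
#   orthorhombic  none / all angles 90        -> a b c
#   tetragonal    a = b / all angles 90       -> a c
#   rhombohedral  a = b = c / alpha=beta=gamma-> a alpha
#   hexagonal     a = b / 90, 90, 120         -> a c
#   cubic         a = b = c / all angles 90   -> a
LATTICE_SYSTEMS: dict[str, int] = {
    "triclinic": 6,
    "monoclinic": 4,
    "orthorhombic": 3,
    "tetragonal": 2,
    "rhombohedral": 2,
    "hexagonal": 2,
    "cubic": 1,
}


# free lattice parameters, as groups changed in tandem: length groups are
# scaled together (e.g. a = b = c for cubic), angle groups shifted together
FREE_LENGTH_GROUPS: dict[str, list[tuple[str, ...]]] = {
    "triclinic": [("a",), ("b",), ("c",)],
    "monoclinic": [("a",), ("b",), ("c",)],
    "orthorhombic": [("a",), ("b",), ("c",)],
    "tetragonal": [("a", "b"), ("c",)],
    "hexagonal": [("a", "b"), ("c",)],
    "rhombohedral": [("a", "b", "c")],
    "cubic": [("a", "b", "c")],
}
FREE_ANGLE_GROUPS: dict[str, list[tuple[str, ...]]] = {
    "triclinic": [("alpha",), ("beta",), ("gamma",)],
    "monoclinic": [("beta",)],
    "orthorhombic": [],
    "tetragonal": [],
    "hexagonal": [],
    "rhombohedral": [("alpha", "beta", "gamma")],
    "cubic": [],
}


def count_lattice_dof(lattice_system: str) -> int:
    """Number of independently sampled lattice parameters for a system."""
    try:
        return LATTICE_SYSTEMS[lattice_system]
    except KeyError:
        raise ValueError(
            f"unknown lattice system {lattice_system!r}; "
            f"expected one of {sorted(LATTICE_SYSTEMS)}"
        ) from None


@dataclass(frozen=True)
class SymmetryOperator:
    """Rotation (integer matrix, fractional basis) plus translation (cell fractions)."""

    rotation: tuple[tuple[int, ...], ...]
    translation: tuple[Fraction, ...]

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, dtype=float)

    @property
    def trans(self) -> np.ndarray:
        return np.array([float(t) for t in self.translation])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (no wrapping)."""
        return np.asarray(frac, dtype=float) @ self.rot.T + self.trans

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        """self after other, translation reduced mod 1."""
        r1 = np.array(self.rotation, dtype=int)
        r2 = np.array(other.rotation, dtype=int)
        rot = tuple(tuple(int(v) for v in row) for row in r1 @ r2)
        f1 = [Fraction(t) for t in self.translation]
        trans = []
        for i in range(3):
            t = sum(Fraction(int(r1[i, j])) * other.translation[j] for j in range(3)) + f1[i]
            trans.append(t % 1)
        return SymmetryOperator(rot, tuple(trans))

    @property
    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, ax in enumerate("xyz"):
                r = self.rotation[i][j]
                if r == 0:
                    continue
                sign = "-" if r < 0 else ("+" if s else "")
                s += f"{sign}{ax}"
            t = self.translation[i]
            if t != 0:
                s += f"+{t}" if t > 0 else f"{t}"
            parts.append(s)
        return ",".join(parts)


def parse_triplet(triplet: str) -> SymmetryOperator:
    """Parse a coordinate triplet like ``-x,y+1/2,-z+1/2``."""
    rows, trans = [], []
    comps = triplet.replace(" ", "").lower().split(",")
    if len(comps) != 3:
        raise ValueError(f"malformed triplet: {triplet!r}")
    for comp in comps:
        row = [0, 0, 0]
        t = Fraction(0)
        # tokenize into signed terms
        terms: list[str] = []
        cur = ""
        for ch in comp:
            if ch in "+-" and cur:
                terms.append(cur)
                cur = ch
            else:
                cur += ch
        if cur:
            terms.append(cur)
        for term in terms:
            sign = -1 if term.startswith("-") else 1
            body = term.lstrip("+-")
            if body in ("x", "y", "z"):
                row["xyz".index(body)] = sign
            else:
                t += sign * Fraction(body)
        rows.append(tuple(row))
        trans.append(t % 1)
    return SymmetryOperator(tuple(rows), tuple(trans))


@dataclass(frozen=True)
class SpaceGroup:
    """A space group: Hermann-Mauguin symbol, general-position operators,
    lattice system and CSD occurrence weight (percent)."""

    symbol: str
    operators: tuple[SymmetryOperator, ...]
    lattice_system: str
    csd_weight: float

    @property
    def multiplicity(self) -> int:
        return len(self.operators)

    def is_closed(self) -> bool:
        """Operator list closed under composition modulo lattice translations."""
        ops = {(op.rotation, op.translation) for op in self.operators}
        for a in self.operators:
            for b in self.operators:
                c = a.compose(b)
                if (c.rotation, c.translation) not in ops:
                    return False
        return True


# Internal operator table: general positions of the 15-group search list.
# CSD weights are approximate occurrence percentages of each group among
# deposited organic structures (used only to order groups and apply the
# probability cutoff); they are not high-precision quantities.
_GROUP_TABLE: dict[str, tuple[str, float, str]] = {
    # symbol: (lattice system, CSD %, ';'-joined triplets)
    "P1": ("triclinic", 1.0, "x,y,z"),
    "P-1": ("triclinic", 24.7, "x,y,z;-x,-y,-z"),
    "P21": ("monoclinic", 5.2, "x,y,z;-x,y+1/2,-z"),
    "C2": ("monoclinic", 0.9, "x,y,z;-x,y,-z;x+1/2,y+1/2,z;-x+1/2,y+1/2,-z"),
    "Cc": ("monoclinic", 1.0, "x,y,z;x,-y,z+1/2;x+1/2,y+1/2,z;x+1/2,-y+1/2,z+1/2"),
    "P2/c": ("monoclinic", 0.8, "x,y,z;-x,y,-z+1/2;-x,-y,-z;x,-y,z+1/2"),
    "P21/c": (
        "monoclinic",
        34.9,
        "x,y,z;-x,y+1/2,-z+1/2;-x,-y,-z;x,-y+1/2,z+1/2",
    ),
    "C2/c": (
        "monoclinic",
        8.3,
        "x,y,z;-x,y,-z+1/2;-x,-y,-z;x,-y,z+1/2;"
        "x+1/2,y+1/2,z;-x+1/2,y+1/2,-z+1/2;-x+1/2,-y+1/2,-z;x+1/2,-y+1/2,z+1/2",
    ),
    "P212121": (
        "orthorhombic",
        7.1,
        "x,y,z;-x+1/2,-y,z+1/2;x+1/2,-y+1/2,-z;-x,y+1/2,-z+1/2",
    ),
    "Pca21": (
        "orthorhombic",
        0.8,
        "x,y,z;-x,-y,z+1/2;-x+1/2,y,z+1/2;x+1/2,-y,z",
    ),
    "Pna21": (
        "orthorhombic",
        1.4,
        "x,y,z;-x,-y,z+1/2;-x+1/2,y+1/2,z+1/2;x+1/2,-y+1/2,z",
    ),
    "Pbcn": (
        "orthorhombic",
        0.9,
        "x,y,z;-x+1/2,-y+1/2,z+1/2;x+1/2,-y+1/2,-z;-x,y,-z+1/2;"
        "-x,-y,-z;x+1/2,y+1/2,-z+1/2;-x+1/2,y+1/2,z;x,-y,z+1/2",
    ),
    "Pbca": (
        "orthorhombic",
        3.4,
        "x,y,z;-x+1/2,-y,z+1/2;x+1/2,-y+1/2,-z;-x,y+1/2,-z+1/2;"
        "-x,-y,-z;x+1/2,y,-z+1/2;-x+1/2,y+1/2,z;x,-y+1/2,z+1/2",
    ),
    "Pnma": (
        "orthorhombic",
        1.2,
        "x,y,z;-x+1/2,-y,z+1/2;x+1/2,-y+1/2,-z+1/2;-x,y+1/2,-z;"
        "-x,-y,-z;x+1/2,y,-z+1/2;-x+1/2,y+1/2,z+1/2;x,-y+1/2,z",
    ),
    # hexagonal setting; cell constraints follow the hexagonal lattice system
    "R-3": (
        "hexagonal",
        0.6,
        "x,y,z;-y,x-y,z;-x+y,-x,z;-x,-y,-z;y,-x+y,-z;x-y,x,-z;"
        "x+2/3,y+1/3,z+1/3;-y+2/3,x-y+1/3,z+1/3;-x+y+2/3,-x+1/3,z+1/3;"
        "-x+2/3,-y+1/3,-z+1/3;y+2/3,-x+y+1/3,-z+1/3;x-y+2/3,x+1/3,-z+1/3;"
        "x+1/3,y+2/3,z+2/3;-y+1/3,x-y+2/3,z+2/3;-x+y+1/3,-x+2/3,z+2/3;"
        "-x+1/3,-y+2/3,-z+2/3;y+1/3,-x+y+2/3,-z+2/3;x-y+1/3,x+2/3,-z+2/3",
    ),
}

_ALIASES = {"H3": "R-3", "R3-": "R-3", "P21/N": "P21/c"}


def _normalize(symbol: str) -> str:
    s = symbol.replace(" ", "")
    s = s[0].upper() + s[1:] if s else s
    return _ALIASES.get(s.upper(), s)


_CACHE: dict[str, SpaceGroup] = {}


def get_space_group(symbol: str) -> SpaceGroup:
    """Look up a shipped space group by Hermann-Mauguin symbol."""
    key = _normalize(symbol)
    # case-insensitive match against the table
    for name in _GROUP_TABLE:
        if name.lower() == key.lower():
            key = name
            break
    else:
        raise KeyError(
            f"space group {symbol!r} is not in the shipped 15-group search list"
        )
    if key not in _CACHE:
        system, weight, triplets = _GROUP_TABLE[key]
        ops = tuple(parse_triplet(t) for t in triplets.split(";"))
        _CACHE[key] = SpaceGroup(key, ops, system, weight)
    return _CACHE[key]


def available_space_groups() -> list[SpaceGroup]:
    """All shipped groups, ordered by descending CSD weight."""
    groups = [get_space_group(s) for s in _GROUP_TABLE]
    return sorted(groups, key=lambda g: -g.csd_weight)
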