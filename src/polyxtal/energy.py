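"""Surrogate pairwise potential with the alchemical structure of the search.

Intramolecular bonded terms (harmonic bonds/angles, cosine torsions) are
always fully coupled.  Intermolecular interactions — the asymmetric unit
with its symmetry mates and periodic images — are scaled by the coupling
λ: at λ = 0 the molecule is fully uncoupled from its surroundings (the
vacuum state), at λ = 1 the crystal is fully interacting.

Pair terms:

* van der Waals: buffered 14-7, ``u(ρ) = ε (1.07/(ρ+0.07))⁷ (1.12/(ρ⁷+0.12) − 2)``
  with ρ = r/r0, under a softcore substitution ρ⁷ → α(1−λ)² + ρ⁷ and a
  λⁿ prefactor (n ≥ 2 so ∂U/∂λ vanishes at λ = 0).
* electrostatics: damped-shifted-force point charges (energy and force
  both zero at the cutoff), with a softcore r → sqrt(r² + α_e(1−λ)²).

Both terms are multiplied by a quintic switching window over the last
Angstrom before the 12 Å cutoff.  All λ- and r-derivatives, including
the mixed ∂²u/∂λ∂r the OST bias force needs, are generated symbolically
once per parameter set and evaluated as vectorized closed forms.

Units: kcal/mol, Å, degrees, amu, elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc as _erfc

from .crystal import CrystalState
from .topology import MoleculeTopology

__all__ = [
    "AlchemicalParams",
    "EnergyResult",
    "bonded_energy",
    "softcore_vdw_pair",
    "intermolecular_energy",
    "total_potential",
    "KB",
    "COULOMB",
    "ATM_A3_TO_KCAL",
]

KB = 1.987204e-3  # kcal/mol/K
COULOMB = 332.063713  # kcal mol^-1 Å e^-2
ATM_A3_TO_KCAL = 1.4584e-5  # 1 atm·Å³ in kcal/mol


@dataclass(frozen=True)
class AlchemicalParams:
    """Tunables of the alchemically scaled pair potential."""

    softcore_alpha: float = 0.7  # dimensionless, inside the buffered 14-7
    lambda_exponent: int = 5  # λⁿ prefactor; n ≥ 2 required
    cutoff: float = 12.0  # Å
    taper_width: float = 1.0  # Å, quintic switch window
    elec_damping: float = 0.2  # Å⁻¹, damped-shifted-force alpha
    elec_softcore: float = 1.0  # Å², softcore offset scale for electrostatics
    use_electrostatics: bool = True

    def __post_init__(self) -> None:
        if self.softcore_alpha <= 0:
            raise ValueError("softcore alpha must be positive")
        if self.lambda_exponent < 2:
            raise ValueError("lambda exponent must be >= 2")


@dataclass
class EnergyResult:
    """Potential energy with per-term breakdown and alchemical derivatives."""

    total: float
    bonded: float
    vdw: float
    electrostatic: float
    gradient: np.ndarray  # (n_atoms, 3) kcal/mol/Å
    dU_dlam: float
    d2U_dlamdx: np.ndarray  # (n_atoms, 3)
    d2U_dlam2: float = 0.0

    def __add__(self, other: "EnergyResult") -> "EnergyResult":
        return EnergyResult(
            self.total + other.total,
            self.bonded + other.bonded,
            self.vdw + other.vdw,
            self.electrostatic + other.electrostatic,
            self.gradient + other.gradient,
            self.dU_dlam + other.dU_dlam,
            self.d2U_dlamdx + other.d2U_dlamdx,
            self.d2U_dlam2 + other.d2U_dlam2,
        )

    @staticmethod
    def zero(n_atoms: int) -> "EnergyResult":
        z = np.zeros((n_atoms, 3))
        return EnergyResult(0.0, 0.0, 0.0, 0.0, z, 0.0, z.copy())


# ---------------------------------------------------------------------------
# symbolic pair functions (cached per parameter set)

_PAIR_CACHE: dict[tuple, dict] = {}


def _pair_functions(params: AlchemicalParams) -> dict:
    """Vectorized closed forms u, ∂u/∂r, ∂u/∂λ, ∂²u/∂λ∂r for both pair terms.

    Generated with sympy once per parameter set; the lambdified functions
    take (r, lam, eps, r0) for vdW and (r, lam, qq) for electrostatics.
    """
    key = (params.softcore_alpha, params.lambda_exponent, params.cutoff,
           params.elec_damping, params.elec_softcore)
    if key in _PAIR_CACHE:
        return _PAIR_CACHE[key]
    import sympy as sp

    r, lam, eps, r0, qq = sp.symbols("r lam eps r0 qq", positive=False)
    alpha = sp.Float(params.softcore_alpha)
    n = sp.Integer(params.lambda_exponent)
    rc = sp.Float(params.cutoff)

    rho7 = (r / r0) ** 7
    s = alpha * (1 - lam) ** 2 + rho7
    rho_s = s ** sp.Rational(1, 7)
    buf = (sp.Float(1.07) / (rho_s + sp.Float(0.07))) ** 7
    well = sp.Float(1.12) / (s + sp.Float(0.12)) - 2
    u_vdw = lam**n * eps * buf * well

    a = sp.Float(params.elec_damping)
    reff = sp.sqrt(r**2 + sp.Float(params.elec_softcore) * (1 - lam) ** 2)
    shift = sp.erfc(a * rc) / rc
    fshift = sp.erfc(a * rc) / rc**2 + 2 * a / sp.sqrt(sp.pi) * sp.exp(-(a * rc) ** 2) / rc
    u_elec = lam**n * sp.Float(COULOMB) * qq * (
        sp.erfc(a * reff) / reff - shift + fshift * (reff - rc)
    )

    mods = ["numpy", {"erfc": _erfc}]
    out = {}
    for name, expr, args in (
        ("vdw", u_vdw, (r, lam, eps, r0)),
        ("elec", u_elec, (r, lam, qq)),
    ):
        out[name] = {
            "u": sp.lambdify(args, expr, modules=mods),
            "du_dr": sp.lambdify(args, sp.diff(expr, r), modules=mods),
            "du_dl": sp.lambdify(args, sp.diff(expr, lam), modules=mods),
            "d2u_dldr": sp.lambdify(args, sp.diff(expr, lam, r), modules=mods),
            "d2u_dl2": sp.lambdify(args, sp.diff(expr, lam, 2), modules=mods),
        }
    _PAIR_CACHE[key] = out
    return out


def _switch(r: np.ndarray, params: AlchemicalParams) -> tuple[np.ndarray, np.ndarray]:
    """Quintic taper S(r) and S'(r): 1 below cutoff−w, 0 beyond the cutoff."""
    rc, w = params.cutoff, params.taper_width
    t = np.clip((r - (rc - w)) / w, 0.0, 1.0)
    s = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t**2)
    ds = -t**2 * (30.0 - 60.0 * t + 30.0 * t**2) / w
    return s, ds


def softcore_vdw_pair(r, eps, r0, lam, params: AlchemicalParams | None = None):
    """Softcore buffered 14-7 pair energy (kcal/mol), taper included.

    λ = 1 recovers the plain buffered 14-7 value (−ε at r = r0);
    λ = 0 gives exactly 0; r = 0 is finite for λ < 1.
    """
    params = params or AlchemicalParams()
    if lam == 0.0:
        return np.zeros_like(np.asarray(r, dtype=float)) if np.ndim(r) else 0.0
    fns = _pair_functions(params)["vdw"]
    r = np.asarray(r, dtype=float)
    u = fns["u"](r, lam, eps, r0)
    s, _ = _switch(r, params)
    u = np.where(r < params.cutoff, u * s, 0.0)
    return float(u) if u.ndim == 0 else u


# ---------------------------------------------------------------------------
# bonded terms


def bonded_energy(topology: MoleculeTopology, coords: np.ndarray) -> EnergyResult:
    """Harmonic bonds and angles plus cosine torsions; λ-independent.

    Bond energy is k_b (b−b0)², angle energy k_θ (θ−θ0)² with θ in
    radians, torsions Σ A (1 + cos(nφ − δ)).  Applies per explicit
    molecule when `coords` holds several copies of the topology.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    nat = topology.n_atoms
    n_mol = len(coords) // nat
    e = 0.0
    grad = np.zeros_like(coords)
    for m in range(n_mol):
        off = m * nat
        x = coords[off:off + nat]
        g = grad[off:off + nat]
        for i, j, kb, b0 in topology.bonds:
            d = x[i] - x[j]
            b = np.linalg.norm(d)
            e += kb * (b - b0) ** 2
            dg = 2.0 * kb * (b - b0) * d / b
            g[i] += dg
            g[j] -= dg
        for i, j, k, kt, t0 in topology.angles:
            rij = x[i] - x[j]
            rkj = x[k] - x[j]
            nij, nkj = np.linalg.norm(rij), np.linalg.norm(rkj)
            cos_t = np.clip(rij @ rkj / (nij * nkj), -1.0, 1.0)
            theta = math.acos(cos_t)
            dtheta = theta - math.radians(t0)
            e += kt * dtheta**2
            sin_t = max(math.sqrt(1.0 - cos_t**2), 1e-12)
            pref = 2.0 * kt * dtheta
            di = (cos_t * rij / nij - rkj / nkj) / (nij * sin_t) * pref
            dk = (cos_t * rkj / nkj - rij / nij) / (nkj * sin_t) * pref
            g[i] += di
            g[k] += dk
            g[j] -= di + dk
        for i, j, k, l, terms in topology.torsions:
            b1 = x[j] - x[i]
            b2 = x[k] - x[j]
            b3 = x[l] - x[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2)
            phi = math.atan2(np.cross(n1, n2) @ b2 / nb2, n1 @ n2)
            de_dphi = 0.0
            for amp, per, phase in terms:
                e += amp * (1.0 + math.cos(per * phi - math.radians(phase)))
                de_dphi += -amp * per * math.sin(per * phi - math.radians(phase))
            # standard torsion gradient (see e.g. Allen & Tildesley)
            gi = -de_dphi * nb2 / max(n1 @ n1, 1e-12) * n1
            gl = de_dphi * nb2 / max(n2 @ n2, 1e-12) * n2
            sv = -(b1 @ b2) / (nb2**2) * gi + (b3 @ b2) / (nb2**2) * gl
            g[i] += gi
            g[j] += -gi + sv
            g[k] += -gl - sv
            g[l] += gl
    z = np.zeros_like(coords)
    return EnergyResult(e, e, 0.0, 0.0, grad, 0.0, z)


# ---------------------------------------------------------------------------
# intermolecular (symmetry mates + periodic images)


def _image_transforms(state: CrystalState, nmax: tuple[int, int, int]):
    """Cartesian (R, t) transforms of every symmetry/translation image whose
    molecules can come within the cutoff of the explicit atoms.

    Yields (R_cart 3x3, T (n_t, 3) Cartesian offsets, origin_mask) per
    symmetry operator, where origin_mask marks the zero translation of
    the identity operator (whose same-molecule pairs are intramolecular
    and handled elsewhere) and is None for every other operator.
    """
    cell = state.cell
    M, Minv = cell.matrix, cell.inv_matrix
    vecs = cell.lattice_vectors
    grid = np.mgrid[-nmax[0]:nmax[0] + 1,
                    -nmax[1]:nmax[1] + 1,
                    -nmax[2]:nmax[2] + 1].reshape(3, -1).T
    trans = grid @ vecs  # (n_t, 3) Cartesian lattice translations
    origin = np.all(grid == 0, axis=1)
    for si, op in enumerate(state.space_group.operators):
        R = M @ op.rot @ Minv
        t0 = M @ op.trans
        yield R, t0 + trans, (origin if si == 0 else None)


def intermolecular_energy(
    state: CrystalState, params: AlchemicalParams | None = None
) -> EnergyResult:
    """Energy per explicit unit of the interactions with all symmetry mates
    and periodic images within the cutoff, scaled by the alchemical λ.

    Cells smaller than twice the cutoff are handled by summing over every
    lattice image within range (an internal replication), never by silent
    truncation.  For a crystal whose molecules are all symmetry-equivalent
    the per-molecule value is independent of the representation (ASU,
    P1 expansion, or replicated cell).
    """
    params = params or AlchemicalParams()
    nat_tot = len(state.coords)
    out = EnergyResult.zero(nat_tot)
    if state.lam == 0.0:
        return out
    fns = _pair_functions(params)
    x = state.coords
    lam = state.lam

    # image range: enough lattice shells that any molecule whose COM is
    # within cutoff + 2 * molecular extent is enumerated
    ext = 0.0
    for m in range(state.n_molecules):
        com = state.molecule_com(m)
        ext = max(ext, float(np.linalg.norm(state.molecule_coords(m) - com, axis=1).max()))
    reach = params.cutoff + 2.0 * ext
    widths = state.cell.perpendicular_widths()
    nmax = tuple(int(math.ceil(reach / w)) for w in widths)
    n_images = (2 * nmax[0] + 1) * (2 * nmax[1] + 1) * (2 * nmax[2] + 1)
    if n_images > 500_000:
        raise ValueError(
            f"cell too thin for the cutoff: {n_images} periodic images "
            f"would be required (cell={state.cell.parameters})"
        )

    top = state.topology
    n_mol = state.n_molecules
    nat = top.n_atoms
    eps_t = np.tile(top.eps, n_mol)
    r0_t = np.tile(top.r0, n_mol)
    q_t = np.tile(top.charges, n_mol)
    eps_pair = np.sqrt(np.outer(eps_t, eps_t))
    r0_pair = 0.5 * (r0_t[:, None] + r0_t[None, :])
    qq_pair = np.outer(q_t, q_t)
    mol_id = np.repeat(np.arange(n_mol), nat)

    e_vdw = e_elec = du_dl = d2u_dl2 = 0.0
    grad = np.zeros_like(x)
    d2 = np.zeros_like(x)

    n_exp = len(x)
    mol_differs = mol_id[:, None] != mol_id[None, :]
    # translation chunking keeps the distance tensor under ~50 MB
    chunk = max(1, int(5e7 / (n_exp * n_exp * 24)))
    for R, T, origin_mask in _image_transforms(state, nmax):
        xR = x @ R.T
        for lo in range(0, len(T), chunk):
            Tc = T[lo:lo + chunk]
            env = xR[None, :, :] + Tc[:, None, :]
            dvec = x[:, None, None, :] - env[None, :, :, :]
            r = np.sqrt(np.einsum("itjk,itjk->itj", dvec, dvec))
            mask = r < params.cutoff
            if origin_mask is not None:
                om = origin_mask[lo:lo + chunk]
                if om.any():
                    mask[:, om, :] &= mol_differs[:, None, :]
            if not mask.any():
                continue
            ii, tt, jj = np.nonzero(mask)
            rr = np.maximum(r[ii, tt, jj], 1e-12)
            sw, dsw = _switch(rr, params)
            ep, r0p, qqp = eps_pair[ii, jj], r0_pair[ii, jj], qq_pair[ii, jj]

            u = fns["vdw"]["u"](rr, lam, ep, r0p)
            ur = fns["vdw"]["du_dr"](rr, lam, ep, r0p)
            ul = fns["vdw"]["du_dl"](rr, lam, ep, r0p)
            ulr = fns["vdw"]["d2u_dldr"](rr, lam, ep, r0p)
            ull = fns["vdw"]["d2u_dl2"](rr, lam, ep, r0p)
            e_vdw += 0.5 * float(np.sum(u * sw))
            if params.use_electrostatics and np.any(qqp != 0.0):
                ue = fns["elec"]["u"](rr, lam, qqp)
                uer = fns["elec"]["du_dr"](rr, lam, qqp)
                uel = fns["elec"]["du_dl"](rr, lam, qqp)
                uelr = fns["elec"]["d2u_dldr"](rr, lam, qqp)
                uell = fns["elec"]["d2u_dl2"](rr, lam, qqp)
                e_elec += 0.5 * float(np.sum(ue * sw))
                u = u + ue
                ur = ur + uer
                ul = ul + uel
                ulr = ulr + uelr
                ull = ull + uell
            du_dl += 0.5 * float(np.sum(ul * sw))
            d2u_dl2 += 0.5 * float(np.sum(ull * sw))

            # d(u*S)/dr along the pair direction, 0.5 weight, both legs
            f = 0.5 * (ur * sw + u * dsw)
            fl = 0.5 * (ulr * sw + ul * dsw)
            rhat = dvec[ii, tt, jj] / rr[:, None]
            np.add.at(grad, ii, f[:, None] * rhat)
            np.add.at(grad, jj, -(f[:, None] * rhat) @ R)
            np.add.at(d2, ii, fl[:, None] * rhat)
            np.add.at(d2, jj, -(fl[:, None] * rhat) @ R)

    total = e_vdw + e_elec
    if not np.isfinite(total) or not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite intermolecular energy (lam={lam}, "
            f"cell={state.cell.parameters})"
        )
    return EnergyResult(total, 0.0, e_vdw, e_elec, grad, du_dl, d2, d2u_dl2)


def _intramolecular_nonbonded(
    state: CrystalState, params: AlchemicalParams
) -> EnergyResult:
    """Nonbonded interactions within each explicit molecule.

    Always fully coupled (evaluated at λ = 1) regardless of the state's
    coupling: the λ = 0 endpoint is an intact vacuum molecule.  1-2/1-3
    pairs are excluded, 1-4 pairs half-scaled.
    """
    nat = state.topology.n_atoms
    out = EnergyResult.zero(len(state.coords))
    if nat < 2:
        return out
    scale = state.topology.exclusion_scale()
    if not scale.any():
        return out
    fns = _pair_functions(params)
    iu, ju = np.triu_indices(nat, k=1)
    sc = scale[iu, ju]
    keep = sc > 0
    iu, ju, sc = iu[keep], ju[keep], sc[keep]
    if len(iu) == 0:
        return out
    top = state.topology
    ep = np.sqrt(top.eps[iu] * top.eps[ju])
    r0p = 0.5 * (top.r0[iu] + top.r0[ju])
    qqp = top.charges[iu] * top.charges[ju]
    for m in range(state.n_molecules):
        x = state.coords[m * nat:(m + 1) * nat]
        d = x[iu] - x[ju]
        rr = np.linalg.norm(d, axis=1)
        inside = rr < params.cutoff
        if not inside.any():
            continue
        rr_i = np.maximum(rr[inside], 1e-12)
        sw, dsw = _switch(rr_i, params)
        u = fns["vdw"]["u"](rr_i, 1.0, ep[inside], r0p[inside])
        ur = fns["vdw"]["du_dr"](rr_i, 1.0, ep[inside], r0p[inside])
        e_v = float(np.sum(sc[inside] * u * sw))
        out.vdw += e_v
        f = sc[inside] * (ur * sw + u * dsw)
        if params.use_electrostatics and np.any(qqp[inside] != 0.0):
            ue = fns["elec"]["u"](rr_i, 1.0, qqp[inside])
            uer = fns["elec"]["du_dr"](rr_i, 1.0, qqp[inside])
            out.electrostatic += float(np.sum(sc[inside] * ue * sw))
            f = f + sc[inside] * (uer * sw + ue * dsw)
        rhat = d[inside] / rr_i[:, None]
        gi = f[:, None] * rhat
        np.add.at(out.gradient, m * nat + iu[inside], gi)
        np.add.at(out.gradient, m * nat + ju[inside], -gi)
    out.total = out.vdw + out.electrostatic
    return out


def total_potential(
    state: CrystalState, params: AlchemicalParams | None = None
) -> EnergyResult:
    """Full potential per explicit unit: bonded + intramolecular nonbonded
    (always on) + λ-scaled intermolecular, with analytic gradient, ∂U/∂λ
    and ∂²U/∂λ∂x."""
    params = params or AlchemicalParams()
    res = bonded_energy(state.topology, state.coords)
    res = res + _intramolecular_nonbonded(state, params)
    res = res + intermolecular_energy(state, params)
    if not np.isfinite(res.total):
        raise FloatingPointError(
            f"non-finite total potential (lam={state.lam}, cell={state.cell.parameters})"
        )
    return res
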