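"""Local minimization of asymmetric-unit coordinates and free lattice parameters.

Quasi-Newton (L-BFGS-B) descent over the Cartesian coordinates together
with the free lattice parameters of the cell's lattice system.  Lattice
degrees of freedom use the same constrained parameterization as the
Monte Carlo barostat, so the lattice-system constraints are preserved
exactly by construction.  Coordinate gradients are analytic; the
gradient with respect to lattice parameters uses 5-point central finite
differences of the analytic energy.

Two named convergence presets are shipped: "search" (rms gradient
0.1 kcal/mol/Å, used for on-the-fly snapshot scoring) and "posthoc"
(0.03 kcal/mol/Å, the final filtering criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .cell import UnitCell
from .crystal import CrystalState
from .energy import AlchemicalParams, total_potential
from .symmetry import FREE_ANGLE_GROUPS, FREE_LENGTH_GROUPS

__all__ = ["MinimizeResult", "minimize_crystal", "RMS_PRESETS"]

RMS_PRESETS = {"search": 0.1, "posthoc": 0.03}


@dataclass
class MinimizeResult:
    """Outcome of a crystal minimization."""

    state: CrystalState
    energy: float  # kcal/mol per explicit unit
    rms_gradient: float  # kcal/mol/Å over all minimized variables
    iterations: int
    converged: bool


def _lattice_vector(cell: UnitCell, system: str) -> np.ndarray:
    pars = dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), cell.parameters))
    vals = [pars[g[0]] for g in FREE_LENGTH_GROUPS[system]]
    vals += [pars[g[0]] for g in FREE_ANGLE_GROUPS[system]]
    return np.array(vals)


def _build_cell(base: UnitCell, system: str, vec: np.ndarray) -> UnitCell:
    pars = dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), base.parameters))
    k = 0
    for group in FREE_LENGTH_GROUPS[system]:
        for name in group:
            pars[name] = vec[k]
        k += 1
    for group in FREE_ANGLE_GROUPS[system]:
        for name in group:
            pars[name] = vec[k]
        k += 1
    return UnitCell(**pars)


def minimize_crystal(
    state: CrystalState,
    rms_target: float = RMS_PRESETS["posthoc"],
    max_iter: int = 500,
    params: AlchemicalParams | None = None,
    relax_lattice: bool = True,
) -> MinimizeResult:
    """Minimize coordinates (and, by default, free lattice parameters).

    The coupling is forced to 1 (fully interacting crystal).  Returns the
    best state found; `converged` is true iff the rms gradient over the
    minimized variables reached the target.  A line-search failure
    returns the best-so-far with converged=False.
    """
    params = params or AlchemicalParams()
    state = replace(state.copy(), lam=1.0)
    system = state.space_group.lattice_system
    n_xyz = state.coords.size
    lat0 = _lattice_vector(state.cell, system) if relax_lattice else np.empty(0)
    z0 = np.concatenate([state.coords.ravel(), lat0])

    def unpack(z: np.ndarray) -> CrystalState:
        coords = z[:n_xyz].reshape(-1, 3)
        cell = _build_cell(state.cell, system, z[n_xyz:]) if relax_lattice else state.cell
        return replace(state, coords=coords, cell=cell)

    def energy_only(z: np.ndarray) -> float:
        try:
            return total_potential(unpack(z), params).total
        except (ValueError, FloatingPointError):
            return 1e10  # invalid cell: repel the line search

    def objective(z: np.ndarray):
        try:
            st = unpack(z)
            res = total_potential(st, params)
        except (ValueError, FloatingPointError):
            return 1e10, np.zeros_like(z)
        g = np.empty_like(z)
        g[:n_xyz] = res.gradient.ravel()
        # 5-point central differences for the lattice block
        for k in range(len(z) - n_xyz):
            h = 1e-4 * max(abs(z[n_xyz + k]), 1.0)
            vals = []
            for step in (-2, -1, 1, 2):
                zz = z.copy()
                zz[n_xyz + k] += step * h
                vals.append(energy_only(zz))
            g[n_xyz + k] = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
        return res.total, g

    # keep lattice proposals geometrically sane during line searches
    bounds = [(None, None)] * n_xyz
    n_len = len(FREE_LENGTH_GROUPS[system]) if relax_lattice else 0
    n_ang = len(FREE_ANGLE_GROUPS[system]) if relax_lattice else 0
    bounds += [(0.8, None)] * n_len + [(20.0, 160.0)] * n_ang
    opt = _scipy_minimize(
        objective, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": rms_target * 1e-2},
    )
    z = opt.x
    e, g = objective(z)
    # keep whichever of start/end is lower (line-search failures can stall)
    e0, g0 = objective(z0)
    if e0 < e:
        z, e, g = z0, e0, g0
    rms = float(np.sqrt(np.mean(g**2)))
    return MinimizeResult(
        state=unpack(z),
        energy=e,
        rms_gradient=rms,
        iterations=int(opt.nit),
        converged=bool(rms <= rms_target),
    )
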