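"""NPT sampling: Langevin dynamics, λ-dynamics and the Monte Carlo barostat.

Atomic coordinates are propagated with a BAOAB-splitting Langevin
integrator; the alchemical coupling is propagated as an auxiliary
Langevin particle through θ with λ = sin²θ, which bounds λ to [0, 1]
smoothly (dλ/dθ vanishes at both endpoints, so no hard reflection is
needed).  Lattice parameters fluctuate through Monte Carlo trial moves
restricted to the free parameters of the cell's lattice system; the
constrained parameters are never touched, so the constraints hold
exactly after any number of accepted moves.

Units: kcal/mol, Å, fs, amu, K, atm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cell import UnitCell
from .crystal import CrystalState
from .energy import ATM_A3_TO_KCAL, KB, AlchemicalParams, EnergyResult, total_potential
from .minimize import minimize_crystal
from .ost import BiasGrid, OSTParams, bias_energy_and_gradient, coverage_statistic, deposit_hill, one_d_bias, tempering_height
from .symmetry import FREE_ANGLE_GROUPS, FREE_LENGTH_GROUPS

__all__ = [
    "ThermoConditions",
    "BarostatParams",
    "DynamicsParams",
    "langevin_step",
    "lambda_force",
    "propose_lattice_move",
    "barostat_delta_E",
    "barostat_accept",
    "rescale_coordinates",
    "snapshot_criterion",
    "run_walker",
    "Snapshot",
    "WalkerResult",
]

# (kcal/mol/Å)/amu in Å/fs²
ACC = 4.184e-4


@dataclass(frozen=True)
class ThermoConditions:
    """Target temperature (K) and pressure (atm)."""

    temperature: float = 298.15
    pressure: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.pressure < 0:
            raise ValueError("require T > 0 and p >= 0")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kT


@dataclass(frozen=True)
class BarostatParams:
    """Monte Carlo barostat tunables.

    Defaults are the production values: density window 0.75-1.6 g/cm³,
    maximum asymmetric-unit volume move 1 Å³, maximum angle move 0.5°,
    one trial every 10 MD steps on average.
    """

    rho_min: float = 0.75
    rho_max: float = 1.6
    v_max: float = 1.0
    a_max: float = 0.5
    mean_interval: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.rho_min < self.rho_max:
            raise ValueError("require 0 < rho_min < rho_max")
        if self.v_max <= 0 or self.a_max <= 0 or self.mean_interval < 1:
            raise ValueError("v_max, a_max and mean_interval must be positive")


@dataclass(frozen=True)
class DynamicsParams:
    """Integrator and schedule parameters."""

    timestep: float = 1.0  # fs
    friction: float = 10.0  # ps⁻¹
    lambda_mass: float = 5.0  # fictitious θ mass, amu·Å²
    seed: int = 0
    n_steps: int = 1000
    snapshot_stride_ps: float = 10.0
    rebuild_stride: int = 1000  # steps between 1D-bias rebuilds

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")


# ---------------------------------------------------------------------------
# Langevin integrator


def langevin_step(x, v, forces, masses, params: DynamicsParams,
                  kT: float, rng: np.random.Generator, force_fn=None):
    """One BAOAB Langevin step; returns (x, v, forces).

    `forces` are kcal/mol/Å at the input positions; `force_fn(x)` supplies
    the forces at the new positions (identity forces reused if omitted,
    which is exact only for constant-force problems).  Deterministic under
    a fixed generator state.
    """
    dt = params.timestep
    gamma = params.friction * 1e-3  # ps⁻¹ -> fs⁻¹
    m = np.asarray(masses, dtype=float)
    minv = ACC / m
    v = v + 0.5 * dt * forces * minv[..., None] if forces.ndim > 1 else v + 0.5 * dt * forces * minv
    x = x + 0.5 * dt * v
    c1 = math.exp(-gamma * dt)
    sigma = np.sqrt((1.0 - c1 * c1) * kT * ACC / m)
    noise = rng.standard_normal(np.shape(v))
    v = c1 * v + (sigma[..., None] * noise if np.ndim(v) > 1 else sigma * noise)
    x = x + 0.5 * dt * v
    new_forces = force_fn(x) if force_fn is not None else forces
    v = v + 0.5 * dt * new_forces * (minv[..., None] if np.ndim(v) > 1 else minv)
    return x, v, new_forces


def lambda_force(theta: float, dU_dlam: float, bias_dlam: float,
                 bias_dflam: float, d2U_dlam2: float) -> float:
    """Generalized force on θ for λ = sin²θ.

    The chain rule collects the potential's ∂U/∂λ, the 2D/1D bias partial
    along λ, and the bias partial along F_λ times ∂F_λ/∂λ = ∂²U/∂λ².
    """
    dtot_dlam = dU_dlam + bias_dlam + bias_dflam * d2U_dlam2
    return -dtot_dlam * math.sin(2.0 * theta)


# ---------------------------------------------------------------------------
# Monte Carlo barostat

def lattice_dof_moves(lattice_system: str) -> list[tuple[str, tuple[str, ...]]]:
    """The independently sampled lattice moves for a system."""
    try:
        lengths = FREE_LENGTH_GROUPS[lattice_system]
        angles = FREE_ANGLE_GROUPS[lattice_system]
    except KeyError:
        raise ValueError(f"unknown lattice system {lattice_system!r}") from None
    return [("length", g) for g in lengths] + [("angle", g) for g in angles]


def propose_lattice_move(
    state: CrystalState,
    params: BarostatParams,
    rng: np.random.Generator,
) -> UnitCell | None:
    """Propose a new unit cell changing one random free lattice parameter.

    Axis move: the asymmetric-unit volume changes by ΔV = v_max(2x−1),
    realized by scaling the chosen axis group.  Angle move: the chosen
    angle group changes by Δ = a_max(2x−1) and all lengths are then
    rescaled uniformly so the volume is unchanged.  Returns None when the
    proposal is geometrically invalid (an automatic rejection).
    """
    system = state.space_group.lattice_system
    moves = lattice_dof_moves(system)
    kind, group = moves[rng.integers(len(moves))]
    cell = state.cell
    pars = dict(zip(("a", "b", "c", "alpha", "beta", "gamma"), cell.parameters))
    x = rng.random()
    try:
        if kind == "length":
            # ΔV applies to the explicit unit; the cell holds `multiplicity`
            # symmetry copies of it
            dv_unit = params.v_max * (2.0 * x - 1.0)
            v_new = cell.volume + dv_unit * state.space_group.multiplicity
            if v_new <= 0:
                return None
            f = (v_new / cell.volume) ** (1.0 / len(group))
            for name in group:
                pars[name] *= f
        else:
            da = params.a_max * (2.0 * x - 1.0)
            for name in group:
                pars[name] += da
            trial = UnitCell(**pars)
            f = (cell.volume / trial.volume) ** (1.0 / 3.0)
            for name in ("a", "b", "c"):
                pars[name] *= f
        return UnitCell(**pars)
    except ValueError:
        return None


def barostat_delta_E(
    dU: float,
    v_current: float,
    v_proposed: float,
    n_molecules: int,
    conditions: ThermoConditions,
) -> float:
    """Metropolis energy for a lattice trial move (volumes are ASU volumes):

    ΔE = ΔU + pΔV − n_molecules · k_B T · ln(V_proposed / V_current)
    """
    if v_current <= 0 or v_proposed <= 0:
        raise ValueError("volumes must be positive")
    pdv = conditions.pressure * (v_proposed - v_current) * ATM_A3_TO_KCAL
    return dU + pdv - n_molecules * conditions.kT * math.log(v_proposed / v_current)


def barostat_accept(
    dE: float, conditions: ThermoConditions, rng: np.random.Generator
) -> bool:
    """Metropolis acceptance: always if ΔE < 0, else with probability e^(−βΔE)."""
    if not np.isfinite(dE):
        raise ValueError("non-finite barostat energy")
    if dE < 0:
        return True
    return rng.random() < math.exp(-dE * conditions.beta)


def rescale_coordinates(state: CrystalState, new_cell: UnitCell) -> np.ndarray:
    """Coordinates for a changed cell keeping each molecule's center-of-mass
    fractional coordinates unchanged; intramolecular geometry is untouched."""
    coords = state.coords.copy()
    nat = state.topology.n_atoms
    for m in range(state.n_molecules):
        com = state.molecule_com(m)
        frac = state.cell.cart_to_frac(com)
        new_com = new_cell.frac_to_cart(frac)
        coords[m * nat:(m + 1) * nat] += new_com - com
    return coords


def snapshot_criterion(
    lam: float,
    minimized_energy: float,
    best_energy: float,
    lam_threshold: float = 0.8,
    energy_window: float = 10.0,
) -> bool:
    """Save a snapshot iff λ exceeds the threshold and the locally minimized
    energy lies within the window of the best energy seen so far."""
    return lam > lam_threshold and (minimized_energy - best_energy) <= energy_window


def random_initial_state(
    topology,
    space_group,
    barostat: BarostatParams | None = None,
    rng: np.random.Generator | None = None,
    lam: float = 0.0,
    coords: np.ndarray | None = None,
) -> CrystalState:
    """Random rigid-body coordinates and unit cell parameters for a walker.

    The density is drawn uniformly inside the barostat band and fixes the
    cell volume; free lattice angles are drawn uniformly in [60°, 120°]
    and free length ratios in [0.7, 1.4] before scaling to the target
    volume.  The molecule gets a uniform random rotation (quaternion) and
    a uniform fractional center of mass.  Starts at λ = 0 (vacuum) by
    default.
    """
    from .crystal import CrystalState as _CS  # local alias for clarity

    barostat = barostat or BarostatParams()
    rng = rng or np.random.default_rng()
    mult = space_group.multiplicity
    rho = rng.uniform(barostat.rho_min, barostat.rho_max)
    v_target = 1.66053906892 * topology.molecular_mass * mult / rho
    system = space_group.lattice_system
    pars = {"a": 1.0, "b": 1.0, "c": 1.0, "alpha": 90.0, "beta": 90.0, "gamma": 90.0}
    if system == "hexagonal":
        pars["gamma"] = 120.0
    for group in FREE_ANGLE_GROUPS[system]:
        ang = rng.uniform(60.0, 120.0)
        for name in group:
            pars[name] = ang
    for group in FREE_LENGTH_GROUPS[system]:
        ratio = rng.uniform(0.7, 1.4)
        for name in group:
            pars[name] = ratio
    trial = UnitCell(**pars)
    scale = (v_target / trial.volume) ** (1.0 / 3.0)
    cell = UnitCell(pars["a"] * scale, pars["b"] * scale, pars["c"] * scale,
                    pars["alpha"], pars["beta"], pars["gamma"])
    # uniform random rotation from a normalized quaternion
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    base = coords if coords is not None else np.zeros((topology.n_atoms, 3))
    base = base - topology.masses @ base / topology.molecular_mass
    placed = base @ rot.T + cell.frac_to_cart(rng.random(3))
    return _CS(topology, placed, cell, space_group, lam)


def sample_lambda_well(
    well,
    ost: OSTParams | None = None,
    conditions: ThermoConditions | None = None,
    n_steps: int = 200_000,
    seed: int = 0,
    lambda_mass: float = 5.0,
    timestep: float = 1.0,
    friction: float = 10.0,
    apply_bias: bool = True,
) -> tuple[BiasGrid, np.ndarray]:
    """OST λ-dynamics on a pure λ-potential (no coordinates).

    `well` provides energy(λ), dU_dlam(λ) and d2U_dlam2(λ).  Returns the
    bias grid (1D bias rebuilt) and the visited λ series; the recovered
    free-energy profile is `free_energy_profile(grid)`.  With
    `apply_bias=False` no hills are deposited and no bias force acts —
    plain Langevin λ-dynamics on the well.
    """
    from .ost import free_energy_profile  # noqa: F401  (re-export convenience)

    ost = ost or OSTParams()
    conditions = conditions or ThermoConditions()
    rng = np.random.default_rng(seed)
    grid = BiasGrid(ost)
    kT = conditions.kT
    dt = timestep
    gamma = friction * 1e-3
    c1 = math.exp(-gamma * dt)
    sig = math.sqrt((1 - c1 * c1) * kT * ACC / lambda_mass)
    theta = rng.random() * math.pi / 2.0
    v = rng.standard_normal() * math.sqrt(kT * ACC / lambda_mass)
    lams = np.empty(n_steps)

    def f_theta(theta: float) -> float:
        lam = math.sin(theta) ** 2
        flam = well.dU_dlam(lam)
        if not apply_bias:
            return lambda_force(theta, flam, 0.0, 0.0, well.d2U_dlam2(lam))
        _, bl, bf = bias_energy_and_gradient(grid, lam, flam)
        m = min(grid._lam_bin(lam), grid.n_lam - 2)
        bl += (grid.one_d[m + 1] - grid.one_d[m]) / grid.params.lam_bin_width
        return lambda_force(theta, flam, bl, bf, well.d2U_dlam2(lam))

    f = f_theta(theta)
    for step in range(n_steps):
        v += 0.5 * dt * f * ACC / lambda_mass
        theta += 0.5 * dt * v
        v = c1 * v + sig * rng.standard_normal()
        theta += 0.5 * dt * v
        f = f_theta(theta)
        v += 0.5 * dt * f * ACC / lambda_mass
        lam = math.sin(theta) ** 2
        lams[step] = lam
        if apply_bias:
            flam = well.dU_dlam(lam)
            grid.record_visit(lam, flam, conditions.beta)
            if (step + 1) % ost.deposition_stride == 0:
                h = tempering_height(ost, coverage_statistic(grid), kT)
                deposit_hill(grid, lam, flam, h)
            if (step + 1) % 2000 == 0:
                one_d_bias(grid, conditions.beta)
    if apply_bias:
        one_d_bias(grid, conditions.beta)
    return grid, lams


def sample_asu_volumes(
    state: CrystalState,
    conditions: ThermoConditions,
    barostat: BarostatParams,
    n_trials: int,
    rng: np.random.Generator,
    energy_fn=None,
    enforce_density: bool = True,
) -> np.ndarray:
    """Barostat-only Monte Carlo: n_trials lattice moves on a state whose
    potential is `energy_fn(state)` (identically zero if omitted — the
    ideal gas).  Returns the explicit-unit volume after every trial.

    The ideal-gas stationary distribution of the unit volume is
    ∝ Vⁿ e^(−βpV) with n the molecule count, mean (n+1)·k_BT/p — the
    closed-form check of the acceptance rule.
    """
    state = state.copy()
    units = state.space_group.multiplicity
    u_cur = energy_fn(state) if energy_fn else 0.0
    out = np.empty(n_trials)
    for t in range(n_trials):
        new_cell = propose_lattice_move(state, barostat, rng)
        if new_cell is not None:
            ok = True
            if enforce_density:
                rho = state.density * state.cell.volume / new_cell.volume
                ok = barostat.rho_min <= rho <= barostat.rho_max
            if ok:
                trial = replace(state, coords=rescale_coordinates(state, new_cell),
                                cell=new_cell)
                u_new = energy_fn(trial) if energy_fn else 0.0
                dE = barostat_delta_E(u_new - u_cur, state.cell.volume / units,
                                      new_cell.volume / units, state.n_molecules,
                                      conditions)
                if barostat_accept(dE, conditions, rng):
                    state, u_cur = trial, u_new
        out[t] = state.cell.volume / units
    return out


# ---------------------------------------------------------------------------
# walker


@dataclass
class Snapshot:
    """A saved candidate packing from the search."""

    state: CrystalState
    energy: float  # minimized potential per explicit unit, kcal/mol
    density: float  # g/cm³ of the minimized state
    lam: float  # coupling at the time of saving
    step: int


@dataclass
class WalkerResult:
    """Trajectory summary, snapshots and bias grid from one walker."""

    state: CrystalState
    snapshots: list[Snapshot]
    bias: BiasGrid
    trajectory: list[dict]
    accepted_moves: int = 0
    trial_moves: int = 0
    status: int = 0
    message: str = ""


def run_walker(
    state: CrystalState,
    conditions: ThermoConditions | None = None,
    dyn: DynamicsParams | None = None,
    barostat: BarostatParams | None = None,
    ost: OSTParams | None = None,
    alchemical: AlchemicalParams | None = None,
    bias: BiasGrid | None = None,
    interactions: bool = True,
    traj_stride: int = 100,
    snapshot_minimize_rms: float = 0.1,
) -> WalkerResult:
    """Run one OST walker: Langevin MD + λ-dynamics + hill deposition +
    barostat trials + conditional snapshot saving.  Fully seeded and
    deterministic via DynamicsParams.seed.

    With `interactions=False` the potential is identically zero (an ideal
    gas): only the barostat acts, which is the reference system for its
    statistical-mechanics checks.
    """
    conditions = conditions or ThermoConditions()
    dyn = dyn or DynamicsParams()
    barostat = barostat or BarostatParams()
    ost = ost or OSTParams()
    alchemical = alchemical or AlchemicalParams()
    grid = bias if bias is not None else BiasGrid(ost)
    rng = np.random.default_rng(dyn.seed)
    state = state.copy()

    masses = np.tile(state.topology.masses, state.n_molecules)
    kT = conditions.kT
    # Maxwell-Boltzmann start
    v = rng.standard_normal(state.coords.shape) * np.sqrt(kT * ACC / masses)[:, None]
    theta = math.asin(math.sqrt(min(max(state.lam, 0.0), 1.0)))
    v_theta = rng.standard_normal() * math.sqrt(kT * ACC / dyn.lambda_mass)

    def evaluate(st: CrystalState) -> EnergyResult:
        if interactions:
            return total_potential(st, alchemical)
        return EnergyResult.zero(len(st.coords))

    snapshots: list[Snapshot] = []
    trajectory: list[dict] = []
    best_energy = math.inf
    accepted = trials = 0
    snap_stride = max(int(round(dyn.snapshot_stride_ps * 1000.0 / dyn.timestep)), 1)
    p_trial = 1.0 / barostat.mean_interval
    dt = dyn.timestep
    gamma = dyn.friction * 1e-3
    c1 = math.exp(-gamma * dt)

    res = evaluate(state)
    try:
        for step in range(dyn.n_steps):
            flam = res.dU_dlam
            _, bias_l, bias_f = bias_energy_and_gradient(grid, state.lam, flam)
            m = min(grid._lam_bin(state.lam), grid.n_lam - 2)
            bias_l += (grid.one_d[m + 1] - grid.one_d[m]) / grid.params.lam_bin_width
            forces = -(res.gradient + bias_f * res.d2U_dlamdx)
            f_theta = lambda_force(theta, res.dU_dlam, bias_l, bias_f, res.d2U_dlam2)

            # BAOAB, coordinates and theta sharing the thermostat step
            minv = ACC / masses
            v += 0.5 * dt * forces * minv[:, None]
            v_theta += 0.5 * dt * f_theta * ACC / dyn.lambda_mass
            state.coords += 0.5 * dt * v
            theta += 0.5 * dt * v_theta
            sig = np.sqrt((1 - c1 * c1) * kT * ACC / masses)
            v = c1 * v + sig[:, None] * rng.standard_normal(v.shape)
            v_theta = c1 * v_theta + math.sqrt(
                (1 - c1 * c1) * kT * ACC / dyn.lambda_mass) * rng.standard_normal()
            state.coords += 0.5 * dt * v
            theta += 0.5 * dt * v_theta
            state.lam = math.sin(theta) ** 2
            res = evaluate(state)
            flam = res.dU_dlam
            _, bias_l, bias_f = bias_energy_and_gradient(grid, state.lam, flam)
            m = min(grid._lam_bin(state.lam), grid.n_lam - 2)
            bias_l += (grid.one_d[m + 1] - grid.one_d[m]) / grid.params.lam_bin_width
            forces = -(res.gradient + bias_f * res.d2U_dlamdx)
            f_theta = lambda_force(theta, res.dU_dlam, bias_l, bias_f, res.d2U_dlam2)
            v += 0.5 * dt * forces * minv[:, None]
            v_theta += 0.5 * dt * f_theta * ACC / dyn.lambda_mass

            if not np.all(np.isfinite(state.coords)):
                raise FloatingPointError("non-finite coordinates")

            # OST bookkeeping
            if interactions:
                grid.record_visit(state.lam, flam, conditions.beta)
                if (step + 1) % ost.deposition_stride == 0:
                    h = tempering_height(ost, coverage_statistic(grid), kT)
                    deposit_hill(grid, state.lam, flam, h)
                if (step + 1) % dyn.rebuild_stride == 0:
                    one_d_bias(grid, conditions.beta)

            # barostat trial (per-step Bernoulli, "every N steps on average")
            if rng.random() < p_trial:
                trials += 1
                new_cell = propose_lattice_move(state, barostat, rng)
                if new_cell is not None:
                    trial_state = replace(state, coords=rescale_coordinates(state, new_cell),
                                          cell=new_cell)
                    rho = trial_state.density
                    if barostat.rho_min <= rho <= barostat.rho_max:
                        units = state.space_group.multiplicity
                        u_old = res.total
                        trial_res = evaluate(trial_state)
                        dE = barostat_delta_E(
                            trial_res.total - u_old,
                            state.cell.volume / units,
                            new_cell.volume / units,
                            state.n_molecules,
                            conditions,
                        )
                        if barostat_accept(dE, conditions, rng):
                            state = trial_state
                            res = trial_res
                            accepted += 1

            if (step + 1) % traj_stride == 0:
                trajectory.append({
                    "step": step + 1,
                    "lam": state.lam,
                    "U": res.total,
                    "F_lam": res.dU_dlam,
                    "volume": state.cell.volume,
                    "density": state.density,
                })

            if interactions and (step + 1) % snap_stride == 0 and state.lam > 0.8:
                mini = minimize_crystal(
                    replace(state.copy(), lam=1.0),
                    rms_target=snapshot_minimize_rms,
                    params=alchemical,
                )
                e_min = mini.energy
                if snapshot_criterion(state.lam, e_min, min(best_energy, e_min)):
                    snapshots.append(Snapshot(
                        mini.state, e_min, mini.state.density, state.lam, step + 1))
                best_energy = min(best_energy, e_min)
    except FloatingPointError as exc:
        return WalkerResult(state, snapshots, grid, trajectory, accepted, trials,
                            status=1, message=f"energy blow-up: {exc}")
    return WalkerResult(state, snapshots, grid, trajectory, accepted, trials)
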