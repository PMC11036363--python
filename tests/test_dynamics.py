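import math
from dataclasses import replace

import numpy as np
import pytest

from polyxtal import CrystalState, UnitCell, get_space_group
from polyxtal.dynamics import (ACC, BarostatParams, DynamicsParams,
                               ThermoConditions, barostat_accept,
                               barostat_delta_E, langevin_step,
                               lattice_dof_moves, propose_lattice_move,
                               random_initial_state, rescale_coordinates,
                               run_walker, sample_asu_volumes,
                               sample_lambda_well, snapshot_criterion)
from polyxtal.energy import ATM_A3_TO_KCAL, KB
from polyxtal.fixtures import make_analytic_lambda_well
from polyxtal.symmetry import LATTICE_SYSTEMS, count_lattice_dof

COND = ThermoConditions()


def _lj_state(lj_system, cell=None, symbol="P1"):
    cell = cell or UnitCell(4.0, 4.0, 4.0, 90, 90, 90)
    return CrystalState(lj_system.topology, np.zeros((1, 3)), cell,
                        get_space_group(symbol), 1.0)


# ---------------------------------------------------------------------------
# Langevin integrator


def test_zero_force_zero_friction_uniform_drift():
    params = DynamicsParams(timestep=2.0, friction=0.0)
    x = np.zeros((1, 3))
    v = np.array([[1.0, -0.5, 0.25]])
    f = np.zeros((1, 3))
    rng = np.random.default_rng(0)
    x, v, _ = langevin_step(x, v, f, [1.0], params, COND.kT, rng)
    assert np.allclose(x, [[2.0, -1.0, 0.5]])


def test_equipartition_harmonic_oscillator(rng):
    """⟨KE⟩ per DoF equals k_BT/2 within 3 SE for a thermostatted oscillator."""
    k = 10.0  # kcal/mol/Å²
    m = np.array([12.0])
    params = DynamicsParams(timestep=1.0, friction=10.0)
    x = np.zeros((1, 3))
    v = np.zeros((1, 3))
    f = -2.0 * k * x
    kes = []
    for step in range(60000):
        x, v, f = langevin_step(x, v, f, m, params, COND.kT, rng,
                                force_fn=lambda xx: -2.0 * k * xx)
        if step > 10000 and step % 10 == 0:
            kes.append(0.5 * m[0] * float(np.sum(v**2)) / ACC)
    kes = np.array(kes) / 3.0  # per DoF
    target = 0.5 * COND.kT
    blocks = kes[:len(kes) // 20 * 20].reshape(20, -1).mean(axis=1)
    se = blocks.std(ddof=1) / math.sqrt(len(blocks))
    assert abs(kes.mean() - target) < 3 * se + 1e-4


def test_same_seed_bit_identical_trajectories(lj_system):
    state = _lj_state(lj_system)
    dyn = DynamicsParams(seed=99, n_steps=300)
    r1 = run_walker(state, COND, dyn)
    r2 = run_walker(state, COND, dyn)
    assert np.array_equal(r1.state.coords, r2.state.coords)
    assert r1.state.lam == r2.state.lam
    assert [f["U"] for f in r1.trajectory] == [f["U"] for f in r2.trajectory]


# ---------------------------------------------------------------------------
# λ-dynamics


def test_lambda_walk_covers_unit_interval():
    """Flat potential + flat bias: λ random-walks across [0, 1], visiting
    both endpoint deciles."""

    class FlatWell:
        def energy(self, lam):
            return 0.0

        def dU_dlam(self, lam):
            return 0.0

        def d2U_dlam2(self, lam):
            return 0.0

    grid, lams = sample_lambda_well(FlatWell(), n_steps=100_000, seed=12,
                                    apply_bias=False)
    assert (lams < 0.1).sum() > 0
    assert (lams > 0.9).sum() > 0


def test_lambda_restrained_to_one():
    """A strong restraint toward λ = 1 keeps λ near 1."""

    class Restraint:
        def energy(self, lam):
            return 50.0 * (1 - lam) ** 2

        def dU_dlam(self, lam):
            return -100.0 * (1 - lam)

        def d2U_dlam2(self, lam):
            return 100.0

    # bias off: pure restrained dynamics must match the Boltzmann weight
    grid, lams = sample_lambda_well(Restraint(), n_steps=30_000, seed=3,
                                    apply_bias=False)
    assert lams[5000:].mean() > 0.9


# ---------------------------------------------------------------------------
# barostat proposals


def test_midpoint_draw_gives_zero_move(lj_system, monkeypatch):
    state = _lj_state(lj_system, symbol="P1")

    class MidRng:
        def integers(self, n):
            return 0  # first dof: a length group

        def random(self):
            return 0.5

    cell = propose_lattice_move(state, BarostatParams(), MidRng())
    assert cell.volume == pytest.approx(state.cell.volume, abs=1e-12)


def test_volume_move_magnitude(lj_system):
    """x = 0.75 with v_max = 1 gives ΔV = +0.5 Å³ on the explicit unit."""
    state = _lj_state(lj_system)

    class FixedRng:
        def integers(self, n):
            return 0

        def random(self):
            return 0.75

    cell = propose_lattice_move(state, BarostatParams(v_max=1.0), FixedRng())
    assert cell.volume - state.cell.volume == pytest.approx(0.5, abs=1e-10)


@pytest.mark.parametrize("symbol,system", [
    ("P1", "triclinic"), ("P21/c", "monoclinic"), ("Pbca", "orthorhombic"),
    ("R-3", "hexagonal"),
])
def test_lattice_constraints_exact_after_many_moves(lj_system, symbol, system, rng):
    cells = {
        "triclinic": UnitCell(4, 5, 6, 80, 100, 95),
        "monoclinic": UnitCell(4, 5, 6, 90, 100, 90),
        "orthorhombic": UnitCell(4, 5, 6, 90, 90, 90),
        "hexagonal": UnitCell(5, 5, 7, 90, 90, 120),
    }
    state = CrystalState(lj_system.topology, np.zeros((1, 3)), cells[system],
                         get_space_group(symbol), 1.0)
    cell = state.cell
    for _ in range(5000):
        proposal = propose_lattice_move(replace(state, cell=cell),
                                        BarostatParams(), rng)
        if proposal is not None:
            cell = proposal
    if system == "monoclinic":
        assert cell.alpha == 90.0 and cell.gamma == 90.0
    elif system == "orthorhombic":
        assert (cell.alpha, cell.beta, cell.gamma) == (90.0, 90.0, 90.0)
    elif system == "hexagonal":
        assert cell.a == cell.b
        assert (cell.alpha, cell.beta, cell.gamma) == (90.0, 90.0, 120.0)


def test_angle_move_preserves_volume(lj_system, rng):
    state = _lj_state(lj_system, UnitCell(4, 5, 6, 80, 100, 95), "P1")

    class AngleRng:
        def __init__(self, inner):
            self.inner = inner

        def integers(self, n):
            return 4  # beta, for triclinic ordering (3 lengths + 3 angles)

        def random(self):
            return self.inner.random()

    for _ in range(50):
        cell = propose_lattice_move(state, BarostatParams(), AngleRng(rng))
        if cell is None:
            continue
        assert cell.volume == pytest.approx(state.cell.volume, rel=1e-12)
        assert cell.beta != state.cell.beta


def test_dof_move_count_matches_lattice_dof():
    for system, dof in LATTICE_SYSTEMS.items():
        assert len(lattice_dof_moves(system)) == count_lattice_dof(system) == dof


# ---------------------------------------------------------------------------
# barostat acceptance


def test_delta_E_identity_move():
    assert barostat_delta_E(0.0, 100.0, 100.0, 1, COND) == 0.0


def test_delta_E_closed_form():
    v = 120.0
    de = barostat_delta_E(0.0, v, 2 * v, 1, COND)
    expected = COND.pressure * v * ATM_A3_TO_KCAL - COND.kT * math.log(2.0)
    assert de == pytest.approx(expected, rel=1e-12)


def test_delta_E_rejects_nonpositive_volume():
    with pytest.raises(ValueError):
        barostat_delta_E(0.0, -1.0, 2.0, 1, COND)


def test_accept_rules(rng):
    assert barostat_accept(-5.0, COND, rng) is True
    # ΔE = 0: e^0 = 1, always accepted
    assert all(barostat_accept(0.0, COND, rng) for _ in range(100))


def test_accept_rate_matches_boltzmann(rng):
    """Empirical acceptance at ΔE = k_BT equals e^(−1) within 3 SE."""
    n = 100_000
    acc = sum(barostat_accept(COND.kT, COND, rng) for _ in range(n)) / n
    p = math.exp(-1.0)
    se = math.sqrt(p * (1 - p) / n)
    assert abs(acc - p) < 3 * se


def test_ideal_gas_volume_distribution(lj_system):
    """Detailed balance: ideal-gas ASU volumes follow V·e^(−βpV); the mean
    is (n+1)k_BT/p within 3 block-averaged SE."""
    cond = ThermoConditions(298.15, 2000.0)
    bp = BarostatParams(rho_min=1e-9, rho_max=1e9, v_max=5.0)
    state = _lj_state(lj_system, UnitCell(3.5, 3.5, 3.5, 90, 90, 90))
    vols = sample_asu_volumes(state, cond, bp, 100_000,
                              np.random.default_rng(7))
    burn = vols[20_000:]
    target = 2.0 * KB * 298.15 / (2000.0 * ATM_A3_TO_KCAL)
    blocks = burn.reshape(40, -1).mean(axis=1)
    se = blocks.std(ddof=1) / math.sqrt(len(blocks))
    assert abs(burn.mean() - target) < 3 * se


def test_density_bounds_auto_reject(lj_system):
    """Out-of-band proposals are rejected before any energy call."""
    calls = []

    def energy_fn(state):
        calls.append(state.density)
        return 0.0

    cond = ThermoConditions()
    bp = BarostatParams(rho_min=0.75, rho_max=1.6, v_max=5.0)
    state = _lj_state(lj_system, UnitCell(3.6, 3.6, 3.6, 90, 90, 90))
    sample_asu_volumes(state, cond, bp, 3000, np.random.default_rng(1),
                       energy_fn=energy_fn)
    assert all(0.75 <= rho <= 1.6 for rho in calls)


# ---------------------------------------------------------------------------
# coordinate rescaling


def test_rescale_identity(ring_system):
    cell = UnitCell(8, 9, 10, 90, 100, 90)
    st = CrystalState(ring_system.topology,
                      ring_system.reference["coords"] + [1, 2, 1.5],
                      cell, get_space_group("P21/c"), 1.0)
    out = rescale_coordinates(st, cell)
    assert np.allclose(out, st.coords, atol=1e-14)


def test_rescale_preserves_geometry_and_com(ring_system):
    cell = UnitCell(8, 9, 10, 90, 100, 90)
    st = CrystalState(ring_system.topology,
                      ring_system.reference["coords"] + [1, 2, 1.5],
                      cell, get_space_group("P21/c"), 1.0)
    new_cell = UnitCell(8.7, 8.6, 10.9, 90, 97, 90)
    out = rescale_coordinates(st, new_cell)
    # intramolecular distances bit-preserved
    d_old = np.linalg.norm(st.coords[:, None] - st.coords[None, :], axis=2)
    d_new = np.linalg.norm(out[:, None] - out[None, :], axis=2)
    assert np.abs(d_old - d_new).max() < 1e-12
    # COM fractional coordinates unchanged
    w = ring_system.topology.masses / ring_system.topology.molecular_mass
    f_old = st.cell.cart_to_frac(w @ st.coords)
    f_new = new_cell.cart_to_frac(w @ out)
    assert np.abs(f_old - f_new).max() < 1e-12


# ---------------------------------------------------------------------------
# snapshots and the walker


@pytest.mark.parametrize("lam,dE,expected", [
    (0.85, 3.0, True),
    (0.70, 0.0, False),
    (0.95, 12.0, False),
])
def test_snapshot_criterion(lam, dE, expected):
    assert snapshot_criterion(lam, dE, 0.0) is expected


def test_walker_zero_steps_returns_initial(lj_system):
    state = _lj_state(lj_system)
    res = run_walker(state, COND, DynamicsParams(n_steps=0))
    assert res.trajectory == [] and res.snapshots == []
    assert np.allclose(res.state.coords, state.coords)


def test_walker_snapshots_satisfy_criterion(lj_system):
    state = _lj_state(lj_system, UnitCell(3.8, 3.9, 4.0, 90, 90, 90))
    dyn = DynamicsParams(seed=5, n_steps=4000, snapshot_stride_ps=0.2)
    res = run_walker(state, COND, dyn)
    assert res.status == 0
    for snap in res.snapshots:
        assert snap.lam > 0.8
    energies = [s.energy for s in res.snapshots]
    if energies:
        assert max(energies) - min(energies) <= 10.0 + 1e-9


def test_random_initial_state_inside_density_band(lj_system, ring_system, rng):
    bp = BarostatParams()
    for topology in (lj_system.topology, ring_system.topology):
        for symbol in ("P1", "P21/c", "Pbca", "R-3"):
            st = random_initial_state(topology, get_space_group(symbol), bp, rng,
                                      coords=None)
            assert bp.rho_min <= st.density <= bp.rho_max
            assert st.lam == 0.0
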