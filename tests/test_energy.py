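import math
from dataclasses import replace

import numpy as np
import pytest

from polyxtal import (AlchemicalParams, CrystalState, UnitCell, bonded_energy,
                      expand_to_p1, get_space_group, intermolecular_energy,
                      replicate_cell, softcore_vdw_pair, total_potential)
from polyxtal.symmetry import available_space_groups

PARAMS = AlchemicalParams()


# ---------------------------------------------------------------------------
# bonded terms


def test_bonded_zero_at_equilibrium(ring_system):
    coords = ring_system.reference["coords"]
    assert bonded_energy(ring_system.topology, coords).total == pytest.approx(0.0, abs=1e-12)


def test_bond_stretch_closed_form(small_molecule):
    """A single bond stretched by 0.1 Å at k_b = 300 costs 3.0 kcal/mol."""
    coords = np.array([[0.0, 0, 0], [1.6, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
    topo = replace_bonds(small_molecule)
    e = bonded_energy(topo, coords).total
    assert e == pytest.approx(300.0 * 0.1**2, abs=1e-12)


def replace_bonds(topology):
    """Topology with only the first bond retained."""
    from dataclasses import replace as dc_replace

    return dc_replace(topology, bonds=[topology.bonds[0]], angles=[], torsions=[])


def test_bonded_gradient_matches_finite_differences(small_molecule, rng):
    coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.1, 1.2, 0.3], [3.0, 1.1, 0.9]])
    coords = coords + rng.normal(0, 0.08, coords.shape)
    res = bonded_energy(small_molecule, coords)
    h = 1e-6
    for i in range(4):
        for k in range(3):
            cp, cm = coords.copy(), coords.copy()
            cp[i, k] += h
            cm[i, k] -= h
            fd = (bonded_energy(small_molecule, cp).total
                  - bonded_energy(small_molecule, cm).total) / (2 * h)
            assert abs(fd - res.gradient[i, k]) < 1e-6


# ---------------------------------------------------------------------------
# softcore buffered 14-7


def test_vdw_minimum_at_r0_fully_coupled():
    assert softcore_vdw_pair(3.8, 0.25, 3.8, 1.0, PARAMS) == pytest.approx(-0.25, abs=1e-12)


def test_vdw_uncoupled_is_zero():
    for r in (0.0, 1.0, 3.8, 11.0):
        assert softcore_vdw_pair(r, 0.25, 3.8, 0.0, PARAMS) == 0.0


def test_vdw_softcore_finite_at_contact():
    v = softcore_vdw_pair(0.0, 0.25, 3.8, 0.5, PARAMS)
    assert np.isfinite(v)


def test_vdw_vanishes_beyond_cutoff():
    assert softcore_vdw_pair(12.5, 0.25, 3.8, 1.0, PARAMS) == 0.0


def test_vdw_continuous_in_lambda():
    lams = np.linspace(0.001, 1.0, 200)
    vals = np.array([softcore_vdw_pair(3.0, 0.25, 3.8, l, PARAMS) for l in lams])
    assert np.all(np.isfinite(vals))
    assert np.abs(np.diff(vals)).max() < 0.05  # no jumps on a fine grid


# ---------------------------------------------------------------------------
# intermolecular energy


def test_uncoupled_state_has_zero_intermolecular(chain_state):
    st = replace(chain_state, lam=0.0)
    res = intermolecular_energy(st, PARAMS)
    assert res.total == 0.0 and res.dU_dlam == 0.0


def test_single_atom_lattice_sum_matches_brute_force(lj_system):
    """P1 cubic single-atom crystal equals a direct image sum."""
    a = 5.0
    cell = UnitCell(a, a, a, 90, 90, 90)
    st = CrystalState(lj_system.topology, np.zeros((1, 3)), cell,
                      get_space_group("P1"), 1.0)
    res = intermolecular_energy(st, PARAMS)
    eps, r0 = 0.238, 3.82
    nmax = int(math.ceil(PARAMS.cutoff / a)) + 1
    brute = 0.0
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            for k in range(-nmax, nmax + 1):
                if i == j == k == 0:
                    continue
                r = a * math.sqrt(i * i + j * j + k * k)
                if r < PARAMS.cutoff:
                    brute += 0.5 * softcore_vdw_pair(r, eps, r0, 1.0, PARAMS)
    assert res.total == pytest.approx(brute, abs=1e-10)


CELL_BY_SYSTEM = {
    "triclinic": UnitCell(8.0, 9.0, 10.0, 85.0, 100.0, 95.0),
    "monoclinic": UnitCell(8.0, 9.0, 10.0, 90.0, 100.0, 90.0),
    "orthorhombic": UnitCell(8.0, 9.0, 10.0, 90.0, 90.0, 90.0),
    "hexagonal": UnitCell(10.0, 10.0, 12.0, 90.0, 90.0, 120.0),
}


@pytest.mark.parametrize("group", [g.symbol for g in available_space_groups()])
def test_representation_equivalence_all_groups(ring_system, group):
    """Per-molecule energy is identical for ASU-symmetric, P1-expanded and
    replicated representations of the same crystal (the cell respects the
    group's lattice system, as any consistent crystal must)."""
    sg = get_space_group(group)
    st = CrystalState(ring_system.topology,
                      ring_system.reference["coords"] + [1.0, 2.0, 1.5],
                      CELL_BY_SYSTEM[sg.lattice_system],
                      sg, 1.0)
    e_asu = intermolecular_energy(st, PARAMS).total
    p1 = expand_to_p1(st, check_overlap=False)
    e_p1 = intermolecular_energy(p1, PARAMS).total / p1.n_molecules
    rep = replicate_cell(p1, 2, 1, 2)
    e_rep = intermolecular_energy(rep, PARAMS).total / rep.n_molecules
    assert e_asu == pytest.approx(e_p1, abs=1e-6)
    assert e_asu == pytest.approx(e_rep, abs=1e-6)


def test_translation_invariance(ring_system):
    cell = UnitCell(8, 9, 10, 90, 100, 90)
    st = CrystalState(ring_system.topology, ring_system.reference["coords"],
                      cell, get_space_group("P1"), 1.0)
    e1 = total_potential(st, PARAMS).total
    st2 = replace(st, coords=st.coords + np.array([1.3, -2.2, 0.7]))
    assert total_potential(st2, PARAMS).total == pytest.approx(e1, abs=1e-9)


# ---------------------------------------------------------------------------
# derivatives


def test_gradient_matches_finite_differences(chain_state):
    res = total_potential(chain_state, PARAMS)
    h = 1e-5
    for i in range(4):
        for k in range(3):
            cp, cm = chain_state.coords.copy(), chain_state.coords.copy()
            cp[i, k] += h
            cm[i, k] -= h
            fd = (total_potential(replace(chain_state, coords=cp), PARAMS).total
                  - total_potential(replace(chain_state, coords=cm), PARAMS).total) / (2 * h)
            assert abs(fd - res.gradient[i, k]) < 1e-6


def test_dU_dlam_matches_finite_differences(chain_state):
    res = total_potential(chain_state, PARAMS)
    h = 1e-6
    fd = (total_potential(replace(chain_state, lam=chain_state.lam + h), PARAMS).total
          - total_potential(replace(chain_state, lam=chain_state.lam - h), PARAMS).total) / (2 * h)
    assert abs(fd - res.dU_dlam) < 1e-6


def test_mixed_second_derivative_matches_finite_differences(chain_state):
    """∂²U/∂λ∂x (the OST chain-rule force ingredient) against FD of ∂U/∂λ."""
    res = total_potential(chain_state, PARAMS)
    h = 1e-5
    for i in range(4):
        for k in (0, 1, 2):
            cp, cm = chain_state.coords.copy(), chain_state.coords.copy()
            cp[i, k] += h
            cm[i, k] -= h
            fd = (total_potential(replace(chain_state, coords=cp), PARAMS).dU_dlam
                  - total_potential(replace(chain_state, coords=cm), PARAMS).dU_dlam) / (2 * h)
            assert abs(fd - res.d2U_dlamdx[i, k]) < 1e-6


def test_d2U_dlam2_matches_finite_differences(chain_state):
    res = total_potential(chain_state, PARAMS)
    h = 1e-5
    fd = (total_potential(replace(chain_state, lam=chain_state.lam + h), PARAMS).dU_dlam
          - total_potential(replace(chain_state, lam=chain_state.lam - h), PARAMS).dU_dlam) / (2 * h)
    assert abs(fd - res.d2U_dlam2) < 1e-6


def test_dU_dlam_zero_at_vacuum_endpoint(chain_state):
    res = total_potential(replace(chain_state, lam=0.0), PARAMS)
    assert res.dU_dlam == 0.0


def test_lambda_exponent_validation():
    with pytest.raises(ValueError):
        AlchemicalParams(lambda_exponent=1)
    with pytest.raises(ValueError):
        AlchemicalParams(softcore_alpha=0.0)


# ---------------------------------------------------------------------------
# physical sanity


def test_repulsive_clash_monotone_in_lambda(lj_system):
    """For a purely repulsive clashing state, U(λ) is nondecreasing.

    A short cutoff keeps only the clashing first shell (r = 2.5 Å, well
    inside r0 = 3.82) so every interaction on the λ path is repulsive.
    """
    params = AlchemicalParams(cutoff=3.0, taper_width=0.4)
    cell = UnitCell(2.5, 2.5, 2.5, 90, 90, 90)
    vals = []
    for lam in np.linspace(0.0, 1.0, 51):
        st = CrystalState(lj_system.topology, np.zeros((1, 3)), cell,
                          get_space_group("P1"), float(lam))
        vals.append(intermolecular_energy(st, params).total)
    assert vals[0] == 0.0 and vals[-1] > 0.0
    # the softcore deformation admits a sub-1e-4 attractive dip near λ=0
    # (the buffered well's attractive branch is briefly visited); beyond
    # that the coupling is strictly nondecreasing
    assert np.all(np.diff(vals) >= -1e-3)
    lams = np.linspace(0.0, 1.0, 51)
    assert np.all(np.diff(np.asarray(vals)[lams[:] >= 0.3]) >= 0.0)


def test_energy_conservation_nve(ring_system):
    """Velocity-Verlet NVE on a toy crystal drifts < 1e-4 kcal/mol/ps/DoF."""
    from polyxtal.dynamics import ACC

    topo = ring_system.topology
    cell = UnitCell(7.0, 7.5, 8.0, 90, 95, 90)
    st = CrystalState(topo, ring_system.reference["coords"] + [0.5, 0.3, 0.2],
                      cell, get_space_group("P1"), 1.0)
    rng = np.random.default_rng(5)
    masses = topo.masses
    kT = 0.59248  # ~298 K in kcal/mol
    v = rng.standard_normal((topo.n_atoms, 3)) * np.sqrt(kT * ACC / masses)[:, None]
    dt = 1.0  # fs
    res = total_potential(st, PARAMS)

    def etot(st, v, res):
        ke = 0.5 * float(np.sum(masses[:, None] * v**2)) / ACC
        return res.total + ke

    n_steps = 2000
    x = st.coords.copy()
    energies = np.empty(n_steps)
    for step in range(n_steps):
        v = v + 0.5 * dt * (-res.gradient) * (ACC / masses)[:, None]
        x = x + dt * v
        st = replace(st, coords=x)
        res = total_potential(st, PARAMS)
        v = v + 0.5 * dt * (-res.gradient) * (ACC / masses)[:, None]
        energies[step] = etot(st, v, res)
    # secular drift: difference of first/last window means averages out the
    # bounded symplectic-integrator oscillation
    w = n_steps // 10
    drift = abs(energies[-w:].mean() - energies[:w].mean())
    dof = 3 * topo.n_atoms
    ps = n_steps * dt / 1000.0
    assert drift / dof / ps < 1e-4


def test_nan_guard(chain_state):
    bad = replace(chain_state, coords=chain_state.coords * np.nan)
    with pytest.raises(FloatingPointError):
        total_potential(bad, PARAMS)
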