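"""Screened Coulomb, SES meshing/areas and the finite-difference Poisson
reaction field, validated against closed forms and brute-force oracles."""
from types import SimpleNamespace

import numpy as np
import networkx as nx
import pytest

from siepka.analytic import born_energy, kirkwood_energy
from siepka.electrostatics import (COULOMB_K, SolverSettings, build_ses,
                                   build_ses_system, coulomb_energy,
                                   reaction_field_energy, sidechain_surface,
                                   total_electrostatic_energy)
from siepka.fixtures import FixtureSpec, make_fixture
from siepka.structure import materialize

from conftest import load_fixture_structure

SETTINGS = SolverSettings()
NOPAIRS = dict(excl_pairs=np.zeros((0, 2), dtype=int),
               pair14=np.zeros((0, 2), dtype=int))


def point_system(coords, charges, radii=None, excl=None, p14=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return SimpleNamespace(
        coords=coords, charges=np.asarray(charges, dtype=float),
        radii=np.asarray(radii if radii is not None else [1.5] * n),
        elements=["X"] * n,
        excl_pairs=np.asarray(excl if excl is not None else
                              np.zeros((0, 2), int)).reshape(-1, 2),
        pair14=np.asarray(p14 if p14 is not None else
                          np.zeros((0, 2), int)).reshape(-1, 2))


# ---------------------------------------------------------------------------
# Coulomb

def test_coulomb_hand_value():
    """Two unit charges at 3.32 Å in ε=2.25: 332.0637/(2.25·3.32)."""
    sys_ = point_system([[0, 0, 0], [3.32, 0, 0]], [1.0, 1.0])
    e = coulomb_energy(sys_, SETTINGS)
    assert e == pytest.approx(332.0637 / (2.25 * 3.32), rel=1e-9)
    assert e == pytest.approx(44.45, abs=0.01)


def test_excluded_pairs_contribute_zero():
    sys_ = point_system([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]],
                        [1.0, -0.5, 0.7], excl=[[0, 1], [0, 2], [1, 2]])
    assert coulomb_energy(sys_, SETTINGS) == 0.0


def test_one_four_scaled_exactly_five_sixths():
    sys_full = point_system([[0, 0, 0], [4.0, 0, 0]], [1.0, 1.0])
    sys_14 = point_system([[0, 0, 0], [4.0, 0, 0]], [1.0, 1.0],
                          p14=[[0, 1]])
    assert coulomb_energy(sys_14, SETTINGS) == pytest.approx(
        5.0 / 6.0 * coulomb_energy(sys_full, SETTINGS), rel=1e-12)


def test_overlapping_charged_pair_raises():
    sys_ = point_system([[0, 0, 0], [0.05, 0, 0]], [1.0, 1.0])
    with pytest.raises(FloatingPointError):
        coulomb_energy(sys_, SETTINGS)


def test_coulomb_exclusions_against_bond_graph_oracle(helix_his_structure):
    """Total Coulomb equals a from-scratch sum using shortest bond paths."""
    sys_ = materialize(helix_his_structure, 0)
    e_impl = coulomb_energy(sys_, SETTINGS)
    g = nx.Graph(sys_.bonds)
    dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
    coords, q = sys_.coords, sys_.charges
    e_ref = 0.0
    for i in range(len(q)):
        for j in range(i + 1, len(q)):
            d = dist.get(i, {}).get(j, 99)
            if d in (1, 2):
                continue
            scale = 5.0 / 6.0 if d == 3 else 1.0
            r = np.linalg.norm(coords[i] - coords[j])
            e_ref += scale * q[i] * q[j] / r
    e_ref *= COULOMB_K / SETTINGS.epsilon_in
    assert e_impl == pytest.approx(e_ref, abs=1e-8)


def test_disjoint_group_interaction_energy():
    """Group-group mode sums only cross pairs."""
    sys_ = point_system([[0, 0, 0], [3.0, 0, 0], [0, 5.0, 0]],
                        [1.0, 1.0, -1.0])
    e_ab = coulomb_energy(sys_, SETTINGS, group_a=[0, 1], group_b=[2])
    r02 = 5.0
    r12 = np.hypot(3.0, 5.0)
    expect = COULOMB_K / 2.25 * (-1.0 / r02 - 1.0 / r12)
    assert e_ab == pytest.approx(expect, rel=1e-12)


# ---------------------------------------------------------------------------
# SES mesh and areas

def test_single_sphere_area_closed_form():
    r_vdw = 1.65 / SETTINGS.radius_scale
    mesh = build_ses([[0.0, 0.0, 0.0]], [r_vdw], SETTINGS)
    assert mesh.total_area == pytest.approx(4 * np.pi * 1.65 ** 2, rel=0.05)


def test_coincident_spheres_area_is_one_sphere():
    r_vdw = 1.65 / SETTINGS.radius_scale
    one = build_ses([[0.0, 0.0, 0.0]], [r_vdw], SETTINGS)
    two = build_ses([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]], [r_vdw, r_vdw],
                    SETTINGS)
    assert two.total_area == pytest.approx(one.total_area, rel=1e-6)


def test_disjoint_spheres_area_sum():
    """Far-separated spheres: two closed components, areas add."""
    r1, r2 = 2.0, 1.5
    mesh = build_ses([[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]],
                     [r1 / 1.1, r2 / 1.1], SETTINGS)
    expect = 4 * np.pi * (r1 ** 2 + r2 ** 2)
    assert mesh.total_area == pytest.approx(expect, rel=0.05)
    # owner partition covers the whole mesh exactly
    a0 = mesh.areas[mesh.owner_atom == 0].sum()
    a1 = mesh.areas[mesh.owner_atom == 1].sum()
    assert a0 + a1 == pytest.approx(mesh.total_area, abs=1e-9)
    assert a0 == pytest.approx(4 * np.pi * r1 ** 2, rel=0.05)


def test_mesh_watertight():
    import trimesh
    mesh = build_ses([[0.0, 0.0, 0.0]], [2.0 / 1.1], SETTINGS)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=True)
    assert tm.is_watertight
    assert tm.euler_number == 2


def test_psesa_subset_of_sesa(helix_his_structure):
    sys_ = materialize(helix_his_structure, 0)
    mesh = build_ses_system(sys_, SETTINGS)
    sesa, psesa = sidechain_surface(mesh, sys_, 4)
    assert 0.0 <= psesa <= sesa
    assert sesa > 20.0  # solvent-exposed by construction


def test_enclosed_his_has_zero_sesa():
    fx = make_fixture(FixtureSpec(kind="burial_cage"))
    st = load_fixture_structure(fx)
    sys_ = materialize(st, 0)
    mesh = build_ses_system(sys_, SETTINGS)
    sesa, psesa = sidechain_surface(mesh, sys_, 0)
    assert sesa == 0.0 and psesa == 0.0


def test_free_his_sesa_large():
    fx = make_fixture(FixtureSpec(kind="free_residue"))
    st = load_fixture_structure(fx)
    sys_ = materialize(st, 0)
    mesh = build_ses_system(sys_, SETTINGS)
    sesa, _ = sidechain_surface(mesh, sys_, 0)
    assert sesa > 20.0


# ---------------------------------------------------------------------------
# reaction field

@pytest.mark.parametrize("q", [1.0, -1.0])
@pytest.mark.parametrize("a", [1.5, 2.0, 3.0])
def test_born_oracle_within_two_percent(q, a):
    sys_ = point_system([[0.0, 0.0, 0.0]], [q],
                        radii=[a / SETTINGS.radius_scale])
    e = reaction_field_energy(sys_, SETTINGS)
    ref = born_energy(q, a, SETTINGS.epsilon_in, SETTINGS.epsilon_out)
    assert e < 0
    assert abs(e - ref) / abs(ref) <= 0.02


def test_kirkwood_two_charge_sphere_within_three_percent():
    sys_ = point_system([[0, 0, 1.0], [0, 0, -1.0], [0, 0, 0]],
                        [1.0, -1.0, 0.0],
                        radii=[0.1, 0.1, 4.0 / SETTINGS.radius_scale])
    e = reaction_field_energy(sys_, SETTINGS)
    ref = kirkwood_energy([[0, 0, 1.0], [0, 0, -1.0]], [1.0, -1.0], 4.0,
                          SETTINGS.epsilon_in, SETTINGS.epsilon_out, lmax=30)
    assert abs(e - ref) / abs(ref) <= 0.03


def test_zero_charge_gives_exactly_zero():
    sys_ = point_system([[0.0, 0.0, 0.0]], [0.0], radii=[2.0])
    assert reaction_field_energy(sys_, SETTINGS) == 0.0


def test_reaction_field_negative_for_net_charge(free_his_structure):
    sys_ = materialize(free_his_structure, 0, overrides={0: ("HIP", None)})
    assert reaction_field_energy(sys_, SETTINGS) < 0.0


def test_rigid_motion_invariance(fast_settings):
    """Total electrostatic energy is invariant (<0.05 kcal/mol) under
    rigid-body rotation + translation (the grid re-centres on the solute)."""
    coords = np.array([[0.0, 0.0, 0.0], [3.1, 0.4, -0.2], [1.2, 2.2, 1.0]])
    q = [0.6, -1.0, 0.4]
    radii = [1.9, 1.7, 1.6]
    sys_a = point_system(coords, q, radii)
    e_a = total_electrostatic_energy(sys_a, SETTINGS).total

    from siepka.geometry import rotation_about_axis
    rot = rotation_about_axis(np.array([1.0, 2.0, 0.5]), 37.0)
    moved = coords @ rot.T + np.array([5.3, -2.1, 7.7])
    sys_b = point_system(moved, q, radii)
    e_b = total_electrostatic_energy(sys_b, SETTINGS).total
    assert abs(e_a - e_b) < 0.05


def test_state_difference_converges_under_refinement(free_his_structure):
    """ΔE between two protonation states moves < 0.1 kcal/mol when the fine
    spacing is halved (differences converge faster than absolute energies)."""
    def de(spacing):
        s = SolverSettings(grid_spacing=spacing)
        e = {}
        for lab in ("HIP", "HIE"):
            sys_ = materialize(free_his_structure, 0,
                               overrides={0: (lab, None)})
            e[lab] = (coulomb_energy(sys_, s)
                      + reaction_field_energy(sys_, s))
        return e["HIP"] - e["HIE"]

    assert abs(de(0.6) - de(0.3)) < 0.1


def test_grid_too_small_raises():
    s = SolverSettings(margin=0.1, fine_margin=0.0)
    sys_ = point_system([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]], [1.0, 1.0],
                        radii=[0.5, 0.5])
    with pytest.raises(ValueError):
        reaction_field_energy(sys_, s)
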