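"""Rotamer enumeration, protonation-state building and hydrogen-bond
network optimization."""
import numpy as np
import pandas as pd
import pytest

from siepka.electrostatics import COULOMB_K
from siepka.fixtures import FixtureSpec, make_fixture, _pdb_lines, _peptide
from siepka.geometry import place_atom
from siepka.params import ParameterSet
from siepka.sampling import (build_protonation_states, enumerate_rotamers,
                             optimize_hbond_network)
from siepka.structure import materialize, read_structure

from conftest import load_fixture_structure


# ---------------------------------------------------------------------------
# rotamers

def test_exposed_helix_his_keeps_multiple_rotamers(helix_his_structure):
    rots = enumerate_rotamers(helix_his_structure, ("A", 5, ""))
    assert rots[0].origin == "native"
    assert len(rots) >= 2


def test_caged_his_keeps_native_only():
    # a tight cage of fixed atoms ~3 Å from the ring: every alternative clashes
    fx = make_fixture(FixtureSpec(kind="burial_cage", shell_radius=3.5))
    st = load_fixture_structure(fx)
    rots = enumerate_rotamers(st, ("A", 1, ""))
    assert len(rots) == 1
    assert rots[0].origin == "native"


def test_chi_minimization_stays_within_window(tables):
    """A near-canonical Asp stays retained with χ1 within ±5° of canonical."""
    fx = make_fixture(FixtureSpec(kind="helix_with_target", restype="ASP"))
    st = read_structure(fx.pdb_text, params=tables)
    rots = enumerate_rotamers(st, ("A", 5, ""))
    lib = [r for r in rots if r.origin == "library"]
    assert lib
    for r in lib:
        canon = min(tables.rotamers["ASP"],
                    key=lambda c: abs((c[0] - r.chi[0] + 180) % 360 - 180))
        assert abs((r.chi[0] - canon[0] + 180) % 360 - 180) <= 5.0 + 1e-6


def test_nontarget_heavy_atoms_untouched(helix_his_structure):
    """Sampling only ever moves the target side chain."""
    st = helix_his_structure
    rots = enumerate_rotamers(st, ("A", 5, ""))
    base = materialize(st, 0)
    for rot in rots[:3]:
        sys_ = materialize(st, 0, overrides={4: ("HIE", dict(rot.coords))})
        for ridx in range(len(st.residues)):
            if ridx == 4:
                continue
            i0 = base.atoms_of_residue(ridx)
            i1 = sys_.atoms_of_residue(ridx)
            heavy0 = [k for k in i0 if base.elements[k] != "H"]
            heavy1 = [k for k in i1 if sys_.elements[k] != "H"]
            assert (base.coords[heavy0] == sys_.coords[heavy1]).all()


# ---------------------------------------------------------------------------
# protonation states

def test_state_cardinality_and_charges(helix_his_structure, tables):
    rots = enumerate_rotamers(helix_his_structure, ("A", 5, ""))
    his_states = build_protonation_states(rots[0], "HIS")
    assert len(his_states) == 6
    charged = [s for s in his_states if tables.formal_charge(s.label) == 1]
    assert sorted(s.state for s in charged) == ["HIP", "HIP-flip"]

    fx = make_fixture(FixtureSpec(kind="helix_with_target", restype="ASP"))
    st = load_fixture_structure(fx)
    arots = enumerate_rotamers(st, ("A", 5, ""))
    asp_states = build_protonation_states(arots[0], "ASP")
    assert len(asp_states) == 5
    anionic = [s for s in asp_states if tables.formal_charge(s.label) == -1]
    assert [s.state for s in anionic] == ["ASP"]


def test_flip_exchanges_heavy_pair_positions(helix_his_structure):
    """The His ring flip swaps Nδ1/Cδ2 and Cε1/Nε2 coordinates exactly."""
    st = helix_his_structure
    plain = materialize(st, 0, overrides={4: ("HID", None)})
    flipped = materialize(st, 0, overrides={4: ("HID", None)}, flips={4})

    def pos(sys_, name):
        idx = [i for i in sys_.atoms_of_residue(4) if sys_.names[i] == name]
        return sys_.coords[idx[0]]

    for a, b in (("ND1", "CD2"), ("CE1", "NE2")):
        np.testing.assert_allclose(pos(plain, a), pos(flipped, b))
        np.testing.assert_allclose(pos(plain, b), pos(flipped, a))
    # protons differ: HD1 rides on ND1, which moved
    assert np.linalg.norm(pos(plain, "HD1") - pos(flipped, "HD1")) > 0.5


# ---------------------------------------------------------------------------
# hydrogen-bond network optimization

def _his_ser_structure(his_state="HIE"):
    """Free His (chain A) plus a Ser (chain B) whose OG sits 3.4 Å from
    the His Nδ1 acceptor."""
    tables = ParameterSet.load_default()
    his = _peptide("HIS", 1, 1)
    st0 = read_structure("\n".join(_pdb_lines(his)[0] + ["END"]) + "\n",
                         params=tables)
    sys0 = materialize(st0, 0, overrides={0: (his_state, None)})
    nd1 = sys0.coords[sys0.names.index("ND1")]
    cg = sys0.coords[sys0.names.index("CG")]
    ce1 = sys0.coords[sys0.names.index("CE1")]
    # approach along the Nδ1 lone pair: in the ring plane, opposite the
    # bisector of the two ring substituents
    lp = nd1 - 0.5 * (cg + ce1)
    lp /= np.linalg.norm(lp)
    og_target = nd1 + 3.0 * lp

    ser_bb = _peptide("ALA", 1, 1)[0][2]
    og = place_atom(ser_bb["CB"], ser_bb["CA"], ser_bb["N"], 1.41, 110.0, 180.0)
    ser_atoms = dict(ser_bb)
    ser_atoms["OG"] = og
    shift = og_target - og
    ser_atoms = {k: v + shift for k, v in ser_atoms.items()}
    lines_a, serial = _pdb_lines(his, chain="A")
    lines_b, _ = _pdb_lines([("SER", 1, ser_atoms)], chain="B",
                            start_serial=serial)
    st = read_structure("\n".join(lines_a + ["TER"] + lines_b + ["END"]) + "\n",
                        params=tables)
    st.residues[1].label = "SER"
    return st


def _oracle_torsion_energy(st, target_ridx, label, dof_ridx, hname, torsion):
    """Independent objective: full pairwise screened Coulomb of the system
    with the given torsion, excluded/1-4 pairs handled from first principles."""
    sys_ = materialize(st, 0, overrides={target_ridx: (label, None)},
                       h_torsions={(dof_ridx, hname): torsion})
    coords, q = sys_.coords, sys_.charges
    n = len(q)
    scale = np.ones((n, n))
    for i, j in sys_.excl_pairs:
        scale[i, j] = scale[j, i] = 0.0
    for i, j in sys_.pair14:
        scale[i, j] = scale[j, i] = 5.0 / 6.0
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    e = COULOMB_K / 2.25 * (np.outer(q, q) * scale / np.maximum(d, 0.5)).sum() / 2
    return float(e)


def test_ser_oh_points_at_his_acceptor_and_matches_bruteforce():
    """Grid search turns the Ser hydroxyl toward the His Nδ1 acceptor, and
    the chosen torsion equals the exhaustive-enumeration minimum."""
    st = _his_ser_structure()
    rots = enumerate_rotamers(st, ("A", 1, ""), library=[])
    state = [s for s in build_protonation_states(rots[0], "HIS")
             if s.state == "HIE"][0]
    opt = optimize_hbond_network(st, 0, state)
    assert (1, "HG") in opt.network_torsions
    chosen = opt.network_torsions[(1, "HG")]

    grid = np.arange(0.0, 360.0, 30.0)
    oracle = {t: _oracle_torsion_energy(st, 0, "HIE", 1, "HG", t)
              for t in grid}
    best = min(oracle, key=oracle.get)
    assert chosen == pytest.approx(best)

    # geometric check: the proton really points at the acceptor
    sys_ = materialize(st, 0, overrides={0: ("HIE", None)},
                       h_torsions={(1, "HG"): chosen})
    hg = sys_.coords[sys_.names.index("HG")]
    nd1 = sys_.coords[sys_.names.index("ND1")]
    d_opt = np.linalg.norm(hg - nd1)
    d_all = []
    for t in grid:
        s2 = materialize(st, 0, overrides={0: ("HIE", None)},
                         h_torsions={(1, "HG"): float(t)})
        d_all.append(np.linalg.norm(s2.coords[s2.names.index("HG")] - nd1))
    # within the grid resolution of pointing at the acceptor: among the
    # nearest few notches and far from the pointing-away orientations
    assert d_opt <= sorted(d_all)[2] + 1e-9
    assert d_opt < max(d_all) - 1.0


def test_network_objective_never_increases():
    st = _his_ser_structure()
    rots = enumerate_rotamers(st, ("A", 1, ""), library=[])
    for state in build_protonation_states(rots[0], "HIS"):
        opt = optimize_hbond_network(st, 0, state)
        default_t = 180.0   # the template default for the Ser hydroxyl
        e_def = _oracle_torsion_energy(st, 0, state.label, 1, "HG", default_t)
        e_opt = _oracle_torsion_energy(
            st, 0, state.label, 1, "HG",
            opt.network_torsions.get((1, "HG"), default_t))
        assert e_opt <= e_def + 1e-9


def test_no_polar_neighbors_returns_state_unchanged(helix_his_structure):
    rots = enumerate_rotamers(helix_his_structure, ("A", 5, ""), library=[])
    state = build_protonation_states(rots[0], "HIS")[0]
    opt = optimize_hbond_network(helix_his_structure, 4, state)
    assert opt is state


def test_asn_flip_matches_two_way_comparison(tables):
    """A flip candidate is set iff the flipped amide lowers the objective."""
    asp = _peptide("ASP", 1, 1)
    st0 = read_structure("\n".join(_pdb_lines(asp)[0] + ["END"]) + "\n",
                         params=tables)
    sys0 = materialize(st0, 0)
    od1 = sys0.coords[sys0.names.index("OD1")]
    cg = sys0.coords[sys0.names.index("CG")]
    direction = (od1 - cg) / np.linalg.norm(od1 - cg)

    asn_bb = _peptide("ALA", 1, 1)[0][2]
    cg_n = place_atom(asn_bb["CB"], asn_bb["CA"], asn_bb["N"], 1.52, 112.6, 180.0)
    od1_n = place_atom(cg_n, asn_bb["CB"], asn_bb["CA"], 1.23, 120.4, -30.0)
    nd2_n = place_atom(cg_n, asn_bb["CB"], asn_bb["CA"], 1.33, 116.4, 150.0)
    asn_atoms = {**asn_bb, "CG": cg_n, "OD1": od1_n, "ND2": nd2_n}
    # put the amide *oxygen* 3.2 Å from the carboxylate oxygen: unflipped is
    # repulsive O···O, flipped donates N-H···O
    shift = (od1 + 3.2 * direction) - od1_n
    asn_atoms = {k: v + shift for k, v in asn_atoms.items()}
    lines_a, serial = _pdb_lines(asp, chain="A")
    lines_b, _ = _pdb_lines([("ASN", 1, asn_atoms)], chain="B",
                            start_serial=serial)
    st = read_structure("\n".join(lines_a + ["TER"] + lines_b + ["END"]) + "\n",
                        params=tables)
    st.residues[1].label = "ASN"

    rots = enumerate_rotamers(st, ("A", 1, ""), library=[])
    state = [s for s in build_protonation_states(rots[0], "ASP")
             if s.state == "ASP"][0]
    opt = optimize_hbond_network(st, 0, state)
    assert 1 in opt.network_flips
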