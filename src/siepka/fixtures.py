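"""Synthetic test structures with controlled electrostatic and burial
properties.

Each fixture kind produces deterministic PDB text plus a manifest of
analytically known properties (net charge, closed-form reaction-field
energies, expected cluster membership, expected burial regime). Pseudo-atoms
are emitted as HETATM records with a sidecar charge/radius table so the main
pipeline ingests them unmodified.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import born_energy
from .geometry import place_atom

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_KINDS", "FixtureError"]

FIXTURE_KINDS = ("born_sphere", "free_residue", "helix_with_target",
                 "charge_probe", "coupled_pair", "burial_cage")


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    kind: str
    q: float = 1.0
    a: float = 2.0                 # Born cavity radius, Å
    restype: str = "HIS"
    n_res: int = 9
    target_pos: int = 5            # 1-based residue index of the target
    distance: float = 4.0          # probe-to-ring-centroid distance, Å
    gap: float = 5.0               # coupled-pair side-chain gap, Å
    shell_radius: float = 6.0
    n_shell: int = 160
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise FixtureError(f"unknown fixture kind {self.kind!r}; "
                               f"choose from {FIXTURE_KINDS}")
        for attr in ("a", "distance", "gap", "shell_radius"):
            if getattr(self, attr) <= 0:
                raise FixtureError(f"{attr} must be positive")


@dataclass
class Fixture:
    pdb_text: str
    manifest: dict
    extra_params: pd.DataFrame | None = None
    het_whitelist: tuple = ()


# ---------------------------------------------------------------------------
# peptide construction (ideal internal coordinates)

_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _build_backbone(n_res, phi=_PHI, psi=_PSI):
    """α-helical backbone N/CA/C/O/CB positions from ideal geometry."""
    res = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.458, 0.0, 0.0])
    dummy = np.array([0.0, -1.0, 0.0])
    c = place_atom(ca, n, dummy, 1.525, 111.2, 60.0)
    res.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        prev = res[-1]
        n_next = place_atom(prev["C"], prev["CA"], prev["N"], 1.329, 116.2, psi)
        ca_next = place_atom(n_next, prev["C"], prev["CA"], 1.458, 121.7, _OMEGA)
        c_next = place_atom(ca_next, n_next, prev["C"], 1.525, 111.2, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for r in res:
        r["O"] = place_atom(r["C"], r["CA"], r["N"], 1.231, 120.8, psi + 180.0)
        r["CB"] = place_atom(r["CA"], r["N"], r["C"], 1.530, 110.5, 122.5)
    return res


def _attach_his(r, chi1=-177.0, chi2=165.0):
    cg = place_atom(r["CB"], r["CA"], r["N"], 1.50, 113.8, chi1)
    nd1 = place_atom(cg, r["CB"], r["CA"], 1.38, 122.8, chi2)
    cd2 = place_atom(cg, r["CB"], r["CA"], 1.36, 131.2, chi2 + 180.0)
    ce1 = place_atom(nd1, cg, r["CB"], 1.32, 109.0, 180.0)
    ne2 = place_atom(ce1, nd1, cg, 1.32, 108.5, 0.0)
    return {"CG": cg, "ND1": nd1, "CD2": cd2, "CE1": ce1, "NE2": ne2}


def _attach_asp(r, chi1=-177.0, chi2=10.0):
    cg = place_atom(r["CB"], r["CA"], r["N"], 1.52, 112.6, chi1)
    od1 = place_atom(cg, r["CB"], r["CA"], 1.25, 118.4, chi2)
    od2 = place_atom(cg, r["CB"], r["CA"], 1.25, 118.4, chi2 + 180.0)
    return {"CG": cg, "OD1": od1, "OD2": od2}


_ELEMENT = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H"}


def _atom_element(name: str) -> str:
    return _ELEMENT.get(name[0], "C")


def _pdb_lines(residues, chain="A", start_serial=1, hetero=False):
    """residues: list of (resname, resnum, {atom name -> xyz})."""
    lines = []
    serial = start_serial
    rec = "HETATM" if hetero else "ATOM  "
    for resname, resnum, atoms in residues:
        for name, xyz in atoms.items():
            nm = name if len(name) == 4 else f" {name:<3s}"
            el = _atom_element(name)
            lines.append(
                f"{rec}{serial:5d} {nm} {resname:<3s} {chain:1s}{resnum:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2s}")
            serial += 1
    return lines, serial


def _peptide(restype, n_res, target_pos, chi1=-177.0, chi2=165.0):
    bb = _build_backbone(n_res)
    residues = []
    for i, r in enumerate(bb, start=1):
        atoms = {k: r[k] for k in ("N", "CA", "C", "O", "CB")}
        if i == target_pos:
            if restype == "HIS":
                atoms.update(_attach_his(r, chi1, chi2))
                residues.append(("HIS", i, atoms))
            else:
                atoms.update(_attach_asp(r, chi1, chi2))
                residues.append(("ASP", i, atoms))
        else:
            residues.append(("ALA", i, atoms))
    return residues


def _ring_centroid(residues, target_pos):
    atoms = dict(residues[target_pos - 1][2])
    names = [n for n in ("CG", "ND1", "CD2", "CE1", "NE2") if n in atoms]
    if not names:
        names = [n for n in ("CG", "OD1", "OD2") if n in atoms]
    return np.mean([atoms[n] for n in names], axis=0), atoms


# ---------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build one synthetic structure and its expected-property manifest."""
    rng = np.random.default_rng(spec.seed)
    _ = rng  # geometry is fully deterministic; the seed is kept for the API
    builder = {
        "born_sphere": _make_born, "free_residue": _make_free,
        "helix_with_target": _make_helix, "charge_probe": _make_probe,
        "coupled_pair": _make_pair, "burial_cage": _make_cage,
    }[spec.kind]
    return builder(spec)


def _make_born(spec) -> Fixture:
    # vdW radius chosen so the pipeline's scaled radius equals the cavity
    radius = spec.a / 1.1
    lines, _ = _pdb_lines([("PSA", 1, {"Q1": np.zeros(3)})], hetero=True)
    pdb = "\n".join(lines + ["END"]) + "\n"
    table = pd.DataFrame([{"label": "PSA", "atom": "Q1", "element": "C",
                           "charge": spec.q, "radius": radius}])
    manifest = {
        "kind": "born_sphere", "net_charge": spec.q,
        "cavity_radius": spec.a,
        "reaction_field_kcal": born_energy(spec.q, spec.a, 2.25, 78.5),
        "ses_area": 4.0 * np.pi * spec.a ** 2,
    }
    return Fixture(pdb, manifest, table, het_whitelist=("PSA",))


def _make_free(spec) -> Fixture:
    residues = _peptide(spec.restype, 1, 1)
    lines, _ = _pdb_lines(residues)
    pdb = "\n".join(lines + ["END"]) + "\n"
    manifest = {"kind": "free_residue", "restype": spec.restype,
                "target": ("A", 1, ""), "exposed": True,
                "min_sesa": 20.0}
    return Fixture(pdb, manifest)


def _make_helix(spec) -> Fixture:
    residues = _peptide(spec.restype, spec.n_res, spec.target_pos)
    lines, _ = _pdb_lines(residues)
    pdb = "\n".join(lines + ["END"]) + "\n"
    manifest = {"kind": "helix_with_target", "restype": spec.restype,
                "target": ("A", spec.target_pos, ""), "exposed": True,
                "min_sesa": 20.0, "n_res": spec.n_res}
    return Fixture(pdb, manifest)


def _make_probe(spec) -> Fixture:
    residues = _peptide(spec.restype, spec.n_res, spec.target_pos)
    centroid, atoms = _ring_centroid(residues, spec.target_pos)
    anchor = residues[spec.target_pos - 1][2]["CB"]
    direction = centroid - anchor
    direction /= np.linalg.norm(direction)
    probe_pos = centroid + spec.distance * direction
    lines, serial = _pdb_lines(residues)
    het, _ = _pdb_lines([("PRB", spec.n_res + 1, {"Q1": probe_pos})],
                        chain="B", start_serial=serial, hetero=True)
    pdb = "\n".join(lines + het + ["END"]) + "\n"
    table = pd.DataFrame([{"label": "PRB", "atom": "Q1", "element": "C",
                           "charge": spec.q, "radius": 1.5}])
    manifest = {"kind": "charge_probe", "restype": spec.restype,
                "target": ("A", spec.target_pos, ""),
                "probe_charge": spec.q, "probe_distance": spec.distance}
    return Fixture(pdb, manifest, table, het_whitelist=("PRB",))


def _make_pair(spec) -> Fixture:
    """Two His tripeptides on parallel rigid scaffolds, side chains facing,
    nearest side-chain heavy atoms separated by ``spec.gap``."""
    pep_a = _peptide("HIS", 3, 2)
    pep_b = _peptide("HIS", 3, 2)
    sc_names = ("CG", "ND1", "CD2", "CE1", "NE2", "CB")
    a_sc = np.array([pep_a[1][2][n] for n in sc_names])
    # mirror the second peptide so the rings face each other, then slide
    # along x until the minimum side-chain distance equals the gap
    flip = np.diag([-1.0, 1.0, 1.0])
    for _, _, atoms in pep_b:
        for n in atoms:
            atoms[n] = flip @ atoms[n]
    b_sc = np.array([pep_b[1][2][n] for n in sc_names])

    def min_gap(shift):
        d = np.linalg.norm(a_sc[:, None, :]
                           - (b_sc + np.array([shift, 0, 0]))[None, :, :],
                           axis=-1)
        return d.min()

    # min_gap(shift) is V-shaped in the slide distance; walk past the
    # minimum, then bisect on the monotonically increasing branch
    shifts = np.arange(-20.0, 120.0, 0.5)
    gaps = np.array([min_gap(s) for s in shifts])
    start = float(shifts[int(np.argmin(gaps))])
    lo, hi = start, 150.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_gap(mid) < spec.gap:
            lo = mid
        else:
            hi = mid
    shift = 0.5 * (lo + hi)
    for _, _, atoms in pep_b:
        for n in atoms:
            atoms[n] = atoms[n] + np.array([shift, 0.0, 0.0])

    lines_a, serial = _pdb_lines(pep_a, chain="A")
    lines_b, _ = _pdb_lines(pep_b, chain="B", start_serial=serial)
    pdb = "\n".join(lines_a + ["TER"] + lines_b + ["END"]) + "\n"
    manifest = {"kind": "coupled_pair", "gap": spec.gap,
                "targets": [("A", 2, ""), ("B", 2, "")],
                "expect_single_cluster": spec.gap < 6.0}
    return Fixture(pdb, manifest)


def _make_cage(spec) -> Fixture:
    residues = _peptide("HIS", 1, 1)
    centroid, _ = _ring_centroid(residues, 1)
    # Fibonacci sphere of neutral shell atoms sealing the probe out
    n = spec.n_shell
    idx = np.arange(n) + 0.5
    phi_ang = np.arccos(1 - 2 * idx / n)
    theta = np.pi * (1 + 5 ** 0.5) * idx
    pts = centroid + spec.shell_radius * np.stack(
        [np.cos(theta) * np.sin(phi_ang), np.sin(theta) * np.sin(phi_ang),
         np.cos(phi_ang)], axis=1)
    shell = [("SHL", 100 + i, {"Q1": p}) for i, p in enumerate(pts)]
    lines, serial = _pdb_lines(residues)
    het, _ = _pdb_lines(shell, chain="S", start_serial=serial, hetero=True)
    pdb = "\n".join(lines + het + ["END"]) + "\n"
    table = pd.DataFrame([{"label": "SHL", "atom": "Q1", "element": "C",
                           "charge": 0.0, "radius": 1.8}])
    manifest = {"kind": "burial_cage", "target": ("A", 1, ""),
                "shell_radius": spec.shell_radius, "expect_sesa": 0.0}
    return Fixture(pdb, manifest, table, het_whitelist=("SHL",))
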