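"""Side-chain conformational sampling for the titratable residue.

Only the target side chain moves: each canonical rotamer from the bundled
backbone-independent library is placed by setting its χ angles, relaxed by a
±5° per-χ constrained golden-section minimization of a soft-core clash
objective, filtered for hard clashes and isostericity, and kept alongside
the native conformation. For every surviving rotamer the full set of
protonation micro-states is built (His: HID/HIE/HIP and their 180° ring
flips, 6 states; Asp: ionized ASP plus neutral ASH with syn/anti carboxyl
proton and their flips, 5 states — the flip of the ionized form is
geometrically degenerate and collapsed). Finally the local hydrogen-bond
network (rotatable polar hydrogens, Asn/Gln amide flips) is optimized on a
discrete grid against a screened-Coulomb objective.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .electrostatics import COULOMB_K
from .geometry import dihedral, rotate_points_about_bond
from .structure import ParameterizedStructure, materialize

log = logging.getLogger(__name__)

__all__ = ["RotamerVariant", "ProtonationVariant", "enumerate_rotamers",
           "build_protonation_states", "optimize_hbond_network",
           "HIS_STATES", "ASP_STATES"]

CHI_ATOMS = {
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
}
#: atoms rotated by each χ (beyond the rotation axis)
CHI_MOVES = {
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2"), ("ND1", "CD2", "CE1", "NE2")],
    "ASP": [("CG", "OD1", "OD2"), ("OD1", "OD2")],
}

#: state label, heavy-flip flag, protonated flag, extra H-torsion overrides
HIS_STATES = [
    ("HID", False, False, {}), ("HIE", False, False, {}),
    ("HIP", False, True, {}),
    ("HID-flip", True, False, {}), ("HIE-flip", True, False, {}),
    ("HIP-flip", True, True, {}),
]
ASP_STATES = [
    ("ASP", False, False, {}),
    ("ASH-syn", False, True, {"HD2": 0.0}),
    ("ASH-anti", False, True, {"HD2": 180.0}),
    ("ASH-syn-flip", True, True, {"HD2": 0.0}),
    ("ASH-anti-flip", True, True, {"HD2": 180.0}),
]


@dataclass
class RotamerVariant:
    chi: tuple
    coords: dict                  # side-chain heavy atom name -> xyz
    origin: str                   # "native" | "library"


@dataclass
class ProtonationVariant:
    rotamer: RotamerVariant
    state: str                    # e.g. "HIP-flip", "ASH-anti"
    label: str                    # parameter-table label (HIP, ASH, ...)
    flip: bool
    protonated: bool
    h_overrides: dict = field(default_factory=dict)   # H name -> torsion
    network_torsions: dict = field(default_factory=dict)  # (ridx, H) -> deg
    network_flips: set = field(default_factory=set)       # residue indices
    energy: float | None = None


# ---------------------------------------------------------------------------
# rotamers

def _environment(structure: ParameterizedStructure, model: int, ridx: int):
    """Heavy atoms of all other usable residues (coords, radii)."""
    ps = structure.params
    xyz = structure.models[model]
    coords, radii = [], []
    for j, res in enumerate(structure.residues):
        if j == ridx or not res.usable:
            continue
        label = res.label or res.name
        for name, gidx in res.atoms.items():
            try:
                _, r, elem = ps.lookup(label, name)
            except Exception:
                r = 1.7
            coords.append(xyz[gidx])
            radii.append(r)
    return (np.asarray(coords).reshape(-1, 3), np.asarray(radii))


def _clash_score(sc_coords: np.ndarray, sc_radii: np.ndarray,
                 env_coords: np.ndarray, env_radii: np.ndarray,
                 factor: float = 0.8) -> float:
    if len(env_coords) == 0 or len(sc_coords) == 0:
        return 0.0
    d = np.linalg.norm(sc_coords[:, None, :] - env_coords[None, :, :], axis=-1)
    lim = factor * (sc_radii[:, None] + env_radii[None, :])
    o = np.clip(lim - d, 0.0, None)
    return float((o ** 2).sum())


def _has_hard_clash(sc_coords, sc_radii, env_coords, env_radii,
                    factor: float = 0.7) -> bool:
    if len(env_coords) == 0:
        return False
    d = np.linalg.norm(sc_coords[:, None, :] - env_coords[None, :, :], axis=-1)
    return bool(np.any(d < factor * (sc_radii[:, None] + env_radii[None, :])))


def _set_chi(restype, coords, backbone, chi_index, target):
    """Rotate the side chain so that χ_(chi_index) equals ``target`` degrees."""
    a1, a2, a3, a4 = CHI_ATOMS[restype][chi_index]
    ref = {**backbone, **coords}
    cur = dihedral(ref[a1], ref[a2], ref[a3], ref[a4])
    movers = [m for m in CHI_MOVES[restype][chi_index] if m in coords]
    pts = np.array([coords[m] for m in movers])
    # rotation about the a2->a3 axis; the sign matches the dihedral convention
    newpts = rotate_points_about_bond(pts, np.asarray(ref[a2]),
                                      np.asarray(ref[a3]), cur - target)
    out = dict(coords)
    for m, p in zip(movers, newpts):
        out[m] = p
    return out


def _get_chis(restype, coords, backbone):
    ref = {**backbone, **coords}
    return tuple(dihedral(ref[a], ref[b], ref[c], ref[d])
                 for a, b, c, d in CHI_ATOMS[restype])


def _golden_minimize(fun, lo, hi, tol=0.2):
    """Deterministic golden-section minimization on [lo, hi]."""
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = fun(c), fun(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def enumerate_rotamers(structure: ParameterizedStructure, residue_key,
                       model: int = 0, library=None) -> list:
    """Native plus surviving library rotamers of a His/Asp target.

    Library rotamers are relaxed within ±5° per χ (two sequential
    golden-section sweeps over the χ angles on the soft clash objective),
    removed if any heavy atom sits closer than 0.7 × (sum of vdW radii) to
    another residue's heavy atom, and retained only if isosteric with the
    native side chain (every heavy atom within 1.5 Å of some native heavy
    atom) or clash-free at a stricter 0.8 factor.
    """
    res = structure.residue_by_key(residue_key)
    ridx = structure.residues.index(res)
    restype = res.restype
    if restype not in CHI_ATOMS:
        raise ValueError(f"residue {residue_key} is not His/Asp")
    ps = structure.params
    xyz = structure.models[model]
    backbone = {n: xyz[res.atoms[n]] for n in ("N", "CA", "C") if n in res.atoms}
    native = structure.sidechain_coords(model, ridx)
    # clash/isostericity are judged on the atoms that actually move (CG and
    # beyond); CB is part of the fixed backbone stem and its covalent
    # contacts with adjacent residues are not clashes
    sc_names = [n for n in native if n != "CB"]
    label = {"HIS": "HIE", "ASP": "ASP"}[restype]
    sc_radii = np.array([ps.lookup(label, n)[1] for n in sc_names])
    env_coords, env_radii = _environment(structure, model, ridx)
    native_chis = _get_chis(restype, native, backbone)

    variants = [RotamerVariant(chi=native_chis, coords=dict(native),
                               origin="native")]
    library = library if library is not None else ps.rotamers.get(restype, [])
    native_pts = np.array([native[n] for n in sc_names])

    for chis in library:
        if max(abs((np.array(chis) - native_chis + 180) % 360 - 180)) < 3.0:
            continue  # duplicate of the native rotamer
        coords = dict(native)
        for ci, target in enumerate(chis):
            coords = _set_chi(restype, coords, backbone, ci, target)

        # ±5° constrained per-χ relaxation, two sweeps; a clash-free rotamer
        # stays at its canonical χ values (the objective is already zero)
        for _ in range(2):
            for ci, center in enumerate(chis):
                def obj(chi_val, _ci=ci):
                    c2 = _set_chi(restype, coords, backbone, _ci, chi_val)
                    pts = np.array([c2[n] for n in sc_names])
                    return _clash_score(pts, sc_radii, env_coords, env_radii)
                if obj(center) <= 0.0:
                    continue
                best = _golden_minimize(obj, center - 5.0, center + 5.0)
                if obj(best) < obj(center):
                    coords = _set_chi(restype, coords, backbone, ci, best)

        pts = np.array([coords[n] for n in sc_names])
        if _has_hard_clash(pts, sc_radii, env_coords, env_radii, 0.7):
            continue
        envelope = np.all(
            np.min(np.linalg.norm(pts[:, None, :] - native_pts[None, :, :],
                                  axis=-1), axis=1) <= 1.5)
        strict_ok = not _has_hard_clash(pts, sc_radii, env_coords, env_radii, 0.8)
        if not (envelope or strict_ok):
            continue
        variants.append(RotamerVariant(chi=_get_chis(restype, coords, backbone),
                                       coords=coords, origin="library"))
    if len(variants) == 1 and library:
        log.warning("no library rotamer survived for %s; native only",
                    residue_key)
    return variants


# ---------------------------------------------------------------------------
# protonation states

def build_protonation_states(variant: RotamerVariant, restype: str) -> list:
    """All protonation micro-states of one rotamer (6 for His, 5 for Asp)."""
    table = {"HIS": HIS_STATES, "ASP": ASP_STATES}[restype]
    out = []
    for state, flip, protonated, hov in table:
        label = state.split("-")[0]
        out.append(ProtonationVariant(rotamer=variant, state=state,
                                      label=label, flip=flip,
                                      protonated=protonated,
                                      h_overrides=dict(hov)))
    return out


# ---------------------------------------------------------------------------
# hydrogen-bond network optimization

def _candidate_dofs(structure, system, target_ridx, radius):
    """Rotatable-proton and flip degrees of freedom near the target."""
    ps = structure.params
    target_atoms = np.nonzero((system.atom_res == target_ridx)
                              & system.is_sidechain)[0]
    tpos = system.coords[target_atoms]
    rot_dofs, flip_dofs = [], []
    for ridx, res in enumerate(structure.residues):
        if not res.usable or res.is_het:
            continue
        label = res.label if ridx != target_ridx else None
        if ridx == target_ridx:
            continue
        near = False
        for i in np.nonzero(system.atom_res == ridx)[0]:
            if len(tpos) and np.min(np.linalg.norm(tpos - system.coords[i],
                                                   axis=1)) <= radius:
                near = True
                break
        if not near:
            continue
        rules = ps.hydrogen_rules(label)
        if any(r.kind == "rot3" for r in rules):
            rot_dofs.append((ridx, "NZ-group", "rot3"))
        for r in rules:
            if r.kind == "rot":
                rot_dofs.append((ridx, r.hname, "rot"))
        if res.name in ("ASN", "GLN"):
            flip_dofs.append(ridx)
    return rot_dofs, flip_dofs


def _moved_energy(system, moved_idx, moved_pos) -> float:
    """Screened-Coulomb objective restricted to pairs touching moved atoms."""
    coords = system.coords.copy()
    coords[moved_idx] = moved_pos
    q = system.charges
    scale = {}
    for a, b in system.excl_pairs:
        scale[(min(a, b), max(a, b))] = 0.0
    for a, b in system.pair14:
        scale[(min(a, b), max(a, b))] = 5.0 / 6.0
    moved = np.asarray(moved_idx)
    others = np.setdiff1d(np.arange(len(q)), moved)
    e = 0.0
    d = np.linalg.norm(coords[moved][:, None, :] - coords[others][None, :, :],
                       axis=-1)
    d = np.maximum(d, 0.5)
    qq = np.outer(q[moved], q[others])
    s = np.ones_like(qq)
    for mi, m in enumerate(moved):
        for oi, o in enumerate(others):
            key = (min(m, o), max(m, o))
            if key in scale:
                s[mi, oi] = scale[key]
    e += float((qq * s / d).sum())
    if len(moved) > 1:
        dm = np.linalg.norm(coords[moved][:, None, :] - coords[moved][None, :, :],
                            axis=-1)
        iu = np.triu_indices(len(moved), k=1)
        dmm = np.maximum(dm[iu], 0.5)
        qmm = np.outer(q[moved], q[moved])[iu]
        smm = np.array([scale.get((min(moved[i], moved[j]),
                                   max(moved[i], moved[j])), 1.0)
                        for i, j in zip(*iu)])
        e += float((qmm * smm / dmm).sum())
    return COULOMB_K / 2.25 * e


def optimize_hbond_network(structure: ParameterizedStructure,
                           target_ridx: int, state: ProtonationVariant,
                           model: int = 0, radius: float = 6.0,
                           torsion_step: float = 30.0) -> ProtonationVariant:
    """Choose polar-H torsions and Asn/Gln flips minimizing the local
    screened-Coulomb objective on a discrete grid.

    With at most three degrees of freedom the grid product is searched
    exhaustively; beyond that, sequential sweeps (two passes, greedy per
    degree of freedom) are used. Deterministic: fixed candidate order,
    first minimum wins. The input configuration is always a candidate, so
    the objective never increases.
    """
    overrides = {target_ridx: (state.label, dict(state.rotamer.coords))}
    torsions = {(target_ridx, h): t for h, t in state.h_overrides.items()}
    flips = {target_ridx} if state.flip else set()

    def build(extra_torsions, extra_flips):
        return materialize(structure, model, overrides=overrides,
                           h_torsions={**torsions, **extra_torsions},
                           flips=flips | extra_flips)

    base = build({}, set())
    rot_dofs, flip_dofs = _candidate_dofs(structure, base, target_ridx, radius)
    if not rot_dofs and not flip_dofs:
        return state

    grid = [float(t) for t in np.arange(0.0, 360.0, torsion_step)]
    choices = []
    for ridx, hname, kind in rot_dofs:
        vals = [float(t) for t in np.arange(0.0, 120.0, torsion_step)] \
            if kind == "rot3" else grid
        choices.append([("torsion", ridx, hname, v) for v in vals])
    for ridx in flip_dofs:
        choices.append([("flip", ridx, None, False), ("flip", ridx, None, True)])

    def apply(config):
        et, ef = {}, set()
        for kind, ridx, hname, val in config:
            if kind == "torsion":
                et[(ridx, hname)] = val
            elif val:
                ef.add(ridx)
        return et, ef

    def objective(config):
        et, ef = apply(config)
        sys_ = build(et, ef)
        # all atoms of residues carrying a degree of freedom are "moved"
        dof_res = {c[1] for c in config}
        moved = np.nonzero(np.isin(sys_.atom_res, list(dof_res)))[0]
        return _moved_energy(sys_, moved, sys_.coords[moved])

    if len(choices) <= 3:
        best_cfg, best_e = None, np.inf
        from itertools import product
        for cfg in product(*choices):
            e = objective(cfg)
            if e < best_e - 1e-12:
                best_cfg, best_e = cfg, e
    else:
        cfg = [c[0] for c in choices]
        for _ in range(2):
            for i, opts in enumerate(choices):
                best_i, best_e = cfg[i], np.inf
                for opt in opts:
                    trial = list(cfg)
                    trial[i] = opt
                    e = objective(trial)
                    if e < best_e - 1e-12:
                        best_i, best_e = opt, e
                cfg[i] = best_i
        best_cfg = tuple(cfg)

    et, ef = apply(best_cfg)
    out = ProtonationVariant(rotamer=state.rotamer, state=state.state,
                             label=state.label, flip=state.flip,
                             protonated=state.protonated,
                             h_overrides=dict(state.h_overrides),
                             network_torsions=et, network_flips=ef)
    return out
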