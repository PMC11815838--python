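"""Structure reading, preparation and parameterization.

The pipeline is: parse PDB text (gemmi) -> strip waters/hetero groups ->
resolve alternate locations -> assign per-residue protonation labels and
force-field parameters -> materialize one concrete :class:`System` per model
(heavy atoms from the file, polar hydrogens rebuilt from ideal geometry)
for the energy machinery.

Residue identity follows the author convention: (chain id, residue number,
insertion code), 1-based numbers as printed in the PDB file.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import place_atom, sp2_bisector_h
from .params import ParameterSet, ParameterError, BACKGROUND_LABEL

log = logging.getLogger(__name__)

__all__ = [
    "Residue", "ParameterizedStructure", "System", "CoupledCluster",
    "FormatError", "LookupError_", "read_structure", "assign_parameters",
    "assign_background_protonation", "find_coupled_clusters", "materialize",
    "write_pdb",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
BACKBONE = ("N", "CA", "C", "O")
#: polar side-chain atoms per titratable residue type
POLAR_SIDECHAIN = {"HIS": ("ND1", "NE2"), "ASP": ("OD1", "OD2")}


class FormatError(ValueError):
    """Unparseable or structurally unusable PDB input."""


class LookupError_(KeyError):
    """Requested chain or residue absent from the structure."""


@dataclass
class Residue:
    chain: str
    seqid: int
    icode: str
    name: str                     # residue name as read (HIS, ASP, ...)
    label: str | None = None      # assigned protonation label (HIE, ASP, ...)
    atoms: dict = field(default_factory=dict)   # atom name -> global index
    is_het: bool = False
    usable: bool = True

    @property
    def key(self):
        return (self.chain, self.seqid, self.icode)

    @property
    def restype(self) -> str:
        if self.name in ("HIS", "HID", "HIE", "HIP"):
            return "HIS"
        if self.name in ("ASP", "ASH"):
            return "ASP"
        return self.name

    def sidechain_names(self):
        return [n for n in self.atoms if n not in BACKBONE and n != "OXT"]


@dataclass
class ParameterizedStructure:
    """Prepared structure: shared atom metadata + one coordinate set per model."""

    residues: list
    atom_names: list
    atom_elements: list
    atom_res: np.ndarray          # residue index per atom
    models: list                  # list of (N, 3) float arrays
    params: ParameterSet | None = None

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residue_by_key(self, key) -> Residue:
        chain, seqid, icode = key
        for r in self.residues:
            if r.chain == chain and r.seqid == seqid and r.icode == icode:
                return r
        raise LookupError_(f"residue {key} not in structure")

    def residue_index(self, key) -> int:
        return self.residues.index(self.residue_by_key(key))

    def sidechain_coords(self, model: int, ridx: int) -> dict:
        res = self.residues[ridx]
        xyz = self.models[model]
        return {n: xyz[i].copy() for n, i in res.atoms.items()
                if n in res.sidechain_names()}


@dataclass
class CoupledCluster:
    members: list                 # residue keys, all targets
    pair_distances: dict          # (key_a, key_b) -> Å


# ---------------------------------------------------------------------------
# reading & preparation

def read_structure(pdb_text: str, chains=None, het_whitelist=(),
                   params: ParameterSet | None = None) -> ParameterizedStructure:
    """Parse PDB text into a prepared :class:`ParameterizedStructure`.

    Waters are always removed; HETATM groups are removed unless named in
    ``het_whitelist`` (in which case ``params`` must carry a charge/radius
    table for them).  All MODEL records are kept as separate models.
    Alternate locations are resolved to the highest occupancy (ties broken
    by altloc letter order). Hydrogens in the file are dropped and rebuilt
    deterministically later.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as e:
        raise FormatError(f"cannot parse PDB text: {e}") from None
    if len(st) == 0:
        raise FormatError("no models in PDB input")
    st.setup_entities()

    if chains is not None:
        present = {ch.name for model in st for ch in model}
        for c in chains:
            if c not in present:
                raise LookupError_(f"requested chain {c!r} not present "
                                   f"(available: {sorted(present)})")

    # collect residues from the first model; require identical layout in all
    def wanted(ch_name, res):
        if chains is not None and ch_name not in chains:
            return False
        if res.name in WATER_NAMES:
            return False
        het = res.het_flag == "H"
        if het and res.name not in het_whitelist:
            return False
        return True

    def best_altloc(res):
        """atom name -> gemmi atom, keeping highest occupancy."""
        chosen = {}
        for at in res:
            if at.element == gemmi.Element("H") or at.element == gemmi.Element("D"):
                continue
            prev = chosen.get(at.name)
            if prev is None:
                chosen[at.name] = at
            else:
                if (at.occ, -ord(at.altloc or "~")) > (prev.occ, -ord(prev.altloc or "~")):
                    chosen[at.name] = at
        return chosen

    residues: list[Residue] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    atom_res: list[int] = []
    layout = []  # (chain, seqid, icode, name, [atom names]) for model checks

    model0 = st[0]
    for ch in model0:
        for res in ch:
            if not wanted(ch.name, res):
                continue
            chosen = best_altloc(res)
            chosen.pop("OXT", None)  # neutral blocked-terminus convention
            r = Residue(chain=ch.name, seqid=res.seqid.num,
                        icode=res.seqid.icode.strip() or "",
                        name=res.name, is_het=res.het_flag == "H")
            for name, at in chosen.items():
                r.atoms[name] = len(atom_names)
                atom_names.append(name)
                atom_elements.append(at.element.name)
                atom_res.append(len(residues))
            if not r.is_het and not all(b in r.atoms for b in BACKBONE):
                r.usable = False
                log.warning("residue %s %s%d%s is missing backbone atoms; "
                            "flagged unusable", r.name, r.chain, r.seqid, r.icode)
            residues.append(r)
            layout.append((ch.name, res.seqid.num, res.seqid.icode, res.name,
                           list(chosen)))
    if not residues:
        raise FormatError("no residues left after preparation")

    models = []
    for model in st:
        coords = np.zeros((len(atom_names), 3))
        k = 0
        for ch in model:
            for res in ch:
                if not wanted(ch.name, res):
                    continue
                chosen = best_altloc(res)
                chosen.pop("OXT", None)
                expect = layout[ [l[:3] for l in layout].index(
                    (ch.name, res.seqid.num, res.seqid.icode)) ][4] \
                    if len(st) > 1 else list(chosen)
                if set(chosen) != set(expect):
                    raise FormatError(
                        f"model {model.name} has a different atom set for "
                        f"{res.name} {ch.name}{res.seqid.num}")
                for name in expect:
                    at = chosen[name]
                    coords[k] = [at.pos.x, at.pos.y, at.pos.z]
                    k += 1
        if k != len(atom_names):
            raise FormatError("models differ in atom count")
        models.append(coords)

    struct = ParameterizedStructure(residues=residues, atom_names=atom_names,
                                    atom_elements=atom_elements,
                                    atom_res=np.asarray(atom_res),
                                    models=models)
    if params is not None:
        assign_parameters(struct, params)
    return struct


def assign_parameters(structure: ParameterizedStructure,
                      tables: ParameterSet) -> ParameterizedStructure:
    """Attach parameter tables and assign default protonation labels.

    Every residue gets a label with an entry in the tables; unknown residues
    raise :class:`ParameterError` naming the residue.
    """
    for r in structure.residues:
        if r.label is None:
            if r.is_het:
                r.label = r.name
            else:
                try:
                    r.label = BACKGROUND_LABEL[r.name]
                except KeyError:
                    raise ParameterError(
                        f"no parameters for residue {r.name} "
                        f"{r.chain}{r.seqid}{r.icode}") from None
        # validate that every heavy atom resolves
        for name in r.atoms:
            if r.is_het:
                tables.lookup(r.label, name)
            elif name in _template_heavy(tables, r.label) or name in BACKBONE:
                tables.lookup(r.label, name)
    structure.params = tables
    return structure


def _template_heavy(tables: ParameterSet, label: str) -> set:
    return {a for a in tables.atoms_of(label)
            if tables.charges[(label, a)][2] != "H"}


# ---------------------------------------------------------------------------
# background protonation

def assign_background_protonation(structure: ParameterizedStructure,
                                  targets: list) -> ParameterizedStructure:
    """Assign predominant pH-7.4 ionization states to non-target residues.

    Asp/Glu are ionized, Lys/Arg protonated; non-target histidines outside
    the targets' coupled clusters are neutral with the tautomer (HID/HIE)
    chosen by a local electrostatic hydrogen-bond score. Target residues are
    left for the engine to enumerate.
    """
    target_keys = set(targets)
    for r in structure.residues:
        if r.is_het or r.key in target_keys:
            continue
        if r.restype == "HIS":
            r.label = _best_his_tautomer(structure, r)
        else:
            r.label = BACKGROUND_LABEL.get(r.name, r.name)
    return structure


def _best_his_tautomer(structure: ParameterizedStructure, res: Residue) -> str:
    """Pick HID vs HIE for a background His by local H-bond electrostatics."""
    best, best_e = "HIE", np.inf
    for label in ("HID", "HIE"):
        e = 0.0
        for m in range(structure.n_models):
            e += _local_tautomer_energy(structure, res, label, m)
        if e < best_e:
            best, best_e = label, e
    return best


def _local_tautomer_energy(structure, res, label, model) -> float:
    """Coulomb score of one His tautomer's ring polar atoms vs neighbours."""
    ps = structure.params
    if ps is None:
        raise ParameterError("parameters must be assigned first")
    xyz = structure.models[model]
    ring = {}
    for name in ("CG", "ND1", "CD2", "CE1", "NE2"):
        if name in res.atoms:
            ring[name] = xyz[res.atoms[name]]
    if len(ring) < 5:
        return 0.0
    atoms = dict(ring)
    if label == "HID":
        atoms["HD1"] = sp2_bisector_h(ring["ND1"], ring["CG"], ring["CE1"], 1.01)
    else:
        atoms["HE2"] = sp2_bisector_h(ring["NE2"], ring["CE1"], ring["CD2"], 1.01)
    centroid = np.mean(list(ring.values()), axis=0)
    # neighbours within 6 Å of the ring centroid, using current labels
    e = 0.0
    for other in structure.residues:
        if other is res or not other.usable:
            continue
        lab = other.label or BACKGROUND_LABEL.get(other.name)
        if lab is None:
            continue
        for name, idx in other.atoms.items():
            p = xyz[idx]
            d0 = np.linalg.norm(p - centroid)
            if d0 > 6.0:
                continue
            try:
                q_other = ps.lookup(lab, name)[0]
            except ParameterError:
                continue
            for aname, apos in atoms.items():
                q_self = ps.lookup(label, aname)[0]
                d = np.linalg.norm(p - apos)
                if d > 0.5:
                    e += q_self * q_other / d
    return e


# ---------------------------------------------------------------------------
# coupled clusters

def find_coupled_clusters(structure: ParameterizedStructure, targets: list,
                          cutoff: float = 6.0) -> list:
    """Maximal connected components of targets under the side-chain
    heavy-atom distance relation (any-model minimum distance < cutoff)."""
    keys = list(targets)
    n = len(keys)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dists = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = _min_sidechain_distance(structure, keys[i], keys[j])
            dists[(keys[i], keys[j])] = d
            if d < cutoff:
                parent[find(i)] = find(j)

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(keys[i])
    clusters = []
    for members in groups.values():
        pd_ = {k: v for k, v in dists.items()
               if k[0] in members and k[1] in members}
        clusters.append(CoupledCluster(members=sorted(members), pair_distances=pd_))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def _min_sidechain_distance(structure, key_a, key_b) -> float:
    ra = structure.residue_by_key(key_a)
    rb = structure.residue_by_key(key_b)
    ia = [ra.atoms[n] for n in ra.sidechain_names()]
    ib = [rb.atoms[n] for n in rb.sidechain_names()]
    best = np.inf
    for xyz in structure.models:
        d = np.linalg.norm(xyz[ia][:, None, :] - xyz[ib][None, :, :], axis=-1)
        best = min(best, float(d.min()))
    return best


# ---------------------------------------------------------------------------
# materialization into a concrete charged-atom system

@dataclass
class System:
    """One concrete all-atom state of one model: the input to the energies."""

    coords: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    names: list
    elements: list
    atom_res: np.ndarray
    is_sidechain: np.ndarray      # bool, Cβ and beyond (incl. side-chain H)
    is_polar_sc: np.ndarray       # His side-chain N / Asp side-chain O
    bonds: list
    excl_pairs: np.ndarray        # (K, 2) 1-2 and 1-3 pairs
    pair14: np.ndarray            # (K, 2) 1-4 pairs
    residue_of: list              # Residue objects aligned with structure

    def atoms_of_residue(self, ridx: int) -> np.ndarray:
        return np.nonzero(self.atom_res == ridx)[0]


def materialize(structure: ParameterizedStructure, model: int = 0,
                overrides: dict | None = None,
                h_torsions: dict | None = None,
                flips: set | None = None) -> System:
    """Build the concrete atom system for one model.

    ``overrides`` maps residue index -> (label, {atom name -> xyz}) and is how
    the sampling engine injects target-residue protonation variants.
    ``h_torsions`` maps (residue index, H name) -> torsion in degrees for
    rotatable polar hydrogens. ``flips`` is a set of residue indices whose
    Asn/Gln amide (or His ring / Asp carboxylate) heavy-atom pair positions
    are exchanged.
    """
    ps = structure.params
    if ps is None:
        raise ParameterError("assign_parameters must run before materialize")
    overrides = overrides or {}
    h_torsions = h_torsions or {}
    flips = flips or set()
    xyz_in = structure.models[model]

    names, elements, coords, charges, radii = [], [], [], [], []
    atom_res, is_sc, is_polar = [], [], []
    bonds: list = []
    index_of: dict = {}  # (ridx, atom name) -> system index

    for ridx, res in enumerate(structure.residues):
        if not res.usable:
            continue
        label, posmap = overrides.get(ridx, (res.label, None))
        if label is None:
            raise ParameterError(f"residue {res.key} has no protonation label")

        heavy = {}
        for aname, gidx in res.atoms.items():
            heavy[aname] = xyz_in[gidx].copy()
        if posmap:
            heavy.update({k: np.asarray(v, dtype=float) for k, v in posmap.items()})
        if ridx in flips:
            _apply_heavy_flip(res.restype if not res.is_het else res.name,
                              label, heavy)

        template = ps.atoms_of(label)
        heavy_template = [a for a in template
                          if ps.charges[(label, a)][2] != "H"]
        missing = [a for a in heavy_template if a not in heavy]
        if missing and not res.is_het:
            rebuilt = _rebuild_missing(ps, label, heavy, missing)
            if not rebuilt:
                res.usable = False
                log.warning("residue %s %s: cannot rebuild %s; skipped",
                            res.name, res.key, missing)
                continue

        polar_names = POLAR_SIDECHAIN.get(res.restype, ())
        for aname in template:
            q, r, elem = ps.charges[(label, aname)]
            if elem == "H":
                continue  # hydrogens placed after all heavy atoms exist
            if aname not in heavy:
                continue
            index_of[(ridx, aname)] = len(names)
            names.append(aname)
            elements.append(elem)
            coords.append(heavy[aname])
            charges.append(q)
            radii.append(r)
            atom_res.append(ridx)
            sc = aname not in BACKBONE
            is_sc.append(sc and not res.is_het)
            is_polar.append(sc and aname in polar_names)
        for a, b in ps.bonds.get(label, []):
            if (ridx, a) in index_of and (ridx, b) in index_of:
                bonds.append((index_of[(ridx, a)], index_of[(ridx, b)]))

    # peptide bonds between consecutive usable residues of the same chain
    order = [i for i, r in enumerate(structure.residues)
             if r.usable and not r.is_het]
    for a, b in zip(order, order[1:]):
        ra, rb = structure.residues[a], structure.residues[b]
        if ra.chain != rb.chain:
            continue
        if (a, "C") in index_of and (b, "N") in index_of:
            ca = np.asarray(coords[index_of[(a, "C")]])
            nb = np.asarray(coords[index_of[(b, "N")]])
            if np.linalg.norm(ca - nb) < 1.8:
                bonds.append((index_of[(a, "C")], index_of[(b, "N")]))

    # hydrogens from ideal geometry
    for ridx, res in enumerate(structure.residues):
        if not res.usable or res.is_het:
            continue
        label = overrides.get(ridx, (res.label, None))[0]
        for rule in ps.hydrogen_rules(label):
            if (label, rule.hname) not in ps.charges:
                continue
            pos = _place_hydrogen(rule, ridx, res, index_of, coords, bonds,
                                  h_torsions)
            if pos is None:
                continue
            q, r, elem = ps.charges[(label, rule.hname)]
            index_of[(ridx, rule.hname)] = len(names)
            names.append(rule.hname)
            elements.append(elem)
            coords.append(pos)
            charges.append(q)
            radii.append(r)
            atom_res.append(ridx)
            sc = rule.parent not in BACKBONE
            is_sc.append(sc)
            is_polar.append(False)
            bonds.append((index_of[(ridx, rule.parent)], len(names) - 1))

    coords = np.asarray(coords, dtype=float)
    excl, p14 = _exclusion_pairs(len(names), bonds)
    return System(coords=coords, charges=np.asarray(charges),
                  radii=np.asarray(radii), names=names, elements=elements,
                  atom_res=np.asarray(atom_res),
                  is_sidechain=np.asarray(is_sc, dtype=bool),
                  is_polar_sc=np.asarray(is_polar, dtype=bool),
                  bonds=bonds, excl_pairs=excl, pair14=p14,
                  residue_of=structure.residues)


FLIP_PAIRS = {
    ("HIS", "ring"): [("ND1", "CD2"), ("CE1", "NE2")],
    ("ASP", "carboxylate"): [("OD1", "OD2")],
    ("ASN", "amide"): [("OD1", "ND2")],
    ("GLN", "amide"): [("OE1", "NE2")],
}


def _apply_heavy_flip(restype: str, label: str, heavy: dict) -> None:
    if restype == "HIS" or label in ("HID", "HIE", "HIP"):
        pairs = FLIP_PAIRS[("HIS", "ring")]
    elif restype == "ASP" or label in ("ASP", "ASH"):
        pairs = FLIP_PAIRS[("ASP", "carboxylate")]
    elif restype == "ASN":
        pairs = FLIP_PAIRS[("ASN", "amide")]
    elif restype == "GLN":
        pairs = FLIP_PAIRS[("GLN", "amide")]
    else:
        return
    for a, b in pairs:
        if a in heavy and b in heavy:
            heavy[a], heavy[b] = heavy[b].copy(), heavy[a].copy()


# generic acyclic growth parameters for rebuilding missing side-chain atoms
_GROW = {"C": (1.52, 111.0), "N": (1.47, 112.0), "O": (1.41, 109.0),
         "S": (1.81, 112.0)}
_RING_LABELS = {"PHE", "TYR", "TRP", "HID", "HIE", "HIP", "PRO"}


def _rebuild_missing(ps: ParameterSet, label: str, heavy: dict,
                     missing: list) -> bool:
    """Rebuild missing acyclic side-chain heavy atoms from ideal internal
    coordinates (trans growth along the bond template). Rings are refused."""
    if label in _RING_LABELS:
        return False
    nbrs: dict = {}
    for a, b in ps.bonds.get(label, []):
        nbrs.setdefault(a, []).append(b)
        nbrs.setdefault(b, []).append(a)
    for _ in range(len(missing) + 1):
        still = [a for a in missing if a not in heavy]
        if not still:
            return True
        progress = False
        for aname in still:
            par = [n for n in nbrs.get(aname, []) if n in heavy]
            if not par:
                continue
            c = par[0]
            gp = [n for n in nbrs.get(c, []) if n in heavy and n != aname]
            if not gp:
                continue
            b = gp[0]
            ggp = [n for n in nbrs.get(b, []) if n in heavy and n != c]
            a3 = ggp[0] if ggp else None
            if a3 is None:
                continue
            elem = ps.charges[(label, aname)][2]
            length, angle = _GROW.get(elem, (1.52, 111.0))
            heavy[aname] = place_atom(heavy[c], heavy[b], heavy[a3],
                                      length, angle, 180.0)
            progress = True
        if not progress:
            return False
    return all(a in heavy for a in missing)


def _place_hydrogen(rule, ridx, res, index_of, coords, bonds, h_torsions):
    parent_key = (ridx, rule.parent)
    if parent_key not in index_of:
        return None
    ppos = np.asarray(coords[index_of[parent_key]])
    if rule.kind == "bisect":
        pidx = index_of[parent_key]
        nb = [j if i == pidx else i for (i, j) in bonds
              if pidx in (i, j)]
        heavy_nb = [coords[k] for k in nb]
        if len(heavy_nb) < 2:
            # chain-terminal amide N: use the residue's own C as a stand-in
            # second reference so the proton is still placed deterministically
            alt = index_of.get((ridx, "C"))
            if alt is None or len(heavy_nb) < 1:
                return None
            heavy_nb.append(coords[alt])
        return sp2_bisector_h(ppos, np.asarray(heavy_nb[0]),
                              np.asarray(heavy_nb[1]), rule.length)
    r2 = index_of.get((ridx, rule.ref2))
    r3 = index_of.get((ridx, rule.ref3))
    if r2 is None or r3 is None:
        return None
    torsion = rule.torsion
    if rule.kind in ("rot", "rot3"):
        base = h_torsions.get((ridx, rule.hname))
        if base is None and rule.kind == "rot3":
            grp = h_torsions.get((ridx, "NZ-group"))
            if grp is not None:
                torsion = rule.torsion + grp
        elif base is not None:
            torsion = base
    elif (ridx, rule.hname) in h_torsions:   # e.g. ASH syn/anti override
        torsion = h_torsions[(ridx, rule.hname)]
    return place_atom(ppos, np.asarray(coords[r2]), np.asarray(coords[r3]),
                      rule.length, rule.angle, torsion)


def _exclusion_pairs(n: int, bonds: list):
    """1-2/1-3 pairs (excluded) and 1-4 pairs via breadth-first search."""
    adj: list = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    excl, p14 = set(), set()
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        for d in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = d
                        nxt.append(v)
            frontier = nxt
        for v, d in dist.items():
            if v <= s:
                continue
            if d in (1, 2):
                excl.add((s, v))
            elif d == 3:
                p14.add((s, v))
    p14 -= excl
    to_arr = lambda s: (np.array(sorted(s), dtype=np.int64).reshape(-1, 2)
                        if s else np.zeros((0, 2), dtype=np.int64))
    return to_arr(excl), to_arr(p14)


# ---------------------------------------------------------------------------
# writing

def write_pdb(structure: ParameterizedStructure) -> str:
    """Serialize the prepared structure back to minimal PDB text."""
    lines = []
    multi = structure.n_models > 1
    for m, xyz in enumerate(structure.models, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for ridx, res in enumerate(structure.residues):
            rec = "HETATM" if res.is_het else "ATOM  "
            for name, gidx in res.atoms.items():
                x, y, z = xyz[gidx]
                el = structure.atom_elements[gidx]
                nm = name if len(name) == 4 else f" {name:<3s}"
                lines.append(
                    f"{rec}{serial:5d} {nm}{'':1s}{res.name:<3s} {res.chain:1s}"
                    f"{res.seqid:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}")
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
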