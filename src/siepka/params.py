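"""Bundled force-field parameter tables: charges, radii, bonds, hydrogens,
rotamers.

All tables are plain TSV under ``siepka/data`` and can be extended or
overridden by user-supplied files of the same layout (e.g. to parameterize a
whitelisted cofactor).
"""
from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ParameterSet", "ParameterError", "HIS_LABELS", "ASP_LABELS",
           "BACKGROUND_LABEL"]

#: protonation labels per titratable residue type
HIS_LABELS = ("HID", "HIE", "HIP")
ASP_LABELS = ("ASP", "ASH")

#: default background label for each standard residue name
BACKGROUND_LABEL = {
    "ALA": "ALA", "GLY": "GLY", "SER": "SER", "THR": "THR", "CYS": "CYS",
    "VAL": "VAL", "LEU": "LEU", "ILE": "ILE", "MET": "MET", "PRO": "PRO",
    "PHE": "PHE", "TYR": "TYR", "TRP": "TRP", "ASN": "ASN", "GLN": "GLN",
    "ASP": "ASP", "GLU": "GLU", "LYS": "LYS", "ARG": "ARG",
    # His tautomer is decided by the H-bond scorer; HIE is the fallback
    "HIS": "HIE", "HID": "HID", "HIE": "HIE", "HIP": "HIP", "ASH": "ASH",
}


class ParameterError(KeyError):
    """Unknown residue label or atom name in the parameter tables."""


def _read_data(name: str) -> pd.DataFrame:
    with resources.files("siepka.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@dataclass
class HydrogenRule:
    hname: str
    parent: str
    ref2: str
    ref3: str
    length: float
    angle: float
    torsion: float
    kind: str  # bisect | torsion | rot | rot3


@dataclass
class ParameterSet:
    """Charge/radius/bond/hydrogen/rotamer tables indexed for fast lookup."""

    charges: dict = field(default_factory=dict)   # (label, atom) -> (q, r, elem)
    bonds: dict = field(default_factory=dict)     # label -> [(a1, a2)]
    hydrogens: dict = field(default_factory=dict)  # label -> [HydrogenRule]
    rotamers: dict = field(default_factory=dict)  # restype -> [(chi1, chi2)]

    @classmethod
    def load_default(cls) -> "ParameterSet":
        ps = cls()
        ps.add_charge_table(_read_data("charges.tsv"))
        for _, row in _read_data("bonds.tsv").iterrows():
            ps.bonds.setdefault(row["label"], []).append((row["atom1"], row["atom2"]))
        for _, row in _read_data("hydrogens.tsv").iterrows():
            rule = HydrogenRule(row["hname"], row["parent"], row["ref2"],
                                row["ref3"], float(row["length"]),
                                float(row["angle"]), float(row["torsion"]),
                                row["kind"])
            ps.hydrogens.setdefault(row["label"], []).append(rule)
        for _, row in _read_data("rotamers.tsv").iterrows():
            ps.rotamers.setdefault(row["restype"], []).append(
                (float(row["chi1"]), float(row["chi2"])))
        return ps

    def add_charge_table(self, df: pd.DataFrame) -> None:
        for _, row in df.iterrows():
            self.charges[(row["label"], row["atom"])] = (
                float(row["charge"]), float(row["radius"]), row["element"])

    def add_charge_file(self, path: str) -> None:
        """Merge a user-supplied charge/radius TSV (label, atom, element,
        charge, radius), e.g. for a whitelisted HET group."""
        self.add_charge_table(pd.read_csv(path, sep="\t"))

    def add_bond(self, label: str, a1: str, a2: str) -> None:
        self.bonds.setdefault(label, []).append((a1, a2))

    def lookup(self, label: str, atom: str):
        try:
            return self.charges[(label, atom)]
        except KeyError:
            raise ParameterError(
                f"no charge/radius entry for atom {atom!r} of residue label "
                f"{label!r}") from None

    def atoms_of(self, label: str) -> list[str]:
        return [a for (lab, a) in self.charges if lab == label]

    def hydrogen_rules(self, label: str) -> list[HydrogenRule]:
        rules = list(self.hydrogens.get(label, []))
        # the wildcard backbone amide H applies to everything except proline
        if label != "PRO":
            rules = [r for r in self.hydrogens.get("*", [])] + rules
        return rules

    def formal_charge(self, label: str) -> float:
        q = sum(v[0] for (lab, _a), v in self.charges.items() if lab == label)
        return round(q)
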