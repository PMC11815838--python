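"""Regenerate the bundled parameter tables under src/siepka/data/.

Maintainer tool; the generated TSVs are committed.

Charges: polar hydrogens explicit, nonpolar-H charges folded into their
carbon; per-residue sums forced exactly onto the designated sink atom so every
label sums to its formal charge.
"""
import os

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "siepka", "data")
os.makedirs(OUT, exist_ok=True)

RADII = {"C": 1.908, "N": 1.824, "O": 1.6612, "S": 2.0, "H": 0.6}

BB = [("N", "N", -0.4157), ("H", "H", 0.2719), ("CA", "C", 0.1160),
      ("C", "C", 0.5973), ("O", "O", -0.5679)]
BB_PRO = [("N", "N", -0.2548), ("CA", "C", 0.1160), ("C", "C", 0.5973),
          ("O", "O", -0.5679)]

# name -> (formal charge, sink atom, side-chain atoms [(name, element, charge)])
RES = {
    "ALA": (0, "CB", [("CB", "C", 0.0)]),
    "GLY": (0, "CA", []),
    "SER": (0, "CB", [("CB", "C", 0.2), ("OG", "O", -0.6546), ("HG", "H", 0.4275)]),
    "THR": (0, "CB", [("CB", "C", 0.27), ("OG1", "O", -0.6761), ("HG1", "H", 0.4102),
                      ("CG2", "C", 0.0)]),
    "CYS": (0, "CB", [("CB", "C", 0.1), ("SG", "S", -0.3119), ("HG", "H", 0.1933)]),
    "VAL": (0, "CB", [("CB", "C", 0.1), ("CG1", "C", 0.0), ("CG2", "C", 0.0)]),
    "LEU": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.1), ("CD1", "C", 0.0),
                      ("CD2", "C", 0.0)]),
    "ILE": (0, "CB", [("CB", "C", 0.1), ("CG1", "C", 0.0), ("CG2", "C", 0.0),
                      ("CD1", "C", 0.0)]),
    "MET": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.06), ("SD", "S", -0.2737),
                      ("CE", "C", 0.15)]),
    "PRO": (0, "CD", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD", "C", 0.1)]),
    "PHE": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD1", "C", 0.0),
                      ("CD2", "C", 0.0), ("CE1", "C", 0.0), ("CE2", "C", 0.0),
                      ("CZ", "C", 0.0)]),
    "TYR": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD1", "C", 0.0),
                      ("CD2", "C", 0.0), ("CE1", "C", 0.0), ("CE2", "C", 0.0),
                      ("CZ", "C", 0.3226), ("OH", "O", -0.5579), ("HH", "H", 0.3992)]),
    "TRP": (0, "CB", [("CB", "C", 0.0), ("CG", "C", -0.1), ("CD1", "C", 0.1),
                      ("NE1", "N", -0.3418), ("HE1", "H", 0.3412), ("CE2", "C", 0.138),
                      ("CD2", "C", 0.0), ("CE3", "C", 0.0), ("CZ2", "C", 0.0),
                      ("CZ3", "C", 0.0), ("CH2", "C", 0.0)]),
    "ASN": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.5833), ("OD1", "O", -0.5931),
                      ("ND2", "N", -0.9191), ("HD21", "H", 0.4196), ("HD22", "H", 0.4196)]),
    "GLN": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD", "C", 0.5833),
                      ("OE1", "O", -0.5931), ("NE2", "N", -0.9191),
                      ("HE21", "H", 0.4196), ("HE22", "H", 0.4196)]),
    "ASP": (-1, "CB", [("CB", "C", -0.2), ("CG", "C", 0.7994), ("OD1", "O", -0.8014),
                       ("OD2", "O", -0.8014)]),
    "ASH": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.6462), ("OD1", "O", -0.5554),
                      ("OD2", "O", -0.6376), ("HD2", "H", 0.4747)]),
    "GLU": (-1, "CB", [("CB", "C", 0.0), ("CG", "C", -0.2), ("CD", "C", 0.8054),
                       ("OE1", "O", -0.8188), ("OE2", "O", -0.8188)]),
    "LYS": (1, "CB", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD", "C", 0.0),
                      ("CE", "C", 0.3260), ("NZ", "N", -0.3854), ("HZ1", "H", 0.34),
                      ("HZ2", "H", 0.34), ("HZ3", "H", 0.34)]),
    "ARG": (1, "CB", [("CB", "C", 0.0), ("CG", "C", 0.0), ("CD", "C", 0.2),
                      ("NE", "N", -0.5295), ("HE", "H", 0.3456), ("CZ", "C", 0.8076),
                      ("NH1", "N", -0.8), ("HH11", "H", 0.4478), ("HH12", "H", 0.4478),
                      ("NH2", "N", -0.8), ("HH21", "H", 0.4478), ("HH22", "H", 0.4478)]),
    "HID": (0, "CB", [("CB", "C", 0.0), ("CG", "C", -0.0266), ("ND1", "N", -0.3811),
                      ("HD1", "H", 0.3649), ("CE1", "C", 0.3449), ("NE2", "N", -0.5727),
                      ("CD2", "C", 0.2439)]),
    "HIE": (0, "CB", [("CB", "C", 0.0), ("CG", "C", 0.1868), ("ND1", "N", -0.5432),
                      ("CE1", "C", 0.3070), ("NE2", "N", -0.2795), ("HE2", "H", 0.3339),
                      ("CD2", "C", -0.0345)]),
    "HIP": (1, "CB", [("CB", "C", 0.0), ("CG", "C", -0.0014), ("ND1", "N", -0.1513),
                      ("HD1", "H", 0.3866), ("CE1", "C", 0.2511), ("NE2", "N", -0.1718),
                      ("HE2", "H", 0.3911), ("CD2", "C", 0.1176)]),
}

rows = []
for label, (formal, sink, side) in RES.items():
    bb = BB_PRO if label == "PRO" else BB
    atoms = [(n, e, q) for (n, e, q) in bb] + list(side)
    total = sum(q for _, _, q in atoms)
    fixed = [(n, e, q + (formal - total if n == sink else 0.0)) for n, e, q in atoms]
    s = sum(q for _, _, q in fixed)
    assert abs(s - formal) < 1e-12, (label, s)
    for n, e, q in fixed:
        rows.append((label, n, e, q, RADII[e]))

with open(os.path.join(OUT, "charges.tsv"), "w") as f:
    f.write("label\tatom\telement\tcharge\tradius\n")
    for label, n, e, q, r in rows:
        f.write(f"{label}\t{n}\t{e}\t{q:.4f}\t{r:.4f}\n")

# ---- bond templates (intra-residue; C(i)-N(i+1) peptide bond added in code)
BONDS_BB = [("N", "H"), ("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]
SIDE_BONDS = {
    "ALA": [],
    "GLY": [],
    "SER": [("CB", "OG"), ("OG", "HG")],
    "THR": [("CB", "OG1"), ("OG1", "HG1"), ("CB", "CG2")],
    "CYS": [("CB", "SG"), ("SG", "HG")],
    "VAL": [("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "TYR": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"),
            ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH"), ("OH", "HH")],
    "TRP": [("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"), ("CD1", "NE1"),
            ("NE1", "HE1"), ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "ASN": [("CB", "CG"), ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22")],
    "GLN": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2"),
            ("NE2", "HE21"), ("NE2", "HE22")],
    "ASP": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "ASH": [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2"), ("OD2", "HD2")],
    "GLU": [("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "LYS": [("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ"),
            ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
    "ARG": [("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "HE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2"), ("NH1", "HH11"), ("NH1", "HH12"),
            ("NH2", "HH21"), ("NH2", "HH22")],
    "HID": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("ND1", "HD1"), ("CE1", "NE2"), ("NE2", "CD2")],
    "HIE": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "HE2"), ("NE2", "CD2")],
    "HIP": [("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"),
            ("ND1", "HD1"), ("CE1", "NE2"), ("NE2", "HE2"), ("NE2", "CD2")],
}

with open(os.path.join(OUT, "bonds.tsv"), "w") as f:
    f.write("label\tatom1\tatom2\n")
    for label in RES:
        names = {n for n, _, _ in (BB_PRO if label == "PRO" else BB)} | \
                {n for n, _, _ in RES[label][2]}
        for a, b in BONDS_BB + SIDE_BONDS[label]:
            if a in names and b in names and not (label == "PRO" and (a, b) == ("N", "H")):
                f.write(f"{label}\t{a}\t{b}\n")

# ---- hydrogen building templates
# kind: bisect  -> in-plane, anti to the bisector of the parent's two heavy
#                  neighbours (backbone NH, ring NH)
#       torsion -> NeRF placement from (parent, ref2, ref3) with fixed torsion
#       rot     -> like torsion but the torsion is a rotatable degree of freedom
# columns: label hname parent ref2 ref3 length angle torsion kind
H_TEMPLATES = [
    ("*", "H", "N", "-", "-", 1.010, 119.0, 0.0, "bisect"),
    ("SER", "HG", "OG", "CB", "CA", 0.960, 108.5, 180.0, "rot"),
    ("THR", "HG1", "OG1", "CB", "CA", 0.960, 108.5, 180.0, "rot"),
    ("CYS", "HG", "SG", "CB", "CA", 1.340, 96.0, 180.0, "rot"),
    ("TYR", "HH", "OH", "CZ", "CE1", 0.960, 110.0, 0.0, "rot"),
    ("TRP", "HE1", "NE1", "-", "-", 1.010, 125.0, 0.0, "bisect"),
    ("ASN", "HD21", "ND2", "CG", "OD1", 1.010, 120.0, 180.0, "torsion"),
    ("ASN", "HD22", "ND2", "CG", "OD1", 1.010, 120.0, 0.0, "torsion"),
    ("GLN", "HE21", "NE2", "CD", "OE1", 1.010, 120.0, 180.0, "torsion"),
    ("GLN", "HE22", "NE2", "CD", "OE1", 1.010, 120.0, 0.0, "torsion"),
    ("LYS", "HZ1", "NZ", "CE", "CD", 1.010, 109.5, 60.0, "rot3"),
    ("LYS", "HZ2", "NZ", "CE", "CD", 1.010, 109.5, 180.0, "rot3"),
    ("LYS", "HZ3", "NZ", "CE", "CD", 1.010, 109.5, 300.0, "rot3"),
    ("ARG", "HE", "NE", "-", "-", 1.010, 120.0, 0.0, "bisect"),
    ("ARG", "HH11", "NH1", "CZ", "NE", 1.010, 120.0, 0.0, "torsion"),
    ("ARG", "HH12", "NH1", "CZ", "NE", 1.010, 120.0, 180.0, "torsion"),
    ("ARG", "HH21", "NH2", "CZ", "NE", 1.010, 120.0, 0.0, "torsion"),
    ("ARG", "HH22", "NH2", "CZ", "NE", 1.010, 120.0, 180.0, "torsion"),
    ("HID", "HD1", "ND1", "-", "-", 1.010, 125.0, 0.0, "bisect"),
    ("HIE", "HE2", "NE2", "-", "-", 1.010, 125.0, 0.0, "bisect"),
    ("HIP", "HD1", "ND1", "-", "-", 1.010, 125.0, 0.0, "bisect"),
    ("HIP", "HE2", "NE2", "-", "-", 1.010, 125.0, 0.0, "bisect"),
    # ASH carboxyl proton: torsion 0 = syn (eclipsing OD1), 180 = anti
    ("ASH", "HD2", "OD2", "CG", "OD1", 0.960, 113.0, 0.0, "torsion"),
]
with open(os.path.join(OUT, "hydrogens.tsv"), "w") as f:
    f.write("label\thname\tparent\tref2\tref3\tlength\tangle\ttorsion\tkind\n")
    for row in H_TEMPLATES:
        f.write("\t".join(str(x) for x in row) + "\n")

# ---- backbone-independent rotamer library (chi modes, degrees)
ROTAMERS = {
    "HIS": [(62, -75), (62, 80), (-177, -165), (-177, -80), (-177, 60),
            (-65, -70), (-65, 165), (-65, 80)],
    "ASP": [(62, -10), (62, 65), (-177, 10), (-177, 65), (-65, -25), (-65, 30)],
}
with open(os.path.join(OUT, "rotamers.tsv"), "w") as f:
    f.write("restype\trotamer\tchi1\tchi2\n")
    for rt, rots in ROTAMERS.items():
        for i, (c1, c2) in enumerate(rots, 1):
            f.write(f"{rt}\t{i}\t{c1}\t{c2}\n")

print("wrote tables to", os.path.abspath(OUT))
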