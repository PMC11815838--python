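#!/usr/bin/env python
"""Optional external-data benchmark: antibody CDR His-scanning mutants.

Reproduces the worked example on the bH1 Fab / Her2 complex (PDB entry
3BE1, to be downloaded separately by the user): each position listed in
``benchmark_3be1_targets.tsv`` is mutated to histidine in silico, the full
pipeline predicts its pKa and side-chain SESA in the bound complex, and the
results are compared with the reported values (tolerance for agreement:
±0.5 pH, ±15 Å²).

    python scripts/benchmark_3be1.py --pdb 3be1.pdb --out results/3be1.json \
        [--heavy H --light L] [--spacing 0.5]

This harness is not part of the offline test suite: it needs the external
structure and takes on the order of hours per run on one CPU at default
solver settings (the complex has thousands of atoms; use --spacing to
trade accuracy for time).
"""
from __future__ import annotations

import argparse
import json
import os

import numpy as np
import pandas as pd

from siepka.electrostatics import SolverSettings
from siepka.engine import predict
from siepka.geometry import place_atom
from siepka.params import ParameterSet
from siepka.structure import read_structure, write_pdb

HERE = os.path.dirname(os.path.abspath(__file__))


def mutate_to_his(structure, key):
    """Replace the side chain of ``key`` by an ideal imidazole at a
    canonical rotamer; the engine's rotamer sampling refines it."""
    res = structure.residue_by_key(key)
    keep = {n: i for n, i in res.atoms.items()
            if n in ("N", "CA", "C", "O", "CB")}
    if "CB" not in keep:
        raise ValueError(f"cannot mutate {key}: no CB atom")
    res.atoms = keep
    res.name = "HIS"
    res.label = None
    new_names = ["CG", "ND1", "CD2", "CE1", "NE2"]
    base = len(structure.atom_names)
    structure.atom_names += new_names
    structure.atom_elements += ["C", "N", "C", "C", "N"]
    structure.atom_res = np.concatenate(
        [structure.atom_res,
         np.full(5, structure.residues.index(res))])
    for m, xyz in enumerate(structure.models):
        n, ca, cb = (xyz[keep[a]] for a in ("N", "CA", "CB"))
        cg = place_atom(cb, ca, n, 1.50, 113.8, -177.0)
        nd1 = place_atom(cg, cb, ca, 1.38, 122.8, 165.0)
        cd2 = place_atom(cg, cb, ca, 1.36, 131.2, -15.0)
        ce1 = place_atom(nd1, cg, cb, 1.32, 109.0, 180.0)
        ne2 = place_atom(ce1, nd1, cg, 1.32, 108.5, 0.0)
        structure.models[m] = np.vstack([xyz, cg, nd1, cd2, ce1, ne2])
    for i, nm in enumerate(new_names):
        res.atoms[nm] = base + i


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--pdb", required=True, help="local path to the 3BE1 file")
    ap.add_argument("--out", required=True)
    ap.add_argument("--heavy", default="H", help="Fab heavy-chain id")
    ap.add_argument("--light", default="L", help="Fab light-chain id")
    ap.add_argument("--spacing", type=float, default=0.4,
                    help="fine Poisson grid spacing, Å")
    args = ap.parse_args()

    targets = pd.read_csv(os.path.join(HERE, "benchmark_3be1_targets.tsv"),
                          sep="\t", keep_default_na=False)
    settings = SolverSettings(grid_spacing=args.spacing)
    tables = ParameterSet.load_default()
    with open(args.pdb) as fh:
        pdb_text = fh.read()

    results = {}
    for _, row in targets.iterrows():
        chain = args.heavy if row["chain_kind"] == "H" else args.light
        key = (chain, int(row["resnum"]), str(row["icode"]).strip())
        st = read_structure(pdb_text, params=tables)
        mutate_to_his(st, key)
        st = read_structure(write_pdb(st), params=tables)
        pred = predict(st, [key], settings=settings)[0]
        results[row["variant"]] = {
            "residue": f"{chain}:{row['resnum']}{row['icode']}",
            "predicted_pka": round(pred.effective_pka, 2),
            "reported_pka": float(row["reported_pka"]),
            "pka_abs_diff": round(abs(pred.effective_pka
                                      - row["reported_pka"]), 2),
            "predicted_sesa": round(pred.sesa, 1),
            "reported_sesa": float(row["reported_sesa"]),
            "sesa_abs_diff": round(abs(pred.sesa - row["reported_sesa"]), 1),
        }
        print(row["variant"], results[row["variant"]])

    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(results, fh, indent=2)


if __name__ == "__main__":
    main()
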