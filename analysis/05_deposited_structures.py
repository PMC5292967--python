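#!/usr/bin/env python
"""Measurement battery on locally provided deposited structures.

The full analysis (ground-state RMSD between crystal forms, G-helix
angle and rigid-body monomer rotation between the U- and V-shaped
complexes, TM2 piston and axial rotation between ground and activated
states, ENM/RTB transition reconstruction) can be run on real PDB
entries of the receptor–transducer complex when local copies exist:

    data/5JJE.pdb  U-shaped ground state (I 21 21 21)
    data/5JJF.pdb  activated (M) state of the same crystal form
    data/5JJJ.pdb  second ground-state complex
    data/1H2S.pdb  V-shaped ground state (P 21 21 2)

This script never downloads anything; it exits cleanly with a note
when the files are absent.  Chain correspondence between depositions
can be given in data/chain_map.json as {"file": {"A": "X", ...}}.
"""

import json
import sys
from pathlib import Path

from uvnma.structures import AtomSelection, pair_common_atoms, read_pdb
from uvnma.superpose import rmsd, superpose

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data"
ENTRIES = {"5JJE": "U-shaped ground state", "5JJF": "activated M state",
           "5JJJ": "second ground state", "1H2S": "V-shaped ground state"}


def load_available() -> dict:
    found = {}
    for code in ENTRIES:
        p = DATA / f"{code}.pdb"
        if p.exists():
            found[code] = read_pdb(p)
    return found


def main() -> int:
    structures = load_available()
    if not structures:
        print("No deposited structures found under data/; place local copies "
              "of " + ", ".join(f"{c}.pdb" for c in ENTRIES)
              + " there to run this analysis. Nothing to do.")
        return 0
    chain_map = {}
    map_file = DATA / "chain_map.json"
    if map_file.exists():
        chain_map = json.loads(map_file.read_text())
    for code, st in structures.items():
        print(f"{code} ({ENTRIES[code]}): {len(st)} atoms, "
              f"chains {st.chains()}, cell {st.unit_cell}, "
              f"space group {st.space_group}")
        if code == "1H2S":
            # 2:2 stoichiometry: two receptor chains + two transducer chains
            print(f"  chain count: {len(st.chains())}")
    if "5JJE" in structures and "5JJJ" in structures:
        a, b = structures["5JJE"], structures["5JJJ"]
        xa, xb, keys = pair_common_atoms(
            a, b, AtomSelection.make(atom_names=("N", "CA", "C", "O")),
            chain_map.get("5JJJ"))
        print(f"\nground-state backbone RMSD over {len(keys)} shared atoms: "
              f"{rmsd(xa, xb, fit=True):.3f} Å")
    if "5JJE" in structures and "1H2S" in structures:
        print("\nU-vs-V geometry requires a chain map between the two "
              "depositions (data/chain_map.json); pair with "
              "pair_common_atoms and measure with "
              "uvnma.superpose.relative_monomer_rotation / "
              "uvnma.geometry.fit_helix_axis as in analysis/02_geometry.py.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
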