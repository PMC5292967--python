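#!/usr/bin/env python
"""Generate the synthetic study structures.

Writes the U/V complex pairs used throughout the analysis (planted
8.5° receptor rotation with 0.5 Å TM2 piston and 19° twist; an 11°
pair for the helix-angle measurement; a noisy replicate) plus the
tight/open crystal-packing fixtures, and records the planted ground
truth alongside.
"""

import json
from pathlib import Path

from uvnma.structures import write_pdb
from uvnma.synthetic import (
    ComplexSpec, lattice_preset, make_lattice_fixture, make_u_v_pair,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "structures"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    specs = {
        "planted_8p5": ComplexSpec(receptor_rotation_deg=8.5, piston_A=0.5,
                                   tm2_twist_deg=19.0),
        "planted_11": ComplexSpec(receptor_rotation_deg=11.0),
        "planted_8p5_noisy": ComplexSpec(receptor_rotation_deg=8.5,
                                         piston_A=0.5, tm2_twist_deg=19.0,
                                         noise_sigma=0.2, seed=1),
    }
    truths = {}
    for name, spec in specs.items():
        u, v, truth = make_u_v_pair(spec)
        write_pdb(u, OUT / f"{name}_U.pdb")
        write_pdb(v, OUT / f"{name}_V.pdb")
        truths[name] = {
            "receptor_rotation_deg": truth.receptor_rotation_deg,
            "piston_A": truth.piston_A,
            "tm2_twist_deg": truth.tm2_twist_deg,
            "noise_sigma": truth.noise_sigma,
            "seed": truth.seed,
        }
        print(f"{name}: {len(u)} atoms, planted rotation "
              f"{truth.receptor_rotation_deg}°, piston {truth.piston_A} Å, "
              f"twist {truth.tm2_twist_deg}°")
    for preset in ("tight", "open"):
        fx = make_lattice_fixture(lattice_preset(preset))
        write_pdb(fx, OUT / f"lattice_{preset}.pdb")
        print(f"lattice_{preset}: {len(fx)} atoms, {fx.space_group}, "
              f"cell {fx.unit_cell}")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=2)
    print(f"\nwrote structures + ground truth to {OUT}")


if __name__ == "__main__":
    main()
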