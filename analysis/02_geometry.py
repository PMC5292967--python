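#!/usr/bin/env python
"""Rigid-body and helix geometry: planted vs recovered.

Measures, for a range of coordinate-noise levels, the receptor's
rigid-body rotation between the U and V forms, the G-helix tilt, and
the TM2 piston and axial rotation, and tabulates recovery accuracy.
The noiseless rows recover the planted values to machine precision;
at 0.2 Å noise the 20-seed means stay within a few percent.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from uvnma.geometry import (
    fit_helix_axis, helix_axial_rotation, interhelix_angle, piston_displacement,
)
from uvnma.structures import pair_common_atoms
from uvnma.superpose import relative_monomer_rotation, superpose
from uvnma.synthetic import ComplexLayout, ComplexSpec, make_u_v_pair

OUT = Path(__file__).resolve().parent.parent / "results"
LAYOUT = ComplexLayout()


def measure(spec: ComplexSpec) -> dict:
    u, v, _ = make_u_v_pair(spec)
    fu, fv, _ = pair_common_atoms(u, v, LAYOUT.frame_selection())
    v_al = v.with_coords(superpose(fv, fu).apply(v.coords))
    frame = LAYOUT.membrane_frame()
    ga = fit_helix_axis(u, "A", LAYOUT.g_helix_range)
    gb = fit_helix_axis(v_al, "A", LAYOUT.g_helix_range)
    return {
        "monomer_rotation_deg": relative_monomer_rotation(
            u, v_al, LAYOUT.receptor_selection("A"),
            LAYOUT.frame_selection()).angle_deg,
        "g_helix_angle_deg": interhelix_angle(ga, gb),
        "piston_A": piston_displacement(u, v_al, "C", LAYOUT.tm2_range,
                                        frame, end="whole"),
        "tm2_twist_deg": helix_axial_rotation(u, v_al, "C", LAYOUT.tm2_range),
    }


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for sigma in (0.0, 0.05, 0.1, 0.2):
        seeds = [0] if sigma == 0.0 else range(20)
        acc = []
        for s in seeds:
            acc.append(measure(ComplexSpec(receptor_rotation_deg=8.5,
                                           piston_A=0.5, tm2_twist_deg=19.0,
                                           noise_sigma=sigma, seed=s)))
            g = measure(ComplexSpec(receptor_rotation_deg=11.0,
                                    noise_sigma=sigma, seed=1000 + s))
            acc[-1]["g_helix_angle_11_deg"] = g["g_helix_angle_deg"]
        df = pd.DataFrame(acc)
        rows.append({
            "noise_sigma_A": sigma,
            "n_seeds": len(seeds),
            "monomer_rotation_deg (planted 8.5)": df["monomer_rotation_deg"].mean(),
            "g_helix_angle_deg (planted 11)": df["g_helix_angle_11_deg"].mean(),
            "piston_A (planted 0.5)": df["piston_A"].mean(),
            "tm2_twist_deg (planted 19)": df["tm2_twist_deg"].mean(),
        })
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "geometry_recovery.csv", index=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(f"\nwrote {OUT/'geometry_recovery.csv'}")


if __name__ == "__main__":
    main()
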