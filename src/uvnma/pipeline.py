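"""End-to-end U→V analysis: one config in, one structured report out.

``run_u2v_analysis`` chains every stage of the workflow — atom pairing
and frame superposition, rigid-body monomer rotation and G-helix
angle, TM2 piston and axial rotation, elastic-network modes (full and
RTB) on the U form, projection of the U→V displacement onto the
low-frequency modes with the best-k reconstruction and a V-like model,
and optionally the lattice clash comparison of the tight/open crystal
packings.  Inputs are either the synthetic preset (planted ground
truth, fully seeded) or a pair of PDB files.

The report is a plain nested dict (JSON-serializable); a saved config
reruns bit-identically for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import enm, geometry, lattice, superpose, synthetic, transition
from .structures import AtomSelection, Structure, read_pdb, write_pdb

__all__ = ["RunConfig", "PipelineStageError", "run_u2v_analysis"]

REPORT_SCHEMA_VERSION = 1


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage label."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Fully serializable run parameters."""

    # inputs: synthetic preset (default) or explicit PDB paths
    u_path: str | None = None
    v_path: str | None = None
    receptor_rotation_deg: float = 8.5
    piston_A: float = 0.5
    tm2_twist_deg: float = 19.0
    noise_sigma: float = 0.0
    seed: int = 0
    # ENM / transition parameters
    cutoff: float = 10.0
    gamma: float = 1.0
    block_scheme: str = "per-helix"        # per-helix | per-residue | uniform:<b>
    k_modes: int = 10
    # lattice stage
    run_lattice: bool = True
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def _blocks_for(scheme: str, structure: Structure,
                layout: synthetic.ComplexLayout,
                n_nodes: int) -> enm.BlockDefinition:
    if scheme == "per-helix":
        return enm.BlockDefinition.from_segments(layout.helix_segments(structure))
    if scheme == "per-residue":
        return enm.BlockDefinition.single_nodes(n_nodes)
    if scheme.startswith("uniform:"):
        return enm.BlockDefinition.uniform(n_nodes, int(scheme.split(":", 1)[1]))
    raise ValueError(f"unknown block scheme {scheme!r}")


def _stage(label: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(label, exc) from exc
        return wrapped
    return deco


def run_u2v_analysis(config: RunConfig) -> dict:
    """Execute the full workflow and return the structured report."""
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": config.to_dict(),
        "stages": {},
    }
    layout = synthetic.ComplexLayout()
    frame = layout.membrane_frame()

    @_stage("inputs")
    def load() -> tuple[Structure, Structure, synthetic.GroundTruth | None]:
        if config.u_path and config.v_path:
            return read_pdb(config.u_path), read_pdb(config.v_path), None
        spec = synthetic.ComplexSpec(
            receptor_rotation_deg=config.receptor_rotation_deg,
            piston_A=config.piston_A,
            tm2_twist_deg=config.tm2_twist_deg,
            noise_sigma=config.noise_sigma,
            seed=config.seed,
        )
        return synthetic.make_u_v_pair(spec)

    u, v, truth = load()
    if truth is not None:
        report["stages"]["planted"] = {
            "receptor_rotation_deg": truth.receptor_rotation_deg,
            "piston_A": truth.piston_A,
            "tm2_twist_deg": truth.tm2_twist_deg,
            "noise_sigma": truth.noise_sigma,
        }

    # --- rigid-body geometry -------------------------------------------------
    try:
        frame_sel = layout.frame_selection()
        rot = superpose.relative_monomer_rotation(
            u, v, layout.receptor_selection("A"), frame_sel)
        from .structures import pair_common_atoms
        fu, fv, _ = pair_common_atoms(u, v, frame_sel)
        frame_fit = superpose.superpose(fv, fu)
        v_aligned = v.with_coords(frame_fit.apply(v.coords))
        ax_u = geometry.fit_helix_axis(u, "A", layout.g_helix_range)
        ax_v = geometry.fit_helix_axis(v_aligned, "A", layout.g_helix_range)
        g_angle = geometry.interhelix_angle(ax_u, ax_v)
        report["stages"]["rigid_body_geometry"] = {
            "monomer_rotation_deg": rot.angle_deg,
            "monomer_rotation_axis": rot.axis.tolist(),
            "g_helix_angle_deg": g_angle,
            "frame_rmsd": frame_fit.rmsd_after,
        }
    except Exception as exc:
        raise PipelineStageError("rigid_body_geometry", exc) from exc

    # --- piston + axial rotation of TM2 -------------------------------------
    try:
        piston = geometry.piston_displacement(
            u, v_aligned, "C", layout.tm2_range, frame, end="whole")
        twist = geometry.helix_axial_rotation(
            u, v_aligned, "C", layout.tm2_range)
        report["stages"]["tm2"] = {
            "piston_A": piston,
            "axial_rotation_deg": twist,
        }
    except Exception as exc:
        raise PipelineStageError("tm2_geometry", exc) from exc

    # --- ENM / RTB modes on U ------------------------------------------------
    try:
        ca_sel = AtomSelection.ca()
        u_ca = u.select(ca_sel)
        model = enm.ENModel(u_ca.coords, cutoff=config.cutoff, gamma=config.gamma)
        blocks = _blocks_for(config.block_scheme, u, layout, model.n_nodes)
        modes = enm.rtb_modes(model, blocks)
        if config.k_modes > modes.n_modes - modes.n_zero_modes:
            raise ValueError(f"k={config.k_modes} exceeds available nonzero modes")
        groups = layout.group_indices(u)
        characters = []
        nz_vectors = modes.nonzero_modes()[1]
        for m in range(min(3, nz_vectors.shape[1])):
            chars = transition.classify_mode(nz_vectors[:, m], u_ca.coords,
                                             groups, frame)
            characters.append({c.group: {
                "translation": c.translation_fraction,
                "rotation": c.rotation_fraction,
                "deformation": c.deformation_fraction,
                "piston": c.piston_component} for c in chars})
        report["stages"]["enm"] = {
            "n_nodes": model.n_nodes,
            "n_connected_components": model.n_connected_components(),
            "n_zero_modes": modes.n_zero_modes,
            "block_scheme": config.block_scheme,
            "lowest_nonzero_eigenvalues": modes.nonzero_modes()[0][:10].tolist(),
            "mode_character_first3": characters,
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("enm", exc) from exc

    # --- transition projection ----------------------------------------------
    try:
        disp, rmsd_initial, _ = transition.transition_vector(
            u, v, selection=ca_sel, frame_selection=frame_sel)
        per_mode, cumulative = transition.mode_overlap(disp, modes)
        coeffs, rmsd_residual = transition.best_k_fit(disp, modes, config.k_modes)
        vlike = transition.displace_along_modes(u, modes, coeffs)
        # RMSD of the V-like model to the true V, both in U's frame
        v_al_ca = v_aligned.select(ca_sel).coords
        rmsd_vlike = superpose.rmsd(vlike.select(ca_sel).coords, v_al_ca)
        report["stages"]["transition"] = {
            "rmsd_initial_A": rmsd_initial,
            "rmsd_after_k_modes_A": rmsd_residual,
            "k_modes": config.k_modes,
            "per_mode_overlap": per_mode[:config.k_modes].tolist(),
            "cumulative_overlap": cumulative[:config.k_modes].tolist(),
            "best_k_coefficients": coeffs.tolist(),
            "vlike_model_rmsd_to_v_A": rmsd_vlike,
        }
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("transition", exc) from exc

    # --- lattice packing comparison ------------------------------------------
    if config.run_lattice:
        try:
            lat = {}
            for preset in ("tight", "open"):
                fixture = synthetic.make_lattice_fixture(
                    synthetic.lattice_preset(preset))
                lm = lattice.LatticeModel(fixture)
                rep = lattice.lattice_clash_report(
                    lm, synthetic.domain_probe_selection())
                lat[preset] = {"counts": rep.counts, "n_mates": rep.n_mates,
                               "clashing": rep.clashing}
            report["stages"]["lattice"] = lat
        except Exception as exc:
            raise PipelineStageError("lattice", exc) from exc

    # --- outputs --------------------------------------------------------------
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(u, out / "U.pdb")
        write_pdb(v, out / "V.pdb")
        write_pdb(vlike, out / "V_like.pdb")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
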