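# uvnma

Quantitative analysis of the "U"↔"V" quaternary transition in 2:2
membrane receptor–transducer complexes (sensory rhodopsin II bound to
its transducer HtrII is the motivating system): rigid-body and helix
geometry between conformations, Cα elastic-network normal modes with
rotation-translation-block (RTB) reduction, projection of the
conformational change onto low-frequency modes, and crystal-lattice
clash analysis of protruding domains.

The package is for structural biologists who want to test whether a
quaternary rearrangement seen between two crystal forms lies along the
soft collective motions of the complex, and whether a crystal packing
could have suppressed one of the two forms.

## What it computes

* **Rigid-body geometry** — Kabsch superposition with rotation
  axis/angle extraction (`uvnma.superpose`): the rotation R minimizing
  ‖R·x + t − y‖² over paired Cα, its equivalent axis–angle, and the
  residual rigid transform of one subunit after the complexes are put
  in a common frame.
* **Helix geometry** (`uvnma.geometry`): helix-axis fitting (exact for
  ideal helices at any fractional turn count), inter-helix angles,
  piston displacement along the membrane normal, rotation of a helix
  about its own axis (circular mean of per-residue angular
  displacements — decouples exactly from the piston), and
  hydrogen-bond / salt-bridge / clash classification.
* **Elastic network modes** (`uvnma.enm`): the anisotropic network
  model H with per-contact super-elements −γ r̂r̂ᵀ, full
  diagonalization, and the RTB reduction onto rigid
  translations/rotations of residue- or helix-blocks, projected back
  to Cartesian displacement fields.
* **Transition projection** (`uvnma.transition`): overlaps
  |v̂ᵢ·d̂|, cumulative overlap, least-squares best-k-mode
  reconstruction with the exact orthogonal decomposition
  RMSD²initial = RMSD²explained + RMSD²residual, and per-group
  rotation/translation/piston character of any mode.
* **Lattice packing** (`uvnma.lattice`): space-group symmetry-mate
  expansion (operators from gemmi, or user-supplied x,y,z triplets)
  and inter-mate contact scoring for a probe region.
* **Synthetic ground truth** (`uvnma.synthetic`): a parameterized 2:2
  helical-bundle complex with a planted receptor rotation (the U→V
  parameter), TM2 piston and axial twist, optional Gaussian noise, and
  tight/open crystal-packing fixtures — every estimator above has a
  recovery test against known answers.

## Worked example

```python
from uvnma.pipeline import RunConfig, run_u2v_analysis

report = run_u2v_analysis(RunConfig())   # synthetic preset, planted truth
geo = report["stages"]["rigid_body_geometry"]
tm2 = report["stages"]["tm2"]
tr = report["stages"]["transition"]
print(geo["monomer_rotation_deg"], geo["g_helix_angle_deg"])
print(tm2["piston_A"], tm2["axial_rotation_deg"])
print(tr["rmsd_initial_A"], tr["rmsd_after_k_modes_A"])
```

prints (defaults: planted 8.5° receptor rotation, 0.5 Å piston, 19°
TM2 twist, no noise):

```
8.499999999999808 8.499999999999742
0.5000000000000262 19.000000000000057
2.8331165730473646 1.0572840028039554
```

i.e. the planted rigid-body rotation, helix tilt, piston and twist are
recovered to machine precision, the planted transition moves the
complex by 2.83 Å RMSD, and the ten lowest nonzero per-helix RTB
modes of the U form reconstruct it down to ~1 Å.

The numbered drivers under `analysis/` run the same computations as a
narrative: `01_simulate.py` (structures + ground truth),
`02_geometry.py` (recovery vs noise), `03_modes_transition.py`
(mode character, overlap, cutoff scan), `04_lattice.py` (tight vs
open packing), `05_deposited_structures.py` (the same battery on
locally provided PDB depositions; it does not download).

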