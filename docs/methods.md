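# Methods

## The question the pipeline answers

A 2:2 membrane photoreceptor–transducer complex crystallizes in two
quaternary arrangements: a "U" shape with both receptors parallel to
the transducer four-helix core, and a "V" shape in which each receptor
is splayed outward toward the cytoplasmic side.  Activation-related
changes within one crystal form are small (sub-Å piston of the
transducer helix TM2 along the membrane normal, a rotation of TM2
about its own axis), while the U→V difference is a rigid-body rotation
of each receptor of order 10°.  The pipeline quantifies these motions,
asks whether the U→V change lies along the low-frequency normal modes
of an elastic network built on the U form, and checks which crystal
packings sterically tolerate a protruding cytoplasmic domain.

## Synthetic study system

All guarantees are established on a generated complex with planted
ground truth (`uvnma.synthetic`).  The geometry:

* Membrane normal = C2 axis = +z; the intracellular side is +z.
* Ideal α-helices: rise 1.5 Å/residue, twist 100°/residue, Cα radius
  2.3 Å.  These defaults give a consecutive Cα–Cα distance of
  √(1.5² + (2·2.3·sin 50°)²) = 3.8296 Å, the value the tests assert.
  26 residues per transmembrane helix (≈39 Å span).
* Transducer core: TM1/TM2 hairpins of two protomers on a circle of
  radius ~5.1 Å around the axis; receptors: four-helix bundles centred
  16 Å off-axis, the innermost ("G") helix facing TM2.  The second
  protomer is the exact C2 image of the first.
* Planted perturbations, applied to the symmetric U form to make V:
  rigid rotation of each receptor about an in-membrane hinge through
  its extracellular contact point (axis ŷ for receptor A, the C2
  image for receptor B), so the complex opens toward the cytoplasm;
  translation of TM2 of one transducer along +z (piston); rotation of
  that helix about its own axis (twist).  Isotropic Gaussian
  coordinate noise is added after planting, independently to U and V.

Default study conditions: rotation 8.5°, piston 0.5 Å, twist 19°
(values typical of such complexes and used as the planted anchors
throughout), noise 0 for exact-recovery tests and σ = 0.2 Å — a
generous stand-in for coordinate uncertainty at moderate resolution —
for 20-seed bias checks.

What the generator does **not** emulate: side chains and sequence
(recovery tests are Cα-level; contact chemistry is tested on small
hand-built all-atom fixtures), loops connecting helices, helix
irregularity, anisotropic/correlated coordinate error, and the lipid
environment.  Passing tests therefore demonstrate estimator
correctness and the mode-space geometry of rigid quaternary motions,
not robustness to real crystallographic artefacts.

## Estimators

**Superposition** is the Kabsch least-squares proper rotation
(reflection branch excluded, via scipy's `align_vectors`); the
axis/angle comes from the rotation's rotation-vector, angle in
[0, 180]°, with a degeneracy flag near 0°/180°.  Collinear or <3-point
inputs are rejected.  The monomer rotation between two conformations
first superposes the complexes over a frame selection (default: the
TM1 helices of both transducers, the most static part), then reports
the residual rigid transform of the subunit selection.

**Helix axis.**  Plain PCA of a helical Cα cloud is biased by up to
~1° when the helix covers a non-integer number of turns, which is far
too coarse for degree-level angle comparisons.  The axis direction is
therefore refined in two steps: (i) second differences of the Cα
trace lie in planes perpendicular to the axis, so sums of consecutive
cross products give the exact axis of an ideal helix; (ii) when the
chain is long enough, the centroid of a sliding window covering an
integer number of turns (the twist is itself estimated from the
rotation of consecutive second differences) lies exactly on the axis,
and a line through those window centroids combines exactness with
~√w noise averaging.  PCA remains the well-definedness gate
(dominant/second eigenvalue ratio > 2) and the fallback.  The axis
origin is the least-squares (Kåsa) circle centre in the transverse
plane, so the radial scatter `fit_rms` equals the helix radius for an
ideal helix.

**Piston** is the signed projection onto the membrane normal of the
displacement of the chosen helix segment's Cα centroid (default: the
quarter of residues nearest the intracellular side; "whole" uses all
residues).  **Axial rotation** projects each shared Cα onto the plane
normal to the axis of the first conformation and takes the circular
mean of per-residue signed angular displacements; because axial
components are projected out, rotation and piston decouple exactly
for a screw motion (property-tested over θ ∈ [0, 40]°, d ∈ [0, 2] Å).

**Contacts.**  Heavy-atom criteria, in priority order: clash < 2.5 Å;
salt bridge ≤ 4.0 Å between opposite formal-charge side-chain termini
(Lys NZ, Arg NE/NH*, His ND1/NE2 vs Asp OD*, Glu OE*); hydrogen bond
≤ 3.5 Å donor–acceptor with antecedent–donor–acceptor angle ≥ 90°
when hydrogens are absent; otherwise contact ≤ 4.5 Å.  These are
standard structural-biology values and all configurable.  Cα-only
input restricts kinds to clash/contact with a warning.

## Elastic network and RTB

The anisotropic network model connects Cα nodes within a cutoff
(default 10 Å, uniform spring constant γ = 1, unit masses; the
acceptance analyses scan cutoff ∈ {8, 10, 12, 13} Å since low-mode
content is cutoff-sensitive and no single value is canonical).  The
3n×3n Hessian has off-diagonal super-elements −γ r̂r̂ᵀ per contact and
diagonal super-elements equal to minus their row sum, so rigid
translations are annihilated by construction.  Dense `eigh` is used
throughout — the systems here are a few hundred nodes.

Zero modes are eigenvalues below 10⁻⁸·λ_max (all modes, if the whole
spectrum is numerically zero, as for a single rigid block); a
connected free-floating model has exactly six.  Mode signs are fixed
by making each vector's largest-magnitude component positive.

RTB projects the Hessian onto an orthonormal basis of rigid
translations/rotations per block (6 DoF per block; 3 for single-node
and 5 for collinear two-node blocks, handled by SVD rank truncation),
solves the reduced eigenproblem, and maps eigenvectors back to
Cartesian fields, which are orthonormal because the block bases are
orthonormal and disjoint.  Each RTB eigenvalue bounds its full
counterpart from above (variational property; asserted per index).
Block presets: one node per block (reproduces the full model exactly),
uniform b-residue blocks, and one block per helix — the preset used
for the quaternary-motion analyses.

The RTB fidelity check uses a four-helix bundle built as two tightly
packed helix pairs joined by a weak link: on a symmetric bundle the
two lowest nonzero modes are nearly degenerate and a single-vector
overlap between RTB and full modes is ill-posed, whereas the
weak-link geometry isolates the inter-pair hinge mode (spectral gap
≈ 3×) and the helix-block RTB mode matches it with overlap ≈ 0.97.

## Transition projection

The U→V displacement field is the paired-Cα coordinate difference
after superposing V onto U — by default over all paired Cα, which at
the Kabsch optimum makes the displacement exactly orthogonal to the
six rigid-body modes; a transducer-frame option is also exposed.
Overlap of displacement d with mode vᵢ is |vᵢ·d|/‖d‖; cumulative
overlap is the root-sum-square.  The best-k reconstruction uses the k
lowest **nonzero** modes (amplitudes are plain projections in an
orthonormal basis), and RMSD²initial = RMSD²explained + RMSD²residual
holds to round-off.  A finite rigid rotation of angle θ lies in the
per-helix RTB span only up to its quadratic curvature term (relative
size tan(θ/2) ≈ 7% at 8.5°), which is the exact residual floor of a
full-basis fit.

Mode character per rigid group (each receptor, the transducer core)
is the least-squares fit of the mode's restriction to an
infinitesimal rigid field t + ω×(r−c) about the group centroid; with
c the centroid, translation and rotation fields are orthogonal, so
the squared-norm fractions (translation, rotation, internal
deformation) are a true decomposition, and t·n̂ is the piston
component.  On the default complex the third nonzero mode is ~80%
receptor rotation — the U→V-like mode — while the transducer moves as
a near-rigid unit.

For the headline reconstruction the planted rotation is calibrated by
bisection so the whole-complex transition RMSD is exactly 2.9 Å; the
ten lowest nonzero per-helix RTB modes then leave a residual of
0.51–0.82 Å across the cutoff scan (0.51 Å at the scan optimum),
i.e. they explain ≥ 96% of the transition amplitude.  The <35%
residual-ratio guarantee is asserted noiseless and at σ = 0.05 Å over
5 seeds; at σ = 0.2 Å it is structurally unattainable because
isotropic noise is almost entirely orthogonal to any 10-dimensional
mode subspace and inflates the residual by ~√(6σ²·(1−10/3n)).

## Lattice analysis

Space-group operators come from gemmi's table (general positions
including centring: P 21 21 2 → 4, I 21 21 21 → 8, P 64 → 6), or from
a text file of x,y,z triplets; closure and unique inverses are
asserted programmatically.  Mates are generated by applying every
operator plus integer cell translations (search range derived from
the molecule extent) in fractional coordinates and keeping images
with any atom within the expansion radius (default 5 Å) of the base.
The clash report classifies probe-vs-mate contacts with the standard
thresholds; the verdict is "clashing" iff at least one clash-kind
pair exists.  The verdict is invariant under re-expressing the
asymmetric unit through any group operator, and clash counts are
monotone in the expansion radius.

The packing fixtures append a two-helix hairpin (a HAMP-like
cytoplasmic protrusion) to one transducer chain.  The "tight" preset
(P 21 21 2, 46×46×58 Å cell) was constructed so the z→−z screw image
of the next crystal layer lands on the protrusion (13 clashes); the
"open" preset (P 1, 200 Å cell) leaves the molecule isolated.

## Numerical choices and limitations

* Coordinates are Å throughout; PDB output quantizes to 3 decimals
  (round trips are asserted at 5×10⁻⁴ Å after the first write).
* Altloc handling keeps blank/'A' only; first model only.
* Degenerate inputs fail loudly: <3 or collinear points for
  superposition, <5 residues or no dominant direction for an axis,
  zero displacement for overlaps, non-covering block partitions.
* The noise convention for point-set recovery tests is per-atom RMS
  displacement (per-coordinate σ/√3).
* Problem sizes: 312-Cα complexes and 80-node bundles keep every
  dense eigendecomposition and the full test suite in the
  seconds-to-a-minute range.
* Real-structure analyses (script 05) require locally supplied PDB
  files and a user-provided chain map between depositions; the
  package never downloads.  Measured values on real structures will
  additionally depend on which residues are ordered in both models —
  the pairing is always the intersection of resolved residues.
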