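# Methods

## Problem setting

`pdnet` treats fixed-backbone sequence design as a per-position
classification problem: given the backbone geometry around one residue,
predict a probability for each of the 20 natural amino acids.  The local
environment is the residue's N nearest neighbors by Cα–Cα distance — a
fixed-size representation that keeps the network input shape constant.  The
contact-rank coverage metric (`evaluation.contact_rank_coverage`) quantifies
what this choice misses: the fraction of heavy-atom contacts (< 4.5 Å) whose
Cα-distance rank exceeds N are outside the modeled environment.

## Structure curation

Training structures are filtered on: experimental method (x-ray), resolution
(strictly better than 2 Å), maximum chain length (> 50 residues), absence of
nucleic acids and of D-amino acids (detected by residue name, e.g. DAL/DPR —
a chirality computation would be stricter and is a possible extension), plus
a user-supplied exclusion list (e.g. membrane proteins).  The first failing
rule is reported.  Files without header metadata (synthetic fixtures) bypass
the header-dependent rules by default (`FilterConfig.keep_missing_method`).
Identical subunits of an oligomer are collapsed to the first chain by id;
near-duplicates use edit-distance identity over the longer sequence.
HETATM content (water, ions, ligands) is dropped at parse time.  Altloc
policy: the 'A' or blank conformer is kept; residues with only other altlocs
fall back to the highest-occupancy one — downstream occupancy screening
discards those clusters during training extraction anyway.

Cluster extraction drops, with a logged reason, any cluster whose member
residues have missing backbone atoms or any atom with occupancy < 1
(training mode only; prediction takes the structure as given).  Chain
termini remain eligible targets: their undefined dihedrals use the sentinel
encoding.  Distance ties in neighbor ranking break by (chain id, residue
number), making extraction deterministic.

## Geometry

* **Dihedrals** follow the IUPAC sign convention. φ_i = C(i−1)–N–Cα–C,
  ψ_i = N–Cα–C–N(i+1), and ω_i describes the peptide bond *preceding*
  residue i.  Angles across a terminus or a chain break (peptide C–N
  distance > 2.0 Å) are undefined and encode as (cos, sin) = (0, 0) — a
  point off the unit circle a model can recognize, while keeping the feature
  vector length fixed.  Note that the IUPAC torsion is invariant under
  reversing the four points; its sign flips under mirror reflection.
* **Canonical frame**: Cα at the origin, N on −x, C in z = 0.  The plane
  condition leaves a two-fold ambiguity, resolved by requiring the
  transformed C to have y > 0; the frame is always a proper rotation.
* **Hydrogen bonds** use the DSSP electrostatic model,
  E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol, bond if
  E < −0.5.  The amide H is reconstructed 1.0 Å from N opposite the bisector
  of the C(i−1)–N and Cα–N directions; chain-start residues and prolines
  never donate.  Pairs closer than 2 in sequence never bond; a 9 Å Cα
  prefilter bounds the search.
* **Secondary structure** is a three-state assignment built from the two
  primitives above: helix = a run of ≥ 3 residues with φ ∈ (−100, −30) and
  ψ ∈ (−80, −5), or residues spanned by an i→i+4 backbone H-bond; sheet =
  extended dihedrals (φ ∈ (−180, −40), ψ ∈ (60, 180] ∪ (−180, −150)) plus at
  least one backbone H-bond to a residue > 2 apart in sequence; everything
  else, including termini, is loop.  This intentionally reproduces only the
  three-state granularity, not any particular assignment program: in an
  ideal antiparallel ladder, for example, only the H-bonded alternate
  residues are labeled sheet.
* **Backbone SASA**: Shrake–Rupley, 960 Fibonacci sphere points per atom,
  probe 1.4 Å, radii N 1.65 / C and Cα 1.76 / O 1.40 Å (Naccess-compatible),
  computed over the whole structure with every sidechain removed from both
  the measured and the occluding sets.  Values are raw Å², not normalized.
  Because the sphere-point set is fixed in space, the structure is first
  rotated into a deterministic principal-axes orientation; this makes SASA —
  and hence all 31 pair features — exactly invariant under rigid motion
  (verified to ~1e-14).  Under mirror reflection (an improper motion) SASA
  agrees only to sampling noise, about 2% at 960 points.

## Network and training

Hidden-layer sizes are configuration, not contract (defaults: probability
subnet 2×64 ReLU → 20 softmax; weight subnet 2×32 ReLU → 1 softplus; head
2×256 ReLU → 20 softmax).  Softplus keeps the per-neighbor weight
nonnegative, so it reads as a relevance measure; a linear output is
available via `ModelConfig.weight_activation`.  Initialization is seeded
He-uniform.  Inputs are z-scored per feature with statistics from the
training set, stored in the model file (raw SASA spans ~0–200 Å² while
cos/sin features span [−1, 1]; without scaling, SGD at the default learning
rate is unstable).

The loss is categorical cross-entropy with multiplicative sample weights
W_i = N_max/N_i (normalized by the batch weight sum), optimized by
mini-batch SGD with Nesterov momentum (defaults 0.01 / 0.9).  Full-scale
defaults (batch 40 000, 1000 epochs) live in `TrainConfig`; the test suite
and the acceptance script use desk-scale settings (batch 256, ≤ 200 epochs,
2000-cluster datasets) — these sizes are the package's own choice of test
problem, sufficient for every property being checked.  Training is
deterministic given the seed, up to floating-point reduction order.  NaN/inf
loss aborts with a diagnostic.

Ties in argmax and top-K selection break by alphabetical amino-acid order
(the label order is `ACDEFGHIKLMNPQRSTVWY` everywhere), so every metric and
restraint set is deterministic.  Per-class recall/precision with an empty
denominator is reported as missing, never as zero, to avoid biasing
per-class averages.

## Synthetic data: what it does and does not show

`fixtures.build_ideal_backbone` places N/Cα/C/O sequentially from internal
coordinates (bond lengths N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å;
angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°, Cα–C–O 120.5°),
recovering the specified torsions to < 1e-6 degrees.

`fixtures.learnable_dataset` labels each cluster by its generating backbone
class — helix (−57, −47), strand (−120, 120), loop-like (60, 60), with
Gaussian coordinate noise σ = 0.05 Å — so the Bayes-optimal accuracy is 1 by
construction.  Passing the learnability check shows the architecture,
gradients, optimizer and data plumbing work end to end; it says nothing
about accuracy on real proteins, where the residue identity is only weakly
determined by backbone geometry (sequence recovery rates for real structures
are far below 1 and require corpus-scale training).

`fixtures.imbalanced_dataset` (95:5) is designed so that the class-weighting
effect is identifiable: per-chain (φ, ψ) offsets ~ N(0, 15°) are quantized
to a 10° grid and the class centers sit 20° apart, with no coordinate noise.
Chains in one grid cell therefore have identical features, mixed-label cells
make the training set itself Bayes-limited (no model can memorize past the
cell-wise label mixture), and class weighting flips the cell-wise vote
toward the minority class exactly where 19·N_minority > N_majority.  With
continuous, per-chain-unique features the effect is masked: the network
memorizes every chain and both variants saturate at recall 1.  Other aspects
of real data the fixtures do not emulate: sidechain packing, real
loop diversity, crystal contacts, sequence-dependent backbone geometry.

## Numerical choices and degenerate inputs

Collinear atom triples raise a geometry error (dihedral, canonical frame).
Coincident Cα positions raise a feature error.  ±180° torsions are mapped to
+180 (half-open range (−180, 180]).  The standardization scale is floored at
1e-6 to protect constant features.  H-bond energies are skipped when any
interatomic distance is < 0.5 Å (clash).  Dataset archives (HDF5) and model
files (npz) carry a feature-order version (`pairfeat-v1`); mixing versions
is an error.  Archives are written with HDF5 timestamps disabled, so
identical content produces identical bytes.

## Known limitations

* Three-state secondary structure by simple rules; no exact agreement with
  Stride/DSSP binaries is attempted, and features computed here will differ
  slightly from pipelines that used those programs.
* D-amino-acid detection is nominal (residue names), not geometric.
* mmCIF is not parsed; multi-model (NMR-style) files use the first model
  only, consistent with the x-ray-only filter.
* PSSM generation and conversion are out of scope; `profile_rmse` compares
  already-converted probability matrices.
* The package emits resfiles but does not run Rosetta; restraint quality can
  only be assessed via `max_possible_identity` (the ceiling the restraints
  impose) without an external design run.
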