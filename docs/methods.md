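# Methods

## The prediction problem

An antibody variable fragment (Fv) is a pair of protein domains — the heavy-
and light-chain variable domains — whose antigen-binding surface is formed by
six hypervariable loops (CDRs), of which CDR H3 is the most variable and the
hardest to model. `scabkit` implements a sequence-only predictor of Fv
geometry that covers both the backbone and the side chains. The structure is
represented, trRosetta-style, by nine per-record quantities:

* four **pairwise geometries** between residues *i* and *j*: the Cβ–Cβ
  distance *d*, the dihedrals ω (CAᵢ–CBᵢ–CBⱼ–CAⱼ) and θ (Nᵢ–CAᵢ–CBᵢ–CBⱼ),
  and the planar angle φ (CAᵢ–CBᵢ–CBⱼ);
* five **side-chain dihedrals** χ₁…χ₅ per residue (χ₅ exists only for
  arginine).

The network emits a 36-bin categorical distribution for each quantity.
Glycine lacks Cβ, so ω/θ/φ are undefined (masked) for any pair touching a
glycine while *d* falls back to CA; χ angles are masked for glycine and
alanine (no Cγ) and proline (non-rotameric), and wherever a constitutive
atom is missing from the coordinates. Masked entries never contribute to
losses or scores.

## Discretization

| output | range | bins | width |
|---|---|---|---|
| d | 0–18 Å | 36 | 0.5 Å |
| ω, θ, χ₂–χ₅ | −180°–180° (periodic) | 36 | 10° |
| φ | 0°–180° | 36 | 5° |
| χ₁ | periodic | 36 | 30×6° + 6×30° |

χ₁ is strongly rotameric, so it uses non-uniform bins: three clusters of ten
fine 6° bins around the wells at −60°, 60° and 180°, separated by six coarse
30° bins. Requiring each well to sit at a fine-bin *center* forces every
edge to lie at 3 mod 6 degrees; the layout therefore lives on the wrapped
domain [−177°, 183°), with the bin (177°, 183°) centered exactly on 180°
and straddling the ±180° cut. Bins are half-open [lo, hi); distances ≥ 18 Å
clip into the last bin; periodic values are wrapped into the domain first
(−180° and +180° are the same bin). The edge lists exported by
`discretize.export_edges_json` are the single source of truth.

## Architecture

Input is the concatenated heavy-then-light sequence, one-hot encoded (L×20)
plus a chain-break delimiter column that is 1 only at the last heavy residue
(L×21 total). Two coupled modules follow:

* **Inter-residue module** — a 1×1 projection to 32 channels, a 3-block 1D
  ResNet (kernel 17), redundant pairwise expansion to L×L×64
  (cell (i,j) = concat(hᵢ, hⱼ)), and a 25-block 2D ResNet (kernel 5×5).
* **Rotamer module** — the pairwise tensor is pooled back to sequential form
  by concatenating its row means and column means (L×128), passed through
  one transformer encoder block (8 heads, feed-forward 512) whose
  self-attention is captured for interpretation, then a 1D convolution
  (kernel 5). Five conditional heads predict χ₁…χ₅; head *k* receives the
  distributions of χ₁…χ₋₁ (ground-truth one-hots under teacher forcing
  during training, predictions at inference).
* **Feedback** — the five χ distributions of both partners (2×5×36 = 360
  channels) are tiled onto the pairwise features before the four final 2D
  output convolutions, so side-chain context informs the pairwise outputs.
  During training the teacher-forced distributions are fed back, which keeps
  the pairwise heads' inputs consistent between the pretraining and joint
  phases.

d and ω are symmetric quantities; their logits are averaged with their
transposes before the softmax. A **control variant** drops the pairwise
stack entirely: the rotamer module runs directly on the L×32 1D-ResNet
output and only χ distributions are produced. Residual blocks are
pre-activation (norm → ReLU → conv); the default normalization is
per-channel over space (instance norm — the batch-size-1 form of batch
normalization, which this architecture family uses). No positional
embedding is used; the convolutions carry order information.

The network and its training run on a small reverse-mode automatic-
differentiation engine over NumPy arrays (`scabkit.nn`): a tape of
vector-Jacobian closures with convolutions implemented as shifted BLAS
matmuls. Every backward pass is verified against numerical differentiation
in the test suite, and the convolution forward against
`scipy.signal.correlate2d`.

## Losses and training

Each output contributes a categorical cross-entropy over its unmasked
entries (ignore label −1). The four pairwise terms are summed with equal
weight. The five rotamer terms are scaled by inverse observation frequency:
w₁ = 1 and wₖ = count(valid χ₁)/count(valid χₖ), so rarely observed
dihedrals (χ₅ above all) are not drowned out; a χ level with zero
observations is excluded with a warning rather than given an arbitrary
weight.

Training uses Adam (lr 10⁻³ by default), batch size 1, and seeded 95/5
training/validation splits per ensemble member (5 members by default,
varying both the split and the weight initialization). A run is
deterministic given its seed. `split=1.0` disables validation and is used
for parameter-recovery experiments; any other split that leaves an empty
side errors.

The schedule mirrors the method's staged training: the inter-residue module
is first trained alone (pairwise losses only), then both modules train in
parallel on the joint loss. In the joint phase the two branches may use
different Adam rates — the inter-residue parameters a small rate, the
rotamer module a normal one. This mattered in practice: the weighted
rotamer loss is an order of magnitude larger than the pairwise loss, and a
single shared rate either stalls the pairwise branch (rate too low) or
destroys its memorized structure (rate too high). Optional global
gradient-norm clipping stabilizes the joint phase.

The shipped desk-scale recipe (`RunConfig.desk_overfit`) is: pairwise
pretraining at lr 10⁻² until the pairwise outputs reach the target argmax
accuracy (capped at 150 epochs), then joint training with the rotamer
branch at 3×10⁻³ and the trunk at 10⁻⁴, clip norm 1.0, early-stopping when
all nine outputs reach the target on the training records. With the reduced
configuration (2 1D blocks, 4 2D blocks, 16 sequence channels, 1×1 output
heads) and three L=60 synthetic records this reaches ≥ 99% argmax accuracy
on all nine outputs in roughly 200–230 epochs (~4 minutes on one CPU).

## Energies, decoy discrimination, constraints

Ensemble-averaged distributions become energies E = −log max(p, 10⁻⁴); the
probability floor keeps empty bins finite and is configurable. Energies are
knotted at bin centers and interpolated with cubic splines — periodic for
dihedral outputs (continuous across ±180°), natural for distance and the
planar angle. Cubic interpolation of −log p can overshoot below the minimum
table energy between knots; tests bound this overshoot at 2 nats for
floor-level tables. Outside the knot range, values clamp to the boundary
knot.

A structure's score is the sum of spline energies at its measured
geometries over all valid pairwise terms (the self-distance diagonal is
skipped — it carries no signal) plus all valid χ terms. `scope="h3_only"`
restricts pair terms to pairs touching CDR H3 and χ terms to H3 residues,
matching loop-resolved energy funnels. Decoys are ranked by ascending
score with stable ties; reported are the CDR-H3 RMSD of the best-scoring
decoy (top-1) and the minimum RMSD among the five best (top-5). CDR-H3
RMSD superposes decoy on native over framework N/CA/C atoms (Kabsch, no
refit) and measures backbone heavy atoms (N/CA/C/O) of the loop.

The Rosetta constraint writer emits one SPLINE line per valid term —
`AtomPair` for d (CB, or CA for glycine), `Dihedral` for ω/θ/χₖ, `Angle`
for φ — with inline `x_axis`/`y_axis` histograms (x at bin centers, in
Ångströms or radians as Rosetta expects; y = −log p). d and ω are written
once per pair (i < j); the direction-dependent θ and φ for both orderings.
Pose numbering is 1-based over the concatenated heavy-then-light chains.
The writer targets the ConstraintSetMover → PackRotamersMover protocol
(ref2015, constraint weight 1.0, `-ex1 -ex2`); the emitted grammar subset
is round-trip parsed by `scoring.parse_rosetta_constraints`, and executing
Rosetta itself is outside this package's scope.

## Evaluation statistics

* **Relative side-chain SASA** — Shrake–Rupley (probe 1.4 Å, 100 points per
  atom, via Bio.PDB) summed over side-chain heavy atoms (everything except
  N/CA/C/O), divided by a per-residue-type reference maximum. The default
  reference is computed once from isolated ideal-geometry residues, so an
  unoccluded side chain scores ≈ 1 by construction; the Tien et al. (2013)
  theoretical column is embedded and selectable for comparison with
  published normalizations. Residues with missing side-chain atoms are
  flagged partial.
* **SASA-stratified side-chain RMSD** — per-residue side-chain heavy-atom
  RMSD after one global framework alignment, averaged within SASA bins
  computed on the native; empty bins are NaN, never zero, and out-of-range
  values are excluded rather than clipped.
* **Cosine dihedral error** — 1 − cos(χ_pred − χ_native) per valid dihedral,
  averaged over χ₁–χ₄ per residue (χ₅ omitted as sparsely observed); a
  per-χ-class reduction is also available.
* **Framework-aligned Cβ deviation** — |Cβ_pred − Cβ_native| per residue
  (CA for glycine) after Kabsch superposition on framework backbone atoms.
* **Attention anchors** — a position's score is the mean attention it
  receives over heads and query positions (column mean of the head-stacked
  attention), normalized so the maximum position is 100%; anchors are the
  top-k positions with ties resolved toward the lower index. Attention is
  interpreted per model, never averaged across ensemble members. The
  aggregation direction (received vs. emitted attention) is a documented
  choice and swappable.

## Synthetic fixtures

All tests run on generated Fv-like records, not real antibodies. The
generator samples sequences from an antibody-like residue composition,
builds backbones from ideal internal coordinates (NeRF) with extended-strand
φ/ψ for frameworks and varied torsions for a CDR-H3-like segment, places
side chains at χ values drawn from the canonical wells {−60°, 60°, 180°}
(+8° Gaussian jitter) with ideal bond lengths and angles, and assigns
Chothia-style numbering (the H3-like segment occupies 95–102, with
insertion codes at position 100 for longer loops). Because the same
topology table drives both placement and χ extraction, the generator's
draws are recovered to ≲10⁻¹² degrees — the closure property all
parameter-recovery experiments rest on. Default fixture sizes are 35+25
residues with a 7-residue H3-like segment.

Decoy ensembles perturb backbone φ/ψ with Gaussian noise (25° by default)
— restricted to the H3 segment for `h3_only`, where the loop is rebuilt in
place anchored at its N-terminal side, leaving a chain break at the far end
as loop-sampling decoys do, so framework atoms stay bit-identical — and
perturb every χ regardless of region. Decoy 0 is always the unperturbed
native. Proline's ring is placed at fixed puckered torsions without exact
ring closure, and decoy carbonyl oxygens are not re-oriented to the
perturbed ψ; both are deliberate idealizations of fixtures whose consumers
read torsions and distances, not physical energies.

What passing on these fixtures does *not* show: performance on real
antibodies (real loop conformational ensembles, crystal artifacts, missing
density, non-ideal covalent geometry) and the published benchmark numbers,
which require the full training corpus and external decoy sets.

## Numerical and design notes

* Dihedrals follow the IUPAC sign convention (clockwise positive viewed
  along the central bond), range [−180°, 180°); the torsion formula is
  verified against an independently derived projection oracle to 10⁻⁶
  degrees on 10⁴ random quadruples.
* Masked values carry NaN; binning NaN raises — callers must mask first.
* Symmetric terminal dihedrals (ASP χ₂, GLU χ₃, PHE/TYR χ₂, ARG χ₅) are
  reported raw, without 180° folding, so binned labels reflect the literal
  dihedral; folding is left to evaluation-time configuration.
* Sequence identity for dataset filtering is computed on shared numbered
  positions (matches/shared), which is appropriate for numbered antibody
  records; greedy clustering keeps the first representative.
* Altloc resolution takes the highest occupancy (ties → first in file);
  multi-model PDB files use the first model.
* Checkpoints embed the model configuration and a hash of the bin-edge
  JSON; loading refuses on hash mismatch so energies are never computed
  against a different discretization.
* The ensemble average of normalized distributions is not renormalized —
  it is normalized to float tolerance already, and skipping the division
  keeps a single-member ensemble bit-identical to a plain forward pass.
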