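# scabkit

Sequence-based prediction of antibody Fv geometry, side chains included.

Antibody engineering lives and dies by the conformation of the six
complementarity-determining loops, above all CDR H3, and by the side chains
those loops present to the antigen. `scabkit` implements a deep network that
takes only the paired heavy/light variable-domain sequence and predicts, as
36-bin probability distributions:

* the inter-residue geometries — Cβ distance *d*, orientation dihedrals
  ω and θ, planar angle φ (an L×L×36 map each), and
* the side-chain dihedrals χ₁…χ₅, predicted **conditionally** (each χₖ head
  is conditioned on χ₁…χₖ₋₁), with the predicted rotamer distributions fed
  back into the pairwise branch.

Around the network the package provides the downstream machinery a
structure-prediction pipeline needs: conversion of distributions to
−log-probability energies with cyclic-spline interpolation, decoy scoring
and top-1/top-5 ranking against CDR-H3 RMSD, Rosetta spline-constraint file
emission, self-attention anchor-position analysis, evaluation statistics
(relative side-chain SASA, cosine dihedral error, framework-aligned Cβ
deviation), dataset curation utilities (resolution/identity filtering,
positional entropy), and a deterministic synthetic Fv generator so the whole
stack is testable on one CPU without downloads. The model, losses and Adam
optimizer run on the package's own NumPy reverse-mode autodiff engine
(`scabkit.nn`); every gradient is verified against numerical
differentiation in the test suite.

It is aimed at computational antibody engineers and method developers:
the library is the primary interface, with a thin `scabkit` CLI
(`inspect`, `geometry`, `synth`, `predict`, `score-decoys`,
`make-constraints`, `bin-edges`) for shell use.

## Worked example

Train a small model to memorize two synthetic Fv records, then use its
energies to pick the native out of a perturbed decoy ensemble:

```python
from scabkit import make_fv, make_decoys
from scabkit.synthetic import SyntheticSpec
from scabkit.network import ModelConfig, ensemble_predict
from scabkit.training import RunConfig, train, argmax_accuracy, _prepare
from scabkit.scoring import to_energies, rank_decoys

records = [make_fv(SyntheticSpec(heavy_len=16, light_len=8, h3_len=5, seed=s))
           for s in (7, 8)]
config = ModelConfig(res1d_blocks=1, res2d_blocks=2, seq_channels=8,
                     attn_ff_dim=64, head_kernel=1)
run = RunConfig(epochs=200, lr=1e-2, phase1_epochs=100, rotamer_lr=3e-3,
                trunk_lr=1e-4, clip_norm=1.0, seed=5, n_models=1, split=1.0)
result = train(records, config, run)
print(f"final training loss: {result.curves[0][-1]['train']:.4f} nats")

encs, labels = _prepare(records)
acc = argmax_accuracy(result.models[0].predict(encs[0]), labels[0])
print("argmax-bin accuracy:", {k: round(v, 3) for k, v in acc.items()})

native = records[0]
energies = to_energies(ensemble_predict(result.models, encs[0]))
decoys, rmsds = make_decoys(native, n=20, noise_deg=25.0, seed=11,
                            region="h3_only")
ranking = rank_decoys(energies, decoys, native, scope="h3_only")
print(f"top-1 RMSD: {ranking.top1_rmsd:.3f} A   "
      f"top-5 RMSD: {ranking.top5_rmsd:.3f} A")
print(f"best-scoring decoy: {ranking.names[ranking.order[0]]}")
```

Output (≈15 s on one CPU):

```
final training loss: 0.0075 nats
argmax-bin accuracy: {'d': 1.0, 'omega': 1.0, 'theta': 1.0, 'phi': 1.0,
 'chi1': 1.0, 'chi2': 1.0, 'chi3': 1.0, 'chi4': 1.0, 'chi5': 1.0}
top-1 RMSD: 0.000 A   top-5 RMSD: 0.000 A
best-scoring decoy: synth7_decoy0
```

Reading this: the loss is the sum of nine masked cross-entropies (a uniform
predictor would sit at ~32 nats here), so 0.0075 means the model has
memorized all nine geometry labelings of its two training records; the
decoy test then shows that the energies carved from its distributions rank
the unperturbed native (decoy 0, RMSD 0 Å by construction) above all 19
torsion-perturbed decoys when scoring is restricted to terms touching the
CDR-H3-like loop.

The model card, bin definitions, loss weighting, training schedule and
evaluation statistics are described in [docs/methods.md](docs/methods.md).

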