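"""Losses, frequency-based chi weighting, the training loop, and dataset
curation diagnostics (resolution/identity filtering, positional entropy).

The loss is categorical cross-entropy per output; the four pairwise terms are
summed with equal weight, the five rotamer terms are scaled by the inverse
observation frequency of each chi angle (chi_1 is the reference), and entries
whose constitutive atoms are missing carry the ignore label -1 and contribute
nothing.  Training uses Adam (lr 1e-3) with batch size 1 on seeded
training/validation splits; the inter-residue branch can be pretrained alone
before the joint phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .antibody_io import FvRecord, encode_sequence
from .discretize import (ALL_OUTPUTS, CHI_OUTPUTS, PAIR_OUTPUTS, LabelTensors,
                         discretize_labels)
from .geometry import compute_geometry
from .network import (DeepSCAbModel, ForwardResult, ModelConfig,
                      PredictionSet)
from .nn import core
from .nn.core import Adam, Tensor


@dataclass
class ChiWeights:
    """Inverse-frequency loss weights w_1..w_5 (w_1 = 1; NaN = head excluded)."""

    w: np.ndarray  # (5,)

    @classmethod
    def uniform(cls) -> "ChiWeights":
        return cls(w=np.ones(5))

    def defined(self, k: int) -> bool:
        return not np.isnan(self.w[k])


def chi_class_weights(labels: list[LabelTensors]) -> ChiWeights:
    """w_k = count(valid chi_1) / count(valid chi_k) over a label set.

    A chi level never observed gets NaN and is excluded from the loss (with a
    warning) rather than receiving an arbitrary weight.
    """
    if not labels:
        raise ValueError("empty dataset")
    counts = np.zeros(5)
    for lab in labels:
        counts += (lab.chi >= 0).sum(axis=0)
    w = np.full(5, np.nan)
    for k in range(5):
        if counts[k] > 0:
            w[k] = counts[0] / counts[k]
    if np.isnan(w).any():
        missing = [f"chi{k + 1}" for k in range(5) if np.isnan(w[k])]
        warnings.warn(f"no observations for {missing}; heads excluded from loss")
    return ChiWeights(w=w)


@dataclass
class LossBreakdown:
    """Cross-entropy per output plus the method's weighted aggregates."""

    per_output: dict[str, float]
    pairwise_total: float
    rotamer_total: float
    total: float


def _ce_from_probs(p: np.ndarray, labels: np.ndarray) -> float:
    flat_p = p.reshape(-1, p.shape[-1])
    flat_l = labels.reshape(-1)
    ok = flat_l >= 0
    if not ok.any():
        return 0.0
    picked = flat_p[np.nonzero(ok)[0], flat_l[ok]]
    return float(-np.log(np.maximum(picked, 1e-300)).mean())


def loss(pred: PredictionSet | ForwardResult, labels: LabelTensors,
         weights: ChiWeights | None = None) -> LossBreakdown:
    """Loss breakdown of a prediction against binned labels.

    Accepts either probabilities (PredictionSet) or a ForwardResult; outputs
    the per-output mean CE over unmasked entries, the equally weighted
    pairwise sum, the chi-weighted rotamer sum, and their total.
    """
    weights = weights or ChiWeights.uniform()
    pset = pred.prediction if isinstance(pred, ForwardResult) else pred
    per: dict[str, float] = {}
    for name in ALL_OUTPUTS:
        if name in PAIR_OUTPUTS and pset.p_d is None:
            continue
        per[name] = _ce_from_probs(pset.output(name), labels.output(name))
    pairwise = sum(per.get(n, 0.0) for n in PAIR_OUTPUTS)
    rotamer = 0.0
    for k in range(5):
        name = f"chi{k + 1}"
        if weights.defined(k):
            rotamer += float(weights.w[k]) * per[name]
    total = pairwise + rotamer
    return LossBreakdown(per_output=per, pairwise_total=pairwise,
                         rotamer_total=rotamer, total=total)


def loss_tensor(fwd: ForwardResult, labels: LabelTensors,
                weights: ChiWeights, include_pairwise: bool = True,
                include_rotamer: bool = True) -> Tensor:
    """Differentiable total loss used by the training loop."""
    terms: list[Tensor] = []
    if include_pairwise and "d" in fwd.logits:
        for name in PAIR_OUTPUTS:
            lg = core.reshape(fwd.logits[name], (-1, fwd.logits[name].shape[-1]))
            terms.append(core.masked_cross_entropy(lg, labels.output(name)))
    if include_rotamer:
        for k in range(5):
            if not weights.defined(k):
                continue
            name = f"chi{k + 1}"
            ce = core.masked_cross_entropy(fwd.logits[name], labels.output(name))
            terms.append(core.scale(ce, float(weights.w[k])))
    total = terms[0]
    for t in terms[1:]:
        total = core.add(total, t)
    return total


def argmax_accuracy(pred: PredictionSet, labels: LabelTensors) -> dict[str, float]:
    """Fraction of unmasked entries whose argmax bin equals the label."""
    out = {}
    for name in ALL_OUTPUTS:
        if name in PAIR_OUTPUTS and pred.p_d is None:
            continue
        p = pred.output(name)
        lab = labels.output(name)
        ok = lab >= 0
        if not ok.any():
            out[name] = np.nan
            continue
        out[name] = float((p.argmax(-1)[ok] == lab[ok]).mean())
    return out


# ---------------------------------------------------------------------------
# training loop

@dataclass
class RunConfig:
    """Training-run parameters.

    The schedule mirrors the method's staged training: `phase1_epochs` train
    the inter-residue branch alone (pairwise losses only, rate `lr`), then
    the two modules train in parallel on the joint loss.  In the joint phase
    the inter-residue parameters (ResNets and pairwise output heads) may use
    a reduced rate `trunk_lr` while the rotamer module (transformer, rotamer
    convolution, chi heads) uses `rotamer_lr` — useful after pretraining,
    when the pairwise branch should be refined gently while the rotamer
    branch is still learning.  With phase1_epochs=0 and no per-branch rates
    this is plain single-rate joint training.
    """

    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0
    n_models: int = 5
    split: float = 0.95
    phase1_epochs: int = 0               # inter-residue pretraining epochs
    rotamer_lr: float | None = None      # joint phase, rotamer module
    trunk_lr: float | None = None        # joint phase, inter-residue module
    clip_norm: float | None = None       # global gradient-norm clip
    target_accuracy: float | None = None  # early stop once reached on train set
    check_every: int = 10

    @classmethod
    def desk_overfit(cls, epochs: int = 300, seed: int = 0) -> "RunConfig":
        """Recipe for CPU-scale parameter-recovery runs: fast pairwise
        memorization, then a dual-rate joint phase that trains the rotamer
        module while gently refining the memorized trunk."""
        return cls(epochs=epochs, lr=1e-2,
                   phase1_epochs=min(150, epochs // 2),
                   rotamer_lr=3e-3, trunk_lr=1e-4, clip_norm=1.0,
                   seed=seed, n_models=1, split=1.0,
                   target_accuracy=0.95, check_every=10)


@dataclass
class TrainResult:
    models: list[DeepSCAbModel]
    curves: list[list[dict]]        # per model, per epoch {train, val}
    weights: ChiWeights
    labels: list[LabelTensors] = field(repr=False, default_factory=list)


def _prepare(records: list[FvRecord]):
    encs = [encode_sequence(r) for r in records]
    labels = [discretize_labels(compute_geometry(r)) for r in records]
    return encs, labels


def train(records: list[FvRecord], config: ModelConfig,
          run: RunConfig | None = None) -> TrainResult:
    """Train an ensemble of `run.n_models` models on independent seeded splits.

    With ``split == 1.0`` all records train and validation is skipped (used
    by overfitting/parameter-recovery experiments); otherwise an empty
    validation split is an error.  Training is deterministic given
    ``run.seed``.  ``phase1_epochs`` pretrains the inter-residue branch alone
    (pairwise losses only) before the joint phase; the control variant trains
    on rotamer losses only throughout.
    """
    if not records:
        raise ValueError("empty dataset")
    run = run or RunConfig()
    encs, labels = _prepare(records)
    weights = chi_class_weights(labels)

    models: list[DeepSCAbModel] = []
    curves: list[list[dict]] = []
    for mi in range(run.n_models):
        mseed = (run.seed * 1009 + mi * 101) % (2 ** 31 - 1)
        rng = np.random.default_rng(mseed)
        order = rng.permutation(len(records))
        n_train = int(round(run.split * len(records)))
        if run.split >= 1.0:
            train_idx, val_idx = list(order), []
        else:
            if n_train < 1 or n_train >= len(records):
                raise ValueError(
                    f"split {run.split} leaves an empty train or validation "
                    f"set for {len(records)} records")
            train_idx, val_idx = list(order[:n_train]), list(order[n_train:])
        model = DeepSCAbModel(config, seed=mseed + 1)
        p1 = run.phase1_epochs if config.variant == "full" else 0
        pretraining = p1 > 0
        in_phase = 0

        rot_prefixes = ("encoder", "rot_conv", "chi_heads")

        def make_opts(joint: bool):
            if not joint:
                return [Adam(model.parameters(), lr=run.lr,
                             clip_norm=run.clip_norm)]
            rot, trunk = [], []
            for name, p in model.named_parameters():
                (rot if name.startswith(rot_prefixes) else trunk).append(p)
            return [Adam(rot, lr=run.rotamer_lr or run.lr,
                         clip_norm=run.clip_norm),
                    Adam(trunk, lr=run.trunk_lr or run.lr,
                         clip_norm=run.clip_norm)]

        opts = make_opts(joint=not pretraining)

        def worst_accuracy(names):
            vals = []
            for ri in train_idx:
                acc = argmax_accuracy(model.predict(encs[ri]), labels[ri])
                vals.append(min(acc[n] for n in names if not np.isnan(acc[n])))
            return min(vals)

        curve: list[dict] = []
        for epoch in range(run.epochs):
            perm = rng.permutation(train_idx)
            tr_loss = 0.0
            for ri in perm:
                fwd = model.forward(encs[ri], teacher_chi=labels[ri])
                lt = loss_tensor(fwd, labels[ri], weights,
                                 include_pairwise=config.variant == "full",
                                 include_rotamer=not pretraining)
                for o in opts:
                    o.zero_grad()
                lt.backward()
                for o in opts:
                    o.step()
                tr_loss += float(lt.data)
            val_loss = np.nan
            if val_idx:
                val_loss = float(np.mean(
                    [loss(model.predict(encs[vi]), labels[vi], weights).total
                     for vi in val_idx]))
            curve.append({"train": tr_loss / len(train_idx), "val": val_loss})
            in_phase += 1

            check = (run.target_accuracy is not None
                     and in_phase % run.check_every == 0)
            if pretraining:
                # advance at the cap or once pairwise has reached the target
                if in_phase >= p1 or (
                        check and worst_accuracy(PAIR_OUTPUTS)
                        >= run.target_accuracy):
                    pretraining = False
                    in_phase = 0
                    opts = make_opts(joint=True)
            elif check:
                names = (ALL_OUTPUTS if config.variant == "full"
                         else CHI_OUTPUTS)
                if worst_accuracy(names) >= run.target_accuracy:
                    break
        models.append(model)
        curves.append(curve)
    return TrainResult(models=models, curves=curves, weights=weights,
                       labels=labels)


# ---------------------------------------------------------------------------
# dataset curation diagnostics

def positional_entropy(numbered_seqs: list[dict]) -> dict:
    """Shannon entropy (bits) of the residue distribution at each numbered
    position; positions absent from a sequence are skipped for that sequence."""
    if not numbered_seqs:
        raise ValueError("need at least one sequence")
    from collections import Counter, defaultdict
    col: dict = defaultdict(Counter)
    for seq in numbered_seqs:
        for pos, aa in seq.items():
            col[pos][aa] += 1
    out = {}
    for pos, counter in col.items():
        p = np.array(list(counter.values()), dtype=float)
        p /= p.sum()
        out[pos] = float(-(p * np.log2(p)).sum())
    return out


def sequence_identity(a: FvRecord, b: FvRecord) -> float:
    """Fraction of matching residues over shared numbered positions."""
    amap = {n: aa for n, aa in zip(a.numbering, a.sequence)}
    bmap = {n: aa for n, aa in zip(b.numbering, b.sequence)}
    shared = set(amap) & set(bmap)
    if not shared:
        return 0.0
    match = sum(amap[k] == bmap[k] for k in shared)
    return match / len(shared)


def filter_dataset(records: list[FvRecord], max_resolution: float = 3.0,
                   identity_cutoff: float | None = None,
                   exclusion_ids: tuple = ()) -> list[FvRecord]:
    """Resolution / identity / exclusion filtering of a record set.

    Keeps records at `max_resolution` A or better, drops excluded ids, and
    greedily clusters by numbered-position sequence identity keeping the
    first representative of each cluster.
    """
    kept: list[FvRecord] = []
    for rec in records:
        if rec.name in exclusion_ids:
            continue
        if rec.resolution is not None and rec.resolution > max_resolution:
            continue
        if identity_cutoff is not None and any(
                sequence_identity(rec, other) >= identity_cutoff
                for other in kept):
            continue
        kept.append(rec)
    return kept
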