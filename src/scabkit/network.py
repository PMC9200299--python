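"""The antibody geometry network.

Two coupled modules predict nine output distributions from sequence alone:

* an **inter-residue module** — a 1D ResNet over the one-hot encoded,
  chain-break-delimited sequence, expanded to pairwise features and refined by
  a 2D ResNet — producing distributions over the C-beta distance d, the
  dihedrals omega and theta, and the planar angle phi;
* a **rotamer module** — the pairwise features pooled back to sequential form,
  passed through a transformer encoder (whose self-attention is captured for
  interpretation) and a 1D convolution, ending in five conditional chi heads
  where each chi_k head receives the distributions (or, when training with
  teacher forcing, the ground-truth one-hots) of chi_1..chi_{k-1}.

The predicted chi distributions are tiled back onto the pairwise features
before the final per-output 2D convolutions, so side-chain context informs
the inter-residue outputs.  d and omega logits are symmetrized by averaging
with their transpose.  A *control* variant drops the pairwise stack entirely
and runs the rotamer module directly on the 1D ResNet output; it emits chi
distributions only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .antibody_io import InputEncoding
from .discretize import (CHI_OUTPUTS, N_BINS, PAIR_OUTPUTS, LabelTensors,
                         export_edges_json)
from .nn import core
from .nn.core import Tensor
from .nn.layers import (Conv1d, Conv2d, Linear, Module, ResBlock1d, ResBlock2d,
                        TransformerEncoderLayer)


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults are the published full model)."""

    res1d_blocks: int = 3
    res1d_kernel: int = 17
    res2d_blocks: int = 25
    res2d_kernel: int = 5
    seq_channels: int = 32
    attn_heads: int = 8
    attn_ff_dim: int = 512
    attn_blocks: int = 1
    rot_conv_kernel: int = 5
    head_kernel: int = 5
    norm: str = "instance"  # per-channel over space (batch norm at batch 1)
    variant: str = "full"

    @property
    def pair_channels(self) -> int:
        return 2 * self.seq_channels

    def __post_init__(self):
        for name in ("res1d_blocks", "res1d_kernel", "res2d_blocks",
                     "res2d_kernel", "seq_channels", "attn_heads",
                     "attn_ff_dim", "attn_blocks", "rot_conv_kernel",
                     "head_kernel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.variant not in ("full", "control"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @classmethod
    def desk(cls, variant: str = "full") -> "ModelConfig":
        """Reduced configuration for CPU-scale training and tests."""
        return cls(res1d_blocks=2, res2d_blocks=4, seq_channels=16,
                   head_kernel=1, variant=variant)


@dataclass
class PredictionSet:
    """Per-output probability distributions plus captured attention.

    Pairwise arrays are (L, L, 36); p_chi is (5, L, 36); attention is
    (heads, L, L).  The control variant leaves the pairwise arrays None.
    """

    p_d: np.ndarray | None
    p_omega: np.ndarray | None
    p_theta: np.ndarray | None
    p_phi: np.ndarray | None
    p_chi: np.ndarray
    attention: np.ndarray

    def output(self, name: str) -> np.ndarray:
        if name in CHI_OUTPUTS:
            return self.p_chi[int(name[3]) - 1]
        arr = getattr(self, f"p_{name}")
        if arr is None:
            raise ValueError(f"variant does not predict pairwise output {name!r}")
        return arr


@dataclass
class ForwardResult:
    """Raw logits (autodiff tensors) of one forward pass, for loss computation."""

    logits: dict[str, Tensor]
    prediction: PredictionSet


class DeepSCAbModel(Module):
    """Full or control network; weights initialized from `seed`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.in_proj = Conv1d(21, c.seq_channels, 1, rng)
        self.blocks1d = [ResBlock1d(c.seq_channels, c.res1d_kernel, rng, c.norm)
                         for _ in range(c.res1d_blocks)]
        if c.variant == "full":
            self.blocks2d = [ResBlock2d(c.pair_channels, c.res2d_kernel, rng, c.norm)
                             for _ in range(c.res2d_blocks)]
            rot_dim = 2 * c.pair_channels
        else:
            self.blocks2d = []
            rot_dim = c.seq_channels
        self.rot_dim = rot_dim
        self.encoder = [TransformerEncoderLayer(rot_dim, c.attn_heads,
                                                c.attn_ff_dim, rng)
                        for _ in range(c.attn_blocks)]
        self.rot_conv = Conv1d(rot_dim, rot_dim, c.rot_conv_kernel, rng)
        self.chi_heads = [Linear(rot_dim + N_BINS * k, N_BINS, rng)
                          for k in range(5)]
        if c.variant == "full":
            fb = c.pair_channels + 10 * N_BINS  # chi feedback of both partners
            self.out_heads = [Conv2d(fb, N_BINS, c.head_kernel, rng)
                              for _ in PAIR_OUTPUTS]

    # ------------------------------------------------------------------
    def forward(self, enc: InputEncoding, teacher_chi: LabelTensors | None = None,
                detach_trunk: bool = False) -> ForwardResult:
        """One forward pass; `teacher_chi` enables teacher forcing.

        With teacher forcing, the conditioning input of head k — and the chi
        feedback tiled onto the pairwise features — is the ground-truth
        one-hot of each chi wherever its label is valid and the predicted
        distribution where it is masked; at inference the predicted
        distributions are always used.  ``detach_trunk`` blocks gradients
        from the rotamer branch into the shared trunk (used when the rotamer
        module is trained separately).
        """
        c = self.config
        L = enc.combined.shape[0]
        if teacher_chi is not None and teacher_chi.chi.shape[0] != L:
            raise ValueError("teacher_chi length does not match the encoding")
        x = Tensor(enc.combined.astype(np.float32))
        h = self.in_proj(x)
        for blk in self.blocks1d:
            h = blk(h)

        pair = None
        if c.variant == "full":
            pair = core.pair_concat(h)
            for blk in self.blocks2d:
                pair = blk(pair)
            seqfeat = core.rowcol_mean(pair)
        else:
            seqfeat = h

        s = core.detach(seqfeat) if detach_trunk else seqfeat
        for layer in self.encoder:
            s = layer(s)
        attention = self.encoder[0].last_attention
        f = self.rot_conv(s)

        chi_logits: list[Tensor] = []
        chi_probs: list[Tensor] = []
        cond: list[Tensor] = []
        for k in range(5):
            inp = core.concat([f] + cond, axis=-1) if cond else f
            lg = self.chi_heads[k](inp)
            pk = core.softmax(lg)
            chi_logits.append(lg)
            chi_probs.append(pk)
            if teacher_chi is not None:
                labels = teacher_chi.chi[:, k]
                valid = (labels >= 0).astype(np.float32)[:, None]
                onehot = np.zeros((L, N_BINS), dtype=np.float32)
                ok = labels >= 0
                onehot[np.nonzero(ok)[0], labels[ok]] = 1.0
                mixed = core.add(core.mul(Tensor(onehot), Tensor(valid)),
                                 core.mul(pk, Tensor(1.0 - valid)))
                cond.append(mixed)
            else:
                cond.append(pk)

        logits: dict[str, Tensor] = {f"chi{k + 1}": lg
                                     for k, lg in enumerate(chi_logits)}
        if c.variant == "full":
            feedback = core.pair_concat(core.concat(cond, axis=-1))
            pfull = core.concat([pair, feedback], axis=-1)
            for name, head in zip(PAIR_OUTPUTS, self.out_heads):
                lg = head(pfull)
                if name in ("d", "omega"):
                    lg = core.sym_avg(lg)
                logits[name] = lg

        def prob(name):
            return core.softmax(logits[name]).data.astype(np.float64)

        pred = PredictionSet(
            p_d=prob("d") if c.variant == "full" else None,
            p_omega=prob("omega") if c.variant == "full" else None,
            p_theta=prob("theta") if c.variant == "full" else None,
            p_phi=prob("phi") if c.variant == "full" else None,
            p_chi=np.stack([prob(f"chi{k + 1}") for k in range(5)]),
            attention=attention,
        )
        return ForwardResult(logits=logits, prediction=pred)

    def predict(self, enc: InputEncoding) -> PredictionSet:
        return self.forward(enc).prediction


def ensemble_predict(models: list[DeepSCAbModel], enc: InputEncoding
                     ) -> PredictionSet:
    """Arithmetic mean of the members' probability distributions.

    The mean of normalized distributions is normalized (to float tolerance),
    so no renormalization is applied — an ensemble of one is bit-identical
    to a plain forward pass.  Attention is taken from the first member only
    (attention maps are interpreted per model, not averaged).
    """
    if not models:
        raise ValueError("empty model list")
    preds = [m.predict(enc) for m in models]

    def avg(name):
        arrs = [getattr(p, name) for p in preds]
        if arrs[0] is None:
            return None
        return arrs[0] if len(arrs) == 1 else np.mean(arrs, axis=0)

    return PredictionSet(p_d=avg("p_d"), p_omega=avg("p_omega"),
                         p_theta=avg("p_theta"), p_phi=avg("p_phi"),
                         p_chi=avg("p_chi"), attention=preds[0].attention)


# ---------------------------------------------------------------------------
# checkpoints

def _bin_hash() -> str:
    return hashlib.sha256(export_edges_json().encode()).hexdigest()


def save_model(model: DeepSCAbModel, path) -> None:
    """Single-file checkpoint: weights + config + bin-edge hash."""
    state = model.state_dict()
    meta = json.dumps({"config": asdict(model.config), "bin_hash": _bin_hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_model(path) -> DeepSCAbModel:
    """Load a checkpoint; refuses to load if the bin-edge hash differs."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["bin_hash"] != _bin_hash():
            raise ValueError("checkpoint was built against different bin edges")
        model = DeepSCAbModel(ModelConfig(**meta["config"]))
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
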