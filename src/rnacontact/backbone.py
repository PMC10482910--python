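"""Tied-axial-attention encoder over MSA token grids.

The backbone embeds an E×L token grid into an E×L×D latent and applies N
encoder blocks.  Each block performs, with pre-layer normalisation and
residual connections:

1. *tied row attention* — one L×L logit map per head, obtained by summing the
   query–key products over all E rows and scaling by 1/sqrt(E·d_head), so the
   map is shared across rows (and invariant to row order);
2. *column attention* over the evolutionary dimension, per column;
3. a two-layer MLP with ReLU.

Dropout follows both attention operations.  The pre-softmax row-attention
logits of every head in every block are the pair features consumed by the
downstream contact heads.
"""

from __future__ import annotations

import hashlib
import io
import json
import struct
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .msa import TokenGrid

__all__ = ["BackboneConfig", "AttentionMaps", "AxialBackbone",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_MAGIC = b"RNACONTACT-CKPT-v1\n"


@dataclass
class BackboneConfig:
    """Architecture hyperparameters.

    Defaults are the desk-scale configuration (N=2 blocks, H=4 heads, D=64);
    larger models are a matter of configuration, not code.
    """

    n_blocks: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    dropout_p: float = 0.1
    vocab_size: int = 8
    n_permutation_classes: int = 4
    mlp_hidden: int = 128
    max_len: int = 512

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_blocks < 1 or self.n_heads < 1:
            raise ValueError("n_blocks and n_heads must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass
class AttentionMaps:
    """Pre-softmax tied row-attention logits, one L×L map per (block, head)."""

    maps: np.ndarray            # (N*H, L, L)
    provenance: list            # [(block, head), ...]

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[1] != self.maps.shape[2]:
            raise ValueError("attention maps must be (channels, L, L)")
        if len(self.provenance) != self.maps.shape[0]:
            raise ValueError("provenance length must equal channel count")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("attention maps contain non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.maps.shape[0]


class AxialBackbone:
    """The encoder with its parameters and task heads."""

    def __init__(self, cfg: BackboneConfig, seed: int = 0):
        self.cfg = cfg
        self.params: dict[str, nn.Parameter] = {}
        rng = np.random.default_rng(seed)
        D, H, F = cfg.embed_dim, cfg.n_heads, cfg.mlp_hidden

        def p(name, shape, scale=0.02):
            self.params[name] = nn.Parameter(rng.normal(0.0, scale, size=shape))

        def zeros(name, shape):
            self.params[name] = nn.Parameter(np.zeros(shape))

        def ones(name, shape):
            self.params[name] = nn.Parameter(np.ones(shape))

        p("tok_emb", (cfg.vocab_size, D))
        p("pos_emb", (cfg.max_len, D))
        for b in range(cfg.n_blocks):
            for att in ("row", "col"):
                ones(f"b{b}.{att}.ln.g", (D,))
                zeros(f"b{b}.{att}.ln.b", (D,))
                for w in ("wq", "wk", "wv", "wo"):
                    p(f"b{b}.{att}.{w}", (D, D))
                zeros(f"b{b}.{att}.bo", (D,))
            ones(f"b{b}.mlp.ln.g", (D,))
            zeros(f"b{b}.mlp.ln.b", (D,))
            p(f"b{b}.mlp.w1", (D, F))
            zeros(f"b{b}.mlp.b1", (F,))
            p(f"b{b}.mlp.w2", (F, D))
            zeros(f"b{b}.mlp.b2", (D,))
        # task heads: reduction + single linear layer
        p("head.inpainting.w", (D, cfg.vocab_size))
        zeros("head.inpainting.b", (cfg.vocab_size,))
        p("head.jigsaw.w", (D, cfg.n_permutation_classes))
        zeros("head.jigsaw.b", (cfg.n_permutation_classes,))
        p("head.bootstrap.w", (D, 2))
        zeros("head.bootstrap.b", (2,))
        p("head.contrastive.w", (D, D))
        zeros("head.contrastive.b", (D,))

    # -- helpers ------------------------------------------------------------
    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    def state_arrays(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return h.hexdigest()[:16]

    def _ln(self, x: nn.Tensor, prefix: str) -> nn.Tensor:
        g, b = self.params[f"{prefix}.ln.g"], self.params[f"{prefix}.ln.b"]
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + 1e-5) ** -0.5 * g + b

    def _dropout(self, x: nn.Tensor, train: bool, rng) -> nn.Tensor:
        pdrop = self.cfg.dropout_p
        if not train or pdrop == 0.0:
            return x
        keep = (rng.random(x.shape) >= pdrop) / (1.0 - pdrop)
        return x * nn.Tensor(keep)

    # -- forward ------------------------------------------------------------
    def embed(self, grid: TokenGrid) -> tuple:
        """Token + column-position embedding; returns (latent, pad_mask).

        ``pad_mask`` is a boolean (L,) vector of PAD columns (excluded from
        row attention).  No row-position term exists, keeping the model
        equivariant to row order.
        """
        cfg = self.cfg
        E, L = grid.values.shape
        if L > cfg.max_len:
            raise ValueError(
                f"alignment length {L} exceeds configured maximum {cfg.max_len}; "
                "crop the grid first (crop_and_subsample)"
            )
        if grid.values.max(initial=0) >= cfg.vocab_size:
            raise ValueError("token id outside configured vocabulary")
        tok = nn.embedding(self.params["tok_emb"], grid.values)          # (E,L,D)
        pos = nn.embedding(self.params["pos_emb"], np.arange(L))          # (L,D)
        pad_cols = np.all(grid.values == grid.vocab.pad_id, axis=0)       # (L,)
        return tok + pos.reshape(1, L, cfg.embed_dim), pad_cols

    def _attn(self, x: nn.Tensor, prefix: str, axis: str, pad_cols, train, rng):
        """Axial attention along columns (axis='row', tied) or rows (axis='col').

        Returns (output, pre-softmax logits or None)."""
        cfg = self.cfg
        E, L, D = x.shape
        H, dh = cfg.n_heads, cfg.head_dim
        q = (x @ self.params[f"{prefix}.wq"]).reshape(E, L, H, dh)
        k = (x @ self.params[f"{prefix}.wk"]).reshape(E, L, H, dh)
        v = (x @ self.params[f"{prefix}.wv"]).reshape(E, L, H, dh)
        if axis == "row":
            # tied: sum query-key products over rows -> one (L,L) map per head
            logits = nn.einsum("eihd,ejhd->hij", q, k) * (1.0 / np.sqrt(E * dh))
            masked = logits
            if pad_cols.any():
                bias = np.where(pad_cols, -1e9, 0.0)[None, None, :]
                masked = logits + nn.Tensor(np.broadcast_to(bias, logits.shape).copy())
            attn = masked.softmax(axis=-1)                                 # (H,L,L)
            out = nn.einsum("hij,ejhd->eihd", attn, v)
            ret_logits = logits
        else:
            logits = nn.einsum("elhd,flhd->hlef", q, k) * (1.0 / np.sqrt(dh))
            attn = logits.softmax(axis=-1)                                 # (H,L,E,E)
            out = nn.einsum("hlef,flhd->elhd", attn, v)
            ret_logits = None
        out = out.reshape(E, L, D) @ self.params[f"{prefix}.wo"] + self.params[f"{prefix}.bo"]
        return self._dropout(out, train, rng), ret_logits

    def axial_block(self, x: nn.Tensor, block: int, pad_cols, train: bool, rng):
        """One encoder block; returns (latent, per-head row logits (H,L,L))."""
        att, row_logits = self._attn(self._ln(x, f"b{block}.row"), f"b{block}.row",
                                     "row", pad_cols, train, rng)
        x = x + att
        att, _ = self._attn(self._ln(x, f"b{block}.col"), f"b{block}.col",
                            "col", pad_cols, train, rng)
        x = x + att
        h = (self._ln(x, f"b{block}.mlp") @ self.params[f"b{block}.mlp.w1"]
             + self.params[f"b{block}.mlp.b1"]).relu()
        x = x + (h @ self.params[f"b{block}.mlp.w2"] + self.params[f"b{block}.mlp.b2"])
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError(f"non-finite activations in block {block}")
        return x, row_logits

    def forward(self, grid: TokenGrid, train: bool = False, rng=None):
        """Run all blocks; returns (final latent, list of row-logit tensors)."""
        if train and rng is None:
            rng = np.random.default_rng(0)
        x, pad_cols = self.embed(grid)
        logit_list = []
        for b in range(self.cfg.n_blocks):
            x, row_logits = self.axial_block(x, b, pad_cols, train, rng)
            logit_list.append(row_logits)
        return x, logit_list

    def forward_collect(self, grid: TokenGrid, mode: str = "eval", rng=None):
        """Forward pass collecting the N·H pre-softmax row-attention maps.

        Returns ``(latent, AttentionMaps)``; in eval mode dropout is off and
        the result is deterministic.
        """
        if mode not in ("train", "eval"):
            raise ValueError("mode must be 'train' or 'eval'")
        latent, logit_list = self.forward(grid, train=(mode == "train"), rng=rng)
        chans = np.concatenate([t.data for t in logit_list], axis=0)
        prov = [(b, h) for b in range(self.cfg.n_blocks) for h in range(self.cfg.n_heads)]
        return latent, AttentionMaps(chans, prov)

    def collect_maps_tensor(self, grid: TokenGrid, train: bool = False, rng=None):
        """As :meth:`forward_collect` but keeps the maps in the autodiff graph
        (needed for fine-tuning through the attention features)."""
        latent, logit_list = self.forward(grid, train=train, rng=rng)
        return latent, nn.concatenate(logit_list, axis=0)

    def task_head(self, latent: nn.Tensor, task: str) -> nn.Tensor:
        """Task-appropriate reduction plus a single linear layer.

        inpainting: none → (E,L,V); jigsaw: mean over L → (E,C);
        bootstrap: none → (E,L,2); contrastive: mean over L → (E,D).
        """
        if task not in ("inpainting", "jigsaw", "bootstrap", "contrastive"):
            raise ValueError(f"unknown task {task!r}")
        w, b = self.params[f"head.{task}.w"], self.params[f"head.{task}.b"]
        if task in ("jigsaw", "contrastive"):
            latent = latent.mean(axis=1)
        return latent @ w + b


# ---------------------------------------------------------------------------
# checkpointing (deterministic byte layout: magic, JSON header, raw arrays)


def save_checkpoint(backbone: AxialBackbone, path, extra: dict | None = None) -> None:
    names = sorted(backbone.params)
    header = {
        "config": asdict(backbone.cfg),
        "arrays": [{"name": n, "shape": list(backbone.params[n].shape)} for n in names],
        "extra": extra or {},
    }
    hbytes = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(CHECKPOINT_MAGIC)
        fh.write(struct.pack("<Q", len(hbytes)))
        fh.write(hbytes)
        for n in names:
            fh.write(np.ascontiguousarray(backbone.params[n].data, dtype=np.float64).tobytes())


def load_checkpoint(path) -> tuple:
    """Returns (AxialBackbone, extra dict)."""
    with open(path, "rb") as fh:
        magic = fh.read(len(CHECKPOINT_MAGIC))
        if magic != CHECKPOINT_MAGIC:
            raise ValueError(f"{path} is not a backbone checkpoint (bad magic)")
        (hlen,) = struct.unpack("<Q", fh.read(8))
        header = json.loads(fh.read(hlen).decode())
        cfg = BackboneConfig(**header["config"])
        bb = AxialBackbone(cfg, seed=0)
        for spec in header["arrays"]:
            shape = tuple(spec["shape"])
            count = int(np.prod(shape)) if shape else 1
            data = np.frombuffer(fh.read(count * 8), dtype=np.float64).reshape(shape)
            bb.params[spec["name"]].data = data.copy()
    return bb, header.get("extra", {})
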