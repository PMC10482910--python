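"""Self-supervised pretext tasks on MSA token grids.

Four tasks provide the pre-training signal:

* **inpainting** — masked-token recovery: randomly chosen tokens are replaced
  by a random legal token and must be classified back to their original id;
* **jigsaw** — columns are split into contiguous chunks and shuffled by a
  permutation drawn from a fixed set; the model classifies which permutation
  was applied;
* **bootstrap** — tokens (or whole rows) are resampled from the column-wise
  empirical token profile; the model flags which entries were replaced;
* **contrastive** — per-sequence latents of the same family are pulled
  together and pushed away from other families (normalised-temperature
  cross-entropy over cosine similarities).

The total pre-training loss is the plain sum of the active task losses.
Augmentations operate on integer grids with numpy generators; losses are
written against the autodiff :class:`~rnacontact.nn.Tensor` so the same code
path serves training and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _perms

import numpy as np

from . import nn
from .msa import TokenGrid

__all__ = [
    "AugmentedBatch",
    "TaskLossSet",
    "apply_inpainting",
    "apply_jigsaw",
    "apply_bootstrap",
    "default_permutation_set",
    "inpainting_loss",
    "jigsaw_loss",
    "bootstrap_loss",
    "contrastive_loss",
    "classification_losses",
    "total_loss",
]

TASKS = ("inpainting", "jigsaw", "bootstrap", "contrastive")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TaskLossSet:
    """Per-task scalar losses and their sum."""

    per_task: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.per_task.values()))

    def __getitem__(self, k):
        return self.per_task[k]


def total_loss(parts: TaskLossSet):
    """Sum of all present task losses (tensors summed in-graph)."""
    vals = list(parts.per_task.values())
    if not vals:
        raise ValueError("no task losses present")
    out = vals[0]
    for v in vals[1:]:
        out = out + v
    return out


@dataclass
class AugmentedBatch:
    """Task-augmented grids plus the self-supervised targets."""

    grids: list
    inpaint_mask: list = field(default_factory=list)      # bool (E,L) per grid
    inpaint_targets: list = field(default_factory=list)   # int  (E,L) per grid
    jigsaw_label: list = field(default_factory=list)      # int (E,) or scalar per grid
    bootstrap_flags: list = field(default_factory=list)   # (E,L) or (E,) per grid
    family_ids: list = field(default_factory=list)        # str per grid


# ---------------------------------------------------------------------------
# augmentations


def apply_inpainting(grid: TokenGrid, fraction: float, seed):
    """Mask random tokens and overwrite them with random legal tokens.

    Each non-PAD position is masked independently with probability
    ``fraction``; masked positions receive a uniform draw over the legal
    (non-special) tokens.  Returns ``(augmented_grid, mask, targets)`` where
    ``targets`` holds the original ids (defined only where ``mask``).
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = _as_rng(seed)
    vocab = grid.vocab
    values = grid.values
    maskable = values != vocab.pad_id
    mask = maskable & (rng.random(values.shape) < fraction)
    out = values.copy()
    n = int(mask.sum())
    legal = np.asarray(vocab.legal_ids)
    out[mask] = legal[rng.integers(0, len(legal), size=n)]
    targets = values.copy()
    return TokenGrid(out, vocab, grid.family_id, grid.query_index), mask, targets


def default_permutation_set(n_chunks: int = 3, C: int = 4) -> list:
    """Fixed permutation set of size C containing the identity (first)."""
    all_p = list(_perms(range(n_chunks)))
    if C > len(all_p):
        raise ValueError(f"C={C} exceeds {n_chunks}! possible permutations")
    return [tuple(p) for p in all_p[:C]]


def apply_jigsaw(grid: TokenGrid, n_chunks: int, permutation_set, per_sequence: bool, seed):
    """Shuffle contiguous column chunks by a permutation drawn from the set.

    Columns are split into ``n_chunks`` near-equal contiguous chunks.  With
    ``per_sequence`` a permutation index is drawn per row; otherwise one
    index is drawn for the whole MSA.  Returns ``(augmented_grid, labels)``
    with the drawn index/indices.
    """
    if n_chunks > grid.length:
        raise ValueError("n_chunks exceeds alignment length")
    perm_set = [tuple(p) for p in permutation_set]
    if len(perm_set) < 2 or tuple(range(n_chunks)) not in perm_set:
        raise ValueError("permutation set must contain the identity and >= 2 entries")
    for p in perm_set:
        if sorted(p) != list(range(n_chunks)):
            raise ValueError(f"permutation {p} does not act on {n_chunks} chunks")
    rng = _as_rng(seed)
    chunks = np.array_split(np.arange(grid.length), n_chunks)
    E = grid.depth
    out = grid.values.copy()
    if per_sequence:
        labels = rng.integers(0, len(perm_set), size=E)
        draws = labels
    else:
        labels = int(rng.integers(0, len(perm_set)))
        draws = np.full(E, labels)
    for e in range(E):
        perm = perm_set[int(draws[e])]
        cols = np.concatenate([chunks[k] for k in perm])
        out[e] = grid.values[e, cols]
    return TokenGrid(out, grid.vocab, grid.family_id, grid.query_index), labels


def column_profiles(grid: TokenGrid) -> np.ndarray:
    """Empirical per-column token distribution over the legal tokens (L, 5)."""
    vocab = grid.vocab
    legal = np.asarray(vocab.legal_ids)
    counts = np.zeros((grid.length, len(legal)))
    for k, tok in enumerate(legal):
        counts[:, k] = (grid.values == tok).sum(axis=0)
    # columns made only of special tokens fall back to uniform
    tot = counts.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    profiles = counts / tot
    profiles[counts.sum(axis=1) == 0] = 1.0 / len(legal)
    return profiles


def apply_bootstrap(grid: TokenGrid, fraction: float, level: str, seed):
    """Resample tokens (or whole rows) from the column-wise token profile.

    ``level='token'``: each non-PAD token is replaced independently with
    probability ``fraction`` by a draw from its column's empirical profile.
    ``level='sequence'``: each row is replaced (all positions resampled) with
    probability ``fraction``.  Returns ``(augmented_grid, flags)`` where
    ``flags`` marks replacements — per token, or per row for sequence level.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if level not in ("sequence", "token"):
        raise ValueError("level must be 'sequence' or 'token'")
    rng = _as_rng(seed)
    vocab = grid.vocab
    legal = np.asarray(vocab.legal_ids)
    profiles = column_profiles(grid)  # (L, 5)
    cum = np.cumsum(profiles, axis=1)
    E, L = grid.values.shape
    out = grid.values.copy()
    if level == "token":
        flags = (grid.values != vocab.pad_id) & (rng.random((E, L)) < fraction)
        u = rng.random((E, L))
        draw_idx = (u[..., None] >= cum[None, :, :]).sum(axis=-1)
        out[flags] = legal[draw_idx[flags]]
    else:
        flags = rng.random(E) < fraction
        u = rng.random((E, L))
        draw_idx = (u[..., None] >= cum[None, :, :]).sum(axis=-1)
        rows = np.where(flags)[0]
        pad = grid.values == vocab.pad_id
        for e in rows:
            repl = legal[draw_idx[e]]
            repl[pad[e]] = vocab.pad_id
            out[e] = repl
    return TokenGrid(out, vocab, grid.family_id, grid.query_index), flags


# ---------------------------------------------------------------------------
# losses


def _lift(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=float))


def _cross_entropy(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Mean softmax cross-entropy; logits (..., K), integer targets (...)."""
    logp = logits.log_softmax(axis=-1)
    picked = logp.gather_last(np.asarray(targets, dtype=np.int64))
    return -picked.mean()


def inpainting_loss(logits, mask: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy over masked positions only.

    Returns ``None`` when the mask is empty (loss absent, not zero).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    logits = _lift(logits)
    flat = logits.reshape(-1, logits.shape[-1])[np.flatnonzero(mask.ravel())]
    return _cross_entropy(flat, np.asarray(targets)[mask])


def jigsaw_loss(logits, labels):
    """Permutation-class cross-entropy (per-sequence or whole-MSA labels)."""
    logits = _lift(logits)
    labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
    if logits.ndim == 1:
        logits = logits.reshape(1, -1)
    return _cross_entropy(logits, labels)


def bootstrap_loss(logits, flags):
    """Binary replaced-vs-original cross-entropy at the configured level."""
    logits = _lift(logits)
    flags = np.asarray(flags, dtype=np.int64)
    flat = logits.reshape(-1, logits.shape[-1])
    return _cross_entropy(flat, flags.ravel())


def contrastive_loss(latents, family_ids, temperature: float = 0.1):
    """NT-Xent over cosine similarities; positives share a family id.

    Invariant to rescaling any latent by a positive factor (cosine).  Raises
    if the batch contains a single family (no negatives).
    """
    fams = np.asarray(family_ids)
    if len(set(fams.tolist())) < 2:
        raise ValueError("contrastive loss needs >= 2 families in the batch")
    z = _lift(latents)
    norm = (z * z).sum(axis=1, keepdims=True) ** 0.5
    z = z / norm
    sim = nn.einsum("id,jd->ij", z, z) * (1.0 / temperature)
    n = sim.shape[0]
    eye = np.eye(n, dtype=bool)
    pos = (fams[:, None] == fams[None, :]) & ~eye
    NEG_INF = -1e9
    denom_mask = np.where(eye, NEG_INF, 0.0)
    num_mask = np.where(pos, 0.0, NEG_INF)
    log_denom = _logsumexp_rows(sim + nn.Tensor(denom_mask))
    log_num = _logsumexp_rows(sim + nn.Tensor(num_mask))
    return -(log_num - log_denom).mean()


def _logsumexp_rows(t: nn.Tensor) -> nn.Tensor:
    m = nn.Tensor(t.data.max(axis=-1, keepdims=True))
    return ((t - m).exp().sum(axis=-1).log()) + m.reshape(-1)


def classification_losses(logits: dict, batch_mask_targets: dict) -> TaskLossSet:
    """Evaluate the classification-style task losses for one grid.

    ``logits`` maps task name → logit tensor; ``batch_mask_targets`` supplies
    the matching targets: ``inpainting=(mask, targets)``, ``jigsaw=labels``,
    ``bootstrap=flags``.  An empty inpainting mask leaves the task absent.
    """
    out = TaskLossSet()
    if "inpainting" in logits:
        mask, targets = batch_mask_targets["inpainting"]
        loss = inpainting_loss(logits["inpainting"], mask, targets)
        if loss is not None:
            out.per_task["inpainting"] = loss
    if "jigsaw" in logits:
        out.per_task["jigsaw"] = jigsaw_loss(logits["jigsaw"], batch_mask_targets["jigsaw"])
    if "bootstrap" in logits:
        out.per_task["bootstrap"] = bootstrap_loss(logits["bootstrap"], batch_mask_targets["bootstrap"])
    return out
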