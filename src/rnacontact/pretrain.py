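"""Multi-task self-supervised pre-training of the axial backbone.

Each step draws one family (two when the contrastive task is active),
crops/subsamples it, applies the active augmentations, runs the backbone in
train mode and minimises the sum of the active task losses with Adam.
Inpainting is the base task; it may be combined with at most one of jigsaw,
bootstrap or contrastive (the pairings evaluated upstream).  With jigsaw
active, the inpainting mask is drawn after the chunks are shuffled.

All randomness is routed through named streams derived from one seed, so a
rerun with the same configuration reproduces the trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn, pretext
from ._rng import stream
from .backbone import AxialBackbone, BackboneConfig
from .msa import TokenGrid, crop_and_subsample
from .pretext import TaskLossSet, total_loss

__all__ = ["PretextTrainer", "TaskConfig"]


@dataclass
class TaskConfig:
    """Hyperparameters of the pretext tasks."""

    inpainting_fraction: float = 0.15
    jigsaw_chunks: int = 3
    jigsaw_classes: int = 4
    jigsaw_per_sequence: bool = True
    bootstrap_fraction: float = 0.15
    bootstrap_level: str = "token"
    contrastive_temperature: float = 0.1


class PretextTrainer:
    """Fit the backbone on unlabeled token grids via pretext tasks.

    Parameters mirror the run configuration: the task list, the task
    hyperparameters, crop/subsample limits applied per step, the number of
    optimisation steps and the Adam learning rate.
    """

    def __init__(self, cfg: BackboneConfig | None = None,
                 tasks=("inpainting",), task_config: TaskConfig | None = None,
                 steps: int = 300, learning_rate: float = 1e-3,
                 max_E: int = 32, max_L: int = 64, seed: int = 0):
        self.cfg = cfg or BackboneConfig()
        self.tasks = tuple(tasks)
        self.task_config = task_config or TaskConfig()
        self.steps = steps
        self.learning_rate = learning_rate
        self.max_E = max_E
        self.max_L = max_L
        self.seed = seed
        unknown = set(self.tasks) - set(pretext.TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")
        secondary = [t for t in self.tasks if t != "inpainting"]
        if "inpainting" in self.tasks and len(secondary) > 1:
            raise ValueError("inpainting combines with at most one secondary task")

    # -- one family, one step -------------------------------------------------
    def _augment(self, grid: TokenGrid, streams) -> tuple:
        """Apply the active augmentations; returns (grid, targets dict)."""
        tc = self.task_config
        targets = {}
        if "jigsaw" in self.tasks:
            perm_set = pretext.default_permutation_set(tc.jigsaw_chunks, tc.jigsaw_classes)
            grid, labels = pretext.apply_jigsaw(grid, tc.jigsaw_chunks, perm_set,
                                                tc.jigsaw_per_sequence, streams["jigsaw"])
            targets["jigsaw"] = labels
        if "bootstrap" in self.tasks:
            grid, flags = pretext.apply_bootstrap(grid, tc.bootstrap_fraction,
                                                  tc.bootstrap_level, streams["bootstrap"])
            targets["bootstrap"] = flags
        if "inpainting" in self.tasks:
            grid, mask, originals = pretext.apply_inpainting(
                grid, tc.inpainting_fraction, streams["inpainting"])
            targets["inpainting"] = (mask, originals)
        return grid, targets

    def _step_losses(self, grids, targets_list, family_ids, streams) -> TaskLossSet:
        bb = self.backbone_
        tc = self.task_config
        parts = TaskLossSet()
        latents = []
        for grid, targets in zip(grids, targets_list):
            latent, _ = bb.forward(grid, train=True, rng=streams["dropout"])
            logits = {}
            if "inpainting" in targets:
                logits["inpainting"] = bb.task_head(latent, "inpainting")
            if "jigsaw" in targets:
                logits["jigsaw"] = bb.task_head(latent, "jigsaw")
            if "bootstrap" in targets:
                if tc.bootstrap_level == "token":
                    logits["bootstrap"] = bb.task_head(latent, "bootstrap")
                else:
                    logits["bootstrap"] = bb.task_head(latent.mean(axis=1), "bootstrap")
            partial = pretext.classification_losses(logits, targets)
            for name, loss in partial.per_task.items():
                parts.per_task[name] = (parts.per_task[name] + loss
                                        if name in parts.per_task else loss)
            if "contrastive" in self.tasks:
                latents.append(bb.task_head(latent, "contrastive"))
        if "contrastive" in self.tasks:
            z = nn.concatenate(latents, axis=0)
            fams = np.concatenate([
                np.full(g.depth, fid) for g, fid in zip(grids, family_ids)
            ])
            parts.per_task["contrastive"] = pretext.contrastive_loss(
                z, fams, tc.contrastive_temperature)
        return parts

    def fit(self, families, seed: int | None = None):
        """Train on a list of :class:`TokenGrid`; returns self.

        ``history_`` records per-step task losses and their sum (the training
        objective is always the plain sum of active task losses)."""
        seed = self.seed if seed is None else seed
        if "contrastive" in self.tasks and len(families) < 2:
            raise ValueError("contrastive task needs at least two families")
        streams = {name: stream(seed, name) for name in
                   ("data", "crop", "inpainting", "jigsaw", "bootstrap", "dropout")}
        self.backbone_ = AxialBackbone(self.cfg, seed=int(stream(seed, "init").integers(2**31)))
        opt = nn.Adam(self.backbone_.parameters(), lr=self.learning_rate)
        self.history_ = []
        n_grids = 2 if "contrastive" in self.tasks else 1
        for step in range(self.steps):
            idx = streams["data"].choice(len(families), size=n_grids, replace=False)
            grids, targets_list, fam_ids = [], [], []
            for i in idx:
                g = crop_and_subsample(families[i], self.max_L, self.max_E,
                                       int(streams["crop"].integers(2**31)))
                g, targets = self._augment(g, streams)
                grids.append(g)
                targets_list.append(targets)
                fam_ids.append(families[i].family_id or str(i))
            parts = self._step_losses(grids, targets_list, fam_ids, streams)
            loss = total_loss(parts)
            opt.zero_grad()
            loss.backward()
            opt.step()
            record = {name: float(t.item()) for name, t in parts.per_task.items()}
            record["total"] = float(loss.item())
            record["step"] = step
            self.history_.append(record)
        return self

    def validate_inpainting(self, families, seed: int = 12345) -> tuple:
        """Masked-token validation: mean cross-entropy and accuracy.

        Deterministic (eval mode, fixed mask seed); returns (ce, accuracy)."""
        bb = self.backbone_
        rng = np.random.default_rng(seed)
        ces, hits, total = [], 0, 0
        for grid in families:
            g = crop_and_subsample(grid, self.max_L, self.max_E,
                                   int(rng.integers(2**31)))
            aug, mask, targets = pretext.apply_inpainting(
                g, self.task_config.inpainting_fraction, rng)
            if not mask.any():
                continue
            latent, _ = bb.forward(aug, train=False)
            logits = bb.task_head(latent, "inpainting")
            loss = pretext.inpainting_loss(logits, mask, targets)
            ces.append(loss.item() * mask.sum())
            pred = logits.data.argmax(axis=-1)
            hits += int((pred[mask] == targets[mask]).sum())
            total += int(mask.sum())
        return float(np.sum(ces) / total), float(hits / total)
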