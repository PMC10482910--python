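"""Shared fixtures: tiny alignments and the session-scoped trained pipeline.

The expensive fixtures (synthetic dataset, 300-step pre-training, downstream
fits) are session-scoped and lazy, so unit-test modules that do not request
them never pay for them.
"""

from __future__ import annotations

import copy
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rnacontact import msa as M
from rnacontact import synthetic
from rnacontact.downstream import (EarlyStopPlan, LabeledFamily, fit_logistic,
                                   finetune_then_boost, split_holdout)
from rnacontact.pretrain import PretextTrainer


@pytest.fixture
def tiny_msa():
    return M.Msa(["ACGU-ACG", "ACGUUACG", "AC-U-ACG"], ["s1", "s2", "s3"],
                 family_id="FAM1")


@pytest.fixture
def tiny_grid(tiny_msa):
    return M.tokenize(tiny_msa)


def _labeled(fam: synthetic.SyntheticFamily) -> LabeledFamily:
    return LabeledFamily(M.tokenize(fam.msa), fam.labels, fam.msa.family_id)


@pytest.fixture(scope="session")
def train_families():
    """8 training families at the default planted-contact conditions."""
    return [_labeled(synthetic.make_family(100 + s, family_id=f"TRAIN{s}"))
            for s in range(8)]


@pytest.fixture(scope="session")
def test_families():
    """4 held-out families, disjoint seeds from training."""
    return [_labeled(synthetic.make_family(900 + s, family_id=f"TEST{s}"))
            for s in range(4)]


@pytest.fixture(scope="session")
def pretrained(train_families):
    """Backbone pre-trained 300 steps on the training MSAs (inpainting)."""
    trainer = PretextTrainer(steps=300, seed=11)
    trainer.fit([f.grid for f in train_families])
    return trainer


@pytest.fixture(scope="session")
def holdout_plan(train_families):
    hold = split_holdout(train_families, 0.1, seed=0)
    return EarlyStopPlan(metrics=("top_l",), patience=10, holdout=hold)


@pytest.fixture(scope="session")
def frozen_fit(pretrained, train_families, holdout_plan):
    """Frozen-backbone bias-free logistic head."""
    return fit_logistic(train_families, pretrained.backbone_, holdout_plan,
                        backbone_frozen=True, max_E=128, seed=21)


@pytest.fixture(scope="session")
def tuned_record(pretrained, train_families, holdout_plan):
    """Fine-tuned backbone + boosted ensemble (on a backbone copy)."""
    bb = copy.deepcopy(pretrained.backbone_)
    boost_plan = EarlyStopPlan(metrics=("loss",), patience=10,
                               holdout=holdout_plan.holdout)
    rec = finetune_then_boost(bb, train_families, holdout_plan, boost_plan,
                              max_epochs=25, max_E=96, seed=22)
    rec["backbone"] = bb
    return rec


@pytest.fixture
def rng():
    return np.random.default_rng(0)
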