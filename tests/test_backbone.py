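"""Tied-axial-attention encoder: shapes, equivariances, determinism."""

import numpy as np
import pytest

from rnacontact import msa as M
from rnacontact import pretext
from rnacontact.backbone import (AxialBackbone, BackboneConfig,
                                 load_checkpoint, save_checkpoint)
from rnacontact.msa import TokenGrid

CFG = BackboneConfig(n_blocks=2, n_heads=4, embed_dim=16, dropout_p=0.0,
                     mlp_hidden=32, max_len=64)


@pytest.fixture
def bb():
    return AxialBackbone(CFG, seed=0)


@pytest.fixture
def grid(rng):
    return TokenGrid(rng.integers(0, 5, size=(5, 12)))


def test_config_invariants():
    with pytest.raises(ValueError, match="divisible"):
        BackboneConfig(embed_dim=10, n_heads=4)
    with pytest.raises(ValueError, match="dropout"):
        BackboneConfig(dropout_p=1.0)


def test_embed_shape_and_positional_terms(bb):
    grid = TokenGrid(np.zeros((2, 6), dtype=int))  # identical tokens everywhere
    latent, pad = bb.embed(grid)
    assert latent.shape == (2, 6, CFG.embed_dim)
    # same token at two positions differs only via the positional term
    diff = latent.data[0, 0] - latent.data[0, 1]
    pos = bb.params["pos_emb"].data
    np.testing.assert_allclose(diff, pos[0] - pos[1], atol=1e-12)


def test_forward_collect_channel_count_and_finiteness(bb, grid):
    latent, maps = bb.forward_collect(grid, mode="eval")
    assert maps.n_channels == CFG.n_blocks * CFG.n_heads
    assert maps.maps.shape == (8, 12, 12)
    assert np.all(np.isfinite(maps.maps))
    assert maps.provenance[0] == (0, 0) and maps.provenance[-1] == (1, 3)


def test_eval_mode_is_deterministic(grid):
    bb = AxialBackbone(BackboneConfig(embed_dim=16, mlp_hidden=32,
                                      dropout_p=0.3, max_len=64), seed=1)
    _, a = bb.forward_collect(grid, mode="eval")
    _, b = bb.forward_collect(grid, mode="eval")
    np.testing.assert_array_equal(a.maps, b.maps)


def test_row_permutation_leaves_row_attention_invariant(bb, grid, rng):
    _, maps = bb.forward_collect(grid, mode="eval")
    perm = rng.permutation(grid.depth)
    permuted = TokenGrid(grid.values[perm])
    latent_p, maps_p = bb.forward_collect(permuted, mode="eval")
    np.testing.assert_allclose(maps_p.maps, maps.maps, atol=1e-6)
    # per-row latents are permuted alongside the rows
    latent, _ = bb.forward_collect(grid, mode="eval")
    np.testing.assert_allclose(latent_p.data, latent.data[perm], atol=1e-8)


def test_single_row_reduces_to_standard_attention_scale(bb):
    # with E=1 the tied scaling 1/sqrt(E*d) equals the usual 1/sqrt(d): the
    # logits must match a direct single-sequence computation
    grid = TokenGrid(np.array([[0, 1, 2, 3, 1, 0]]))
    x, _ = bb.embed(grid)
    xn = bb._ln(x, "b0.row")
    q = (xn @ bb.params["b0.row.wq"]).data.reshape(1, 6, 4, 4)
    k = (xn @ bb.params["b0.row.wk"]).data.reshape(1, 6, 4, 4)
    expect = np.einsum("eihd,ejhd->hij", q, k) / np.sqrt(4)
    _, logits = bb._attn(xn, "b0.row", "row", np.zeros(6, bool), False, None)
    np.testing.assert_allclose(logits.data, expect, atol=1e-10)


def test_task_head_shapes(bb, grid):
    latent, _ = bb.forward(grid, train=False)
    assert bb.task_head(latent, "inpainting").shape == (5, 12, 8)
    assert bb.task_head(latent, "jigsaw").shape == (5, 4)
    assert bb.task_head(latent, "bootstrap").shape == (5, 12, 2)
    assert bb.task_head(latent, "contrastive").shape == (5, 16)
    with pytest.raises(ValueError, match="unknown task"):
        bb.task_head(latent, "folding")


def test_length_above_maximum_instructs_to_crop(bb):
    grid = TokenGrid(np.zeros((2, 65), dtype=int))
    with pytest.raises(ValueError, match="crop"):
        bb.embed(grid)


def test_gradient_reaches_every_parameter(bb, grid):
    """Smoke property: with all four tasks active across two steps, every
    parameter array receives a nonzero gradient somewhere."""
    from rnacontact import nn

    touched = {k: False for k in bb.params}
    rng = np.random.default_rng(0)
    grid2 = TokenGrid(rng.integers(0, 4, size=(4, 12)), family_id="other")

    # step 1: inpainting + jigsaw + bootstrap
    aug, mask, targets = pretext.apply_inpainting(grid, 0.3, seed=1)
    latent, _ = bb.forward(aug, train=False)
    loss = pretext.inpainting_loss(bb.task_head(latent, "inpainting"), mask, targets)
    loss = loss + pretext.jigsaw_loss(bb.task_head(latent, "jigsaw"),
                                      np.zeros(5, dtype=int))
    loss = loss + pretext.bootstrap_loss(bb.task_head(latent, "bootstrap"),
                                         np.zeros((5, 12), dtype=int))
    loss.backward()
    for k, p in bb.params.items():
        if p.grad is not None and np.any(p.grad != 0):
            touched[k] = True
        p.grad = None

    # step 2: contrastive over two families
    l1, _ = bb.forward(grid, train=False)
    l2, _ = bb.forward(grid2, train=False)
    z = nn.concatenate([bb.task_head(l1, "contrastive"),
                        bb.task_head(l2, "contrastive")], axis=0)
    fams = np.array(["a"] * 5 + ["b"] * 4)
    pretext.contrastive_loss(z, fams, 0.1).backward()
    for k, p in bb.params.items():
        if p.grad is not None and np.any(p.grad != 0):
            touched[k] = True

    untouched = [k for k, v in touched.items() if not v
                 and not k.startswith("pos_emb")]
    # positional rows beyond L legitimately receive no gradient
    assert np.any(bb.params["pos_emb"].grad[:12] != 0)
    assert untouched == []


def test_nonfinite_activation_names_block(bb, grid):
    bb.params["b1.mlp.w2"].data[:] = np.inf
    with pytest.raises(FloatingPointError, match="block 1"):
        bb.forward(grid, train=False)


def test_checkpoint_round_trip(tmp_path, bb, grid):
    _, before = bb.forward_collect(grid, mode="eval")
    path = tmp_path / "bb.ckpt"
    save_checkpoint(bb, path, extra={"tasks": ["inpainting"]})
    loaded, extra = load_checkpoint(path)
    assert extra == {"tasks": ["inpainting"]}
    assert loaded.state_hash() == bb.state_hash()
    _, after = loaded.forward_collect(grid, mode="eval")
    np.testing.assert_array_equal(after.maps, before.maps)


def test_checkpoint_bad_magic(tmp_path):
    p = tmp_path / "junk.ckpt"
    p.write_bytes(b"not a checkpoint")
    with pytest.raises(ValueError, match="magic"):
        load_checkpoint(p)
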