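# Methods

## The model

The backbone is an MSA encoder over token grids of shape E×L (E aligned
sequences, L columns) with vocabulary {A, C, G, U, gap, UNK, MASK, PAD}
(V = 8; ambiguity codes collapse to UNK, `T` is read as `U`). Embedding is a
learned token table plus a learned column-position table; there is no
row-position term, which makes the whole model equivariant to row order — a
property the tests assert, since an alignment's row order is arbitrary.

Each of the N encoder blocks applies, with pre-layer normalisation and
residual connections:

1. **Tied row attention.** Per head, query–key products are summed over all
   E rows and scaled by 1/√(E·d_head), producing a single L×L logit map
   shared by every row (for E = 1 this reduces to the standard 1/√d_head
   scaling). Softmax is taken over columns; PAD columns are masked out with
   an additive −10⁹ bias. Dropout follows the attention output.
2. **Column attention** over the E dimension, per column, scaled by
   1/√d_head, also followed by dropout.
3. A two-layer MLP with ReLU.

Task heads are a task-appropriate reduction plus one linear layer:
per-position V-way logits for inpainting, per-sequence C-way logits after a
mean over columns for the jigsaw, per-position (or per-sequence) binary
logits for the bootstrap task, and a per-sequence latent vector for the
contrastive task.

The *pair features* for the downstream heads are the **pre-softmax** row
attention logits of all N·H heads at pixel (i, j), symmetrised as
(map[i,j] + map[j,i])/2 — tied row attention is nearly but not exactly
symmetric, and the arithmetic mean makes every emitted score matrix exactly
symmetric.

Default desk-scale configuration: N = 2 blocks, H = 4 heads, D = 64,
MLP width 128, dropout 0.1. Larger models are configuration, not code.

## Pretext tasks

* **Inpainting** (base task): each non-PAD token is masked independently
  with probability 0.15 and overwritten with a uniformly random legal token
  (A/C/G/U/gap); the loss is mean cross-entropy over masked positions only,
  and reported as *absent* (not zero) if a draw masks nothing. Column-shaped
  masks and profile-based replacement sampling exist behind flags but are
  off by default, as neither improves the task.
* **Jigsaw**: columns are split into 3 near-equal contiguous chunks and
  permuted by one of C = 4 fixed permutations (identity first), drawn per
  sequence by default; the model classifies the permutation. When combined
  with inpainting, the mask is drawn after shuffling.
* **Bootstrap**: tokens (default) or whole rows are resampled from the
  column-wise empirical token profile with probability 0.15; the model flags
  replacements (binary cross-entropy). A resampled position counts as
  replaced even when the draw reproduces the original token — in
  low-entropy columns the task is intrinsically ambiguous.
* **Contrastive**: NT-Xent at temperature 0.1 over cosine similarities of
  per-sequence latents; positives are sequences of the same family within
  the batch, so a batch must contain at least two families. The loss is
  invariant to rescaling any latent.

Inpainting combines with at most one secondary task. The training objective
is always the unweighted sum of the active task losses, and the per-step log
records each part next to the total (their additivity is asserted exactly).

Pre-training draws one family per step (two when contrastive is active),
subsamples it to at most 32 rows and 64 columns (query always kept), and
takes one full-batch Adam step at learning rate 10⁻³. 300 steps suffice for
the desk-scale backbone to beat the uninformed baselines (validation masked
cross-entropy below ln V, accuracy above 1/V) on held-out synthetic
families.

## Downstream heads and regimes

The **logistic head** is deliberately bias-free: contact log-odds are a pure
weighted sum of attention values, so the 0.5 decision threshold coincides
with log-odds 0 and the zero feature vector scores exactly 0.5. Losses:
class-weighted cross-entropy (positive weight #neg/#pos — contacts are
sparse), focal loss with γ = 2 and the same class weighting, or dice loss
with smoothing 1.0. Optimisation is full-batch Adam.

The **boosted ensemble** delegates fitting to xgboost (exact greedy trees,
single thread, fixed seed, base_score 0.5 so the margin is a pure leaf sum;
scale_pos_weight = #neg/#pos) but all scoring goes through the package's own
evaluator on the exported trees: F_K(x) = Σₖ w_{q_k(x)}, probability
σ(F_K(x)). Tests verify the re-evaluation against the engine's margins.
Cross-entropy and focal objectives are supported; dice is not expressible as
a per-sample separable boosting objective and is rejected explicitly.
Defaults: up to 200 rounds, depth 3, learning rate 0.1.

**Early stopping** uses a family-level holdout (10% of training families,
at least one) and monitors any of validation loss, MCC, F1, or macro top-L
precision with patience 10; a checkpoint is recorded at the best value of
every monitored metric. **Fine-tuning** trains the logistic head with the
backbone unfrozen (backbone learning rate 10⁻³, head 0.05, one Adam step per
family per epoch); the fine-tuned + boosted regime selects the checkpoint of
the requested fine-tune metric as feature extractor and then fits the trees,
recording both early-stop metrics in the model file. To bound the cost of
backpropagating through the encoder, fine-tuning passes may subsample
families to a configurable number of rows (default 128 in the CLI; 96 in the
acceptance script); test-time prediction always uses the full alignment.

## Mean-field DCA baseline

Sequences are reweighted by 1/(number of rows at ≥ 80% identity, self
included); M_eff is the weight sum. Frequencies use the q = 5 alphabet
(A, C, G, U, gap; UNK counts as gap) with pseudocount λ = M_eff mixed as
α = λ/(λ + M_eff): f₁ ← (1−α)f₁ + α/q, f₂ ← (1−α)f₂ + α/q². The gap state
is dropped at every site (gauge fixing, and it keeps the correlation matrix
well conditioned); site-diagonal blocks are δ_ab f_i(a) − f_i(a)f_i(b). The
coupling matrix is e = −C⁻¹; pair scores are the Frobenius norm of each 4×4
nucleotide block, symmetrised, with the average product correction
S′_ij = S_ij − S̄_i S̄_j / S̄ computed over off-diagonal entries. Ranking is
by descending score with deterministic (i, j) tie-breaks. A singular C
raises with the advice to increase λ. Pseudo-likelihood maximisation is out
of scope; the baseline here is explicitly the mean-field variant.

## Metrics

All metrics operate on included upper-triangle pairs only; pairs with
|i−j| < 4 (configurable) or touching unresolved residues/query gaps are
excluded. Predicted positive means score ≥ threshold (default 0.5). MCC uses
the signed formula with the 0-on-zero-denominator convention (it must be
able to go negative). Top-(k·L) precision selects the ⌈k·L⌉ highest-scoring
pairs — ceiling, with L the query's ungapped length — treats them all as
positive predictions and reports the true fraction; ties break
lexicographically on (i, j), which is documented because it changes results
on tied scores. Micro aggregation pools confusion counts before deriving;
macro derives per sample and reports mean ± population standard deviation.
Every metric is tested against an independent brute-force implementation on
random fixtures (counts exactly, ratios to 10⁻¹²).

## Synthetic planted-contact families

The generator plants n disjoint pairs (each index in at most one pair,
|i−j| ≥ 4; optionally non-crossing to mimic nested secondary structure) and
builds a Potts model whose couplings reward Watson–Crick combinations
(A-U, U-A, G-C, C-G) with strength β (G-U wobble optionally at β/2); fields
are small normal draws (σ = 0.1). β = 0 yields independent columns.

Sampling is by sequential-site Gibbs sweeps, vectorised across chains. By
default every row is the endpoint of its own independent chain after 100
burn-in sweeps, so rows are i.i.d.; configuring fewer chains instead takes
every 10th sweep after burn-in. The sampler is validated against exact
Boltzmann enumeration on 2–3-site models (total variation < 0.02 at 50,000
samples).

Default family conditions, used throughout the tests and the acceptance
script: L = 30, E = 300, 5 planted pairs, β = 3, minimum separation 4; the
downstream experiments use 8 training and 4 held-out test families. At these
conditions the attention maps of the pre-trained backbone carry enough
covariation signal that both downstream heads place all five planted pairs
in their top-L predictions, i.e. they sit at the 5/30 ≈ 0.167 ceiling, an
order of magnitude above the 5/351 ≈ 0.014 planted-density random
expectation.

**What the generator does not emulate:** phylogenetic relatedness between
rows (reweighting tests therefore use explicit duplicate rows), indels and
alignment errors (rows are gap-free), length variation within a family,
pseudoknot statistics beyond the nested/non-nested flag, and the long-tailed
family-size distribution of real MSA databases. Passing tests demonstrate
that the mechanism recovers planted covariation; they do not calibrate
absolute performance on real RNA families, where contacts are denser, the
coupling structure is weaker and heterogeneous, and alignment depth varies
by orders of magnitude.

## Numerical choices and degenerate inputs

* The autodiff layer accumulates gradients in float64; attention logit
  masking uses an additive −10⁹ rather than −∞ to keep softmax gradients
  finite. Non-finite activations raise with the offending block index.
* Checkpoints use a fixed byte layout (magic string, sorted JSON header,
  raw float64 arrays in name order) so identical states produce identical
  files — zip-based containers embed timestamps and would break the
  bit-reproducibility guarantee.
* All randomness flows through named streams derived from one run seed
  (CRC-based child seeds below 2³¹), so every artifact can be regenerated
  bit-identically from its persisted config; xgboost runs single-threaded
  with `tree_method="exact"` for the same reason.
* Degenerate cases: empty inpainting masks report an absent loss; columns of
  special tokens fall back to uniform bootstrap profiles; crop/subsample
  clamps at grid bounds and always keeps the query; an all-tie score matrix
  ranks lexicographically; single-class labels are rejected by the boosted
  head; a single-family batch is rejected by the contrastive loss.

## Known limitations

* The backbone runs on numpy; it is adequate for desk-scale models
  (hundreds of steps, E ≤ a few hundred, L ≤ a few hundred) but not for
  full-scale pre-training on thousands of families.
* Column attention is quadratic in E; the fine-tuning path bounds this by
  row subsampling rather than attention sparsification.
* Probabilities are not recalibrated after boosting or fine-tuning;
  threshold-based metrics on the DCA baseline are not meaningful (its
  scores are rankings, not probabilities), which is why top-L precision is
  the primary cross-method metric.
* mmCIF assemblies are not expanded; contacts are computed within one chain
  of the first model.
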