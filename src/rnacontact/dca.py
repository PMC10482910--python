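"""Mean-field direct coupling analysis (DCA) over an RNA alignment.

The classical covariation baseline: fit a generalized Potts model to the MSA
in the mean-field approximation and rank pairs by the strength of their
direct coupling.  Steps:

1. identity-based sequence reweighting (weight 1/m, m = number of sequences
   at or above the identity threshold, self included; M_eff = Σ weights);
2. pseudocount-regularised single-site and pair frequencies over the q=5
   alphabet (A, C, G, U, gap);
3. couplings e = −C⁻¹ where C is the connected-correlation matrix, gauge
   fixed by dropping the gap state at every site;
4. per-pair Frobenius norm over the non-gap coupling block, followed by the
   average product correction (APC).

Exposed both as the :class:`MeanFieldDCA` estimator (``fit`` then
``contact_scores()``) and as the underlying functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import ContactScores
from .msa import DEFAULT_VOCAB, Msa, TokenGrid, tokenize

__all__ = [
    "SiteFrequencies",
    "sequence_weights",
    "site_frequencies",
    "mf_coupling_scores",
    "rank_pairs",
    "MeanFieldDCA",
]

Q = 5  # A, C, G, U, gap


def _dca_states(grid: TokenGrid) -> np.ndarray:
    """Map the token grid onto the DCA alphabet: nucleotides 0..3, all else gap."""
    v = grid.values
    out = np.where(v <= 3, v, 4)
    return out.astype(np.int64)


def sequence_weights(grid: TokenGrid, identity_threshold: float = 0.8):
    """Identity-based reweighting; returns (weights, M_eff).

    A sequence's weight is 1 / #{rows with fractional identity >= threshold},
    counting itself, so k identical copies weigh 1/k each."""
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    s = _dca_states(grid)
    E, L = s.shape
    counts = np.zeros(E)
    # blockwise all-pairs identity to bound memory
    block = max(1, 2**22 // max(1, E * L))
    for start in range(0, E, block):
        chunk = s[start:start + block]          # (b, L)
        ident = (chunk[:, None, :] == s[None, :, :]).mean(axis=2)  # (b, E)
        counts[start:start + block] = (ident >= identity_threshold).sum(axis=1)
    weights = 1.0 / counts
    return weights, float(weights.sum())


@dataclass
class SiteFrequencies:
    """Regularised weighted frequencies of a Potts model fit."""

    f1: np.ndarray          # (L, q)
    f2: np.ndarray          # (L, L, q, q), pair frequencies for i != j
    weights: np.ndarray
    m_eff: float
    pseudocount: float
    q: int = Q


def site_frequencies(grid: TokenGrid, weights: np.ndarray, pseudocount: float) -> SiteFrequencies:
    """Weighted single/pair frequencies with pseudocount mixing.

    With α = λ/(λ + M_eff): f1 ← (1−α)·f1 + α/q and, for i≠j,
    f2 ← (1−α)·f2 + α/q²."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    s = _dca_states(grid)
    E, L = s.shape
    weights = np.asarray(weights, dtype=float)
    m_eff = weights.sum()
    one_hot = np.zeros((E, L, Q))
    one_hot[np.arange(E)[:, None], np.arange(L)[None, :], s] = 1.0
    wh = one_hot * weights[:, None, None]
    f1 = wh.sum(axis=0) / m_eff                                   # (L, q)
    f2 = np.einsum("elq,emr->lmqr", wh, one_hot) / m_eff          # (L, L, q, q)
    alpha = pseudocount / (pseudocount + m_eff)
    f1 = (1 - alpha) * f1 + alpha / Q
    f2 = (1 - alpha) * f2 + alpha / (Q * Q)
    return SiteFrequencies(f1, f2, weights, float(m_eff), pseudocount)


def _apc(S: np.ndarray) -> np.ndarray:
    """Average product correction over the off-diagonal entries."""
    L = S.shape[0]
    np.fill_diagonal(S, 0.0)
    row = S.sum(axis=1) / (L - 1)
    total = S.sum() / (L * (L - 1))
    corrected = S - np.outer(row, row) / total
    np.fill_diagonal(corrected, 0.0)
    return corrected


def mf_coupling_scores(freqs: SiteFrequencies, apc: bool = True) -> np.ndarray:
    """Mean-field couplings and APC-corrected Frobenius pair scores (L×L).

    Gauge: the gap state is dropped at every site before building and
    inverting the connected-correlation matrix, so the couplings (and the
    Frobenius norm) live on the nucleotide states only."""
    L, q = freqs.f1.shape
    r = q - 1  # retained states per site (gap dropped)
    f1 = freqs.f1[:, :r]                                # (L, r)
    f2 = freqs.f2[:, :, :r, :r]                         # (L, L, r, r)
    C = f2 - np.einsum("iq,jr->ijqr", f1, f1)
    # site-diagonal blocks use f_ii(a,b) = delta_ab f_i(a)
    for i in range(L):
        C[i, i] = np.diag(f1[i]) - np.outer(f1[i], f1[i])
    Cm = C.transpose(0, 2, 1, 3).reshape(L * r, L * r)
    try:
        e = -np.linalg.inv(Cm)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is singular; increase the pseudocount"
        ) from err
    eb = e.reshape(L, r, L, r)
    S = np.sqrt(np.einsum("iajb,iajb->ij", eb, eb))
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)
    return _apc(S) if apc else S


def rank_pairs(scores: np.ndarray, min_separation: int = 4) -> list:
    """Included upper-triangle pairs in descending score order.

    Ties break lexicographically on (i, j)."""
    L = scores.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    keep = (ju - iu) >= min_separation
    iu, ju = iu[keep], ju[keep]
    s = scores[iu, ju]
    order = np.lexsort((ju, iu, -s))
    return [(int(i), int(j)) for i, j in zip(iu[order], ju[order])]


class MeanFieldDCA(BaseEstimator):
    """Mean-field DCA as an sklearn-style estimator.

    Parameters
    ----------
    identity_threshold : float
        Sequence-reweighting identity cutoff (fraction of identical columns).
    pseudocount : float or "meff"
        Regularisation strength λ; the default ``"meff"`` uses λ = M_eff
        (strong regularisation, the standard mean-field choice).
    apc : bool
        Apply the average product correction to the Frobenius scores.
    min_separation : int
        Pairs closer than this along the chain are excluded from ranking.
    """

    def __init__(self, identity_threshold: float = 0.8, pseudocount="meff",
                 apc: bool = True, min_separation: int = 4):
        self.identity_threshold = identity_threshold
        self.pseudocount = pseudocount
        self.apc = apc
        self.min_separation = min_separation

    def fit(self, X, y=None):
        """Fit on an :class:`Msa` or :class:`TokenGrid`."""
        grid = tokenize(X, DEFAULT_VOCAB) if isinstance(X, Msa) else X
        weights, m_eff = sequence_weights(grid, self.identity_threshold)
        lam = m_eff if self.pseudocount == "meff" else float(self.pseudocount)
        freqs = site_frequencies(grid, weights, lam)
        self.weights_ = weights
        self.m_eff_ = m_eff
        self.frequencies_ = freqs
        self.scores_ = mf_coupling_scores(freqs, apc=self.apc)
        self.n_features_in_ = grid.length
        return self

    def contact_scores(self) -> ContactScores:
        return ContactScores(self.scores_, self.min_separation)

    def ranked_pairs(self) -> list:
        return rank_pairs(self.scores_, self.min_separation)
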