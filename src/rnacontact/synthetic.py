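"""Planted-contact Potts families: the desk-scale synthetic test bed.

Families are sampled from a generalized Potts model over the four
nucleotides whose pairwise couplings are nonzero only on a planted set of
contact pairs; the couplings reward Watson–Crick complementary combinations
(A-U, U-A, G-C, C-G, optionally the G-U wobble), so planted columns covary
the way base-paired alignment columns do.  The planted pairs are the exact
ground-truth contact labels.

Rows are drawn by Gibbs sampling.  By default each row comes from its own
independent chain (burn-in sweeps, then one sample), making rows i.i.d.;
phylogenetic relatedness is deliberately not modelled.  Setting ``n_chains``
below E instead takes thinned sweeps from fewer chains.

Default family conditions: L=30, E=300, 5 planted pairs, coupling strength
β=3, minimum separation 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa import Msa
from .structure import ContactLabels

__all__ = [
    "PottsModel",
    "SyntheticFamily",
    "sample_pair_topology",
    "build_potts",
    "sample_msa",
    "make_family",
    "emit_dataset",
    "enumerate_boltzmann",
    "DEFAULTS",
]

NUCLEOTIDES = "ACGU"
Q = 4
# complementary state combinations rewarded by the planted couplings
WATSON_CRICK = [(0, 3), (3, 0), (1, 2), (2, 1)]  # A-U, U-A, C-G, G-C
WOBBLE = [(2, 3), (3, 2)]                        # G-U, U-G

DEFAULTS = dict(L=30, E=300, n_pairs=5, beta=3.0, min_separation=4)


@dataclass
class PottsModel:
    """Fields h and planted pairwise couplings J (stored for i < j)."""

    L: int
    q: int
    h: np.ndarray                 # (L, q)
    J: dict                       # {(i, j): (q, q) array}, i < j
    planted_pairs: list           # [(i, j), ...] i < j
    min_separation: int
    beta: float

    def __post_init__(self):
        for (i, j), mat in self.J.items():
            if not (0 <= i < j < self.L):
                raise ValueError("couplings must be stored with 0 <= i < j < L")
            if mat.shape != (self.q, self.q):
                raise ValueError("coupling block shape mismatch")
        for i, j in self.planted_pairs:
            if j - i < self.min_separation:
                raise ValueError("planted pair violates minimum separation")

    def coupling(self, i: int, j: int) -> np.ndarray:
        """J_ij with the symmetry J_ij(a,b) = J_ji(b,a)."""
        if i < j:
            return self.J.get((i, j), np.zeros((self.q, self.q)))
        return self.J.get((j, i), np.zeros((self.q, self.q))).T

    def energy(self, state: np.ndarray) -> float:
        """Negative log-probability up to the partition constant."""
        e = sum(self.h[i, state[i]] for i in range(self.L))
        e += sum(mat[state[i], state[j]] for (i, j), mat in self.J.items())
        return float(e)


@dataclass
class SyntheticFamily:
    msa: Msa
    labels: ContactLabels
    truth: PottsModel
    seed: int = 0


def _crosses(p, q) -> bool:
    (i, j), (k, l) = sorted([p, q])
    return i < k < j < l


def sample_pair_topology(L: int, n_pairs: int, min_separation: int = 4,
                         nested: bool = False, seed: int = 0) -> list:
    """Draw disjoint planted pairs, optionally non-crossing (nested).

    Each index participates in at most one pair; ``nested`` forbids
    crossings i<k<j<l, mimicking RNA secondary structure."""
    rng = np.random.default_rng(seed)
    candidates = [(i, j) for i in range(L) for j in range(i + min_separation, L)]
    for _ in range(200):
        order = rng.permutation(len(candidates))
        chosen, used = [], set()
        for idx in order:
            i, j = candidates[idx]
            if i in used or j in used:
                continue
            if nested and any(_crosses((i, j), c) for c in chosen):
                continue
            chosen.append((i, j))
            used.update((i, j))
            if len(chosen) == n_pairs:
                return sorted(chosen)
    raise ValueError(
        f"could not place {n_pairs} pairs with L={L}, min_separation={min_separation}"
        f"{', nested' if nested else ''}"
    )


def build_potts(pairs, beta: float, seed: int = 0, L: int | None = None,
                min_separation: int = 4, field_scale: float = 0.1,
                wobble: bool = False) -> PottsModel:
    """Potts model with complementarity-rewarding couplings on the pairs.

    β=0 gives an independent-columns model; the wobble pair (G-U) is
    rewarded at β/2 when enabled.  Fields are small i.i.d. normal draws."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    pairs = sorted(tuple(p) for p in pairs)
    if L is None:
        L = max((j for _, j in pairs), default=0) + 1
    rng = np.random.default_rng(seed)
    h = rng.normal(0.0, field_scale, size=(L, Q))
    block = np.zeros((Q, Q))
    for a, b in WATSON_CRICK:
        block[a, b] = beta
    if wobble:
        for a, b in WOBBLE:
            block[a, b] = beta / 2.0
    J = {(i, j): block.copy() for i, j in pairs} if beta > 0 else {}
    return PottsModel(L, Q, h, J, list(pairs), min_separation, beta)


def _gibbs_sweep(model: PottsModel, states: np.ndarray, rng: np.random.Generator,
                 partners: list) -> None:
    """One sequential-site Gibbs sweep, vectorised across chains (in place)."""
    n = states.shape[0]
    for i in range(model.L):
        logits = np.broadcast_to(model.h[i], (n, Q)).copy()
        for j, mat in partners[i]:
            logits += mat[:, states[:, j]].T
        g = rng.gumbel(size=(n, Q))
        states[:, i] = np.argmax(logits + g, axis=1)


def sample_msa(model: PottsModel, E: int, burn_in: int = 100, thinning: int = 10,
               seed: int = 0, n_chains: int | None = None,
               family_id: str = "synthetic") -> Msa:
    """Gibbs-sample E aligned rows from the Potts model.

    With the default ``n_chains=E`` every row is the state of its own chain
    after ``burn_in`` sweeps (rows i.i.d.); with fewer chains, rows are
    thinned sweeps (every ``thinning``-th) taken after burn-in."""
    if E < 1:
        raise ValueError("E must be >= 1")
    rng = np.random.default_rng(seed)
    if n_chains is None:
        n_chains = E
    n_chains = min(n_chains, E)
    # partner list per site: (other site, coupling matrix oriented as J(a, s_other))
    partners = [[] for _ in range(model.L)]
    for (i, j), mat in model.J.items():
        partners[i].append((j, mat))
        partners[j].append((i, mat.T))
    states = rng.integers(0, Q, size=(n_chains, model.L))
    for _ in range(burn_in):
        _gibbs_sweep(model, states, rng, partners)
    rows = [states.copy()]
    n_rounds = -(-E // n_chains) - 1
    for _ in range(n_rounds):
        for _ in range(thinning):
            _gibbs_sweep(model, states, rng, partners)
        rows.append(states.copy())
    samples = np.concatenate(rows, axis=0)[:E]
    seqs = ["".join(NUCLEOTIDES[a] for a in row) for row in samples]
    ids = [f"seq{i:04d}" for i in range(E)]
    return Msa(seqs, ids, family_id=family_id, query_index=0)


def planted_labels(model: PottsModel) -> ContactLabels:
    matrix = np.zeros((model.L, model.L), dtype=np.int8)
    for i, j in model.planted_pairs:
        matrix[i, j] = matrix[j, i] = 1
    return ContactLabels(matrix, model.min_separation, threshold_angstrom=0.0)


def make_family(seed: int, L: int = DEFAULTS["L"], E: int = DEFAULTS["E"],
                n_pairs: int = DEFAULTS["n_pairs"], beta: float = DEFAULTS["beta"],
                min_separation: int = DEFAULTS["min_separation"],
                nested: bool = False, burn_in: int = 100, thinning: int = 10,
                n_chains: int | None = None,
                family_id: str | None = None) -> SyntheticFamily:
    """One planted-contact family with exact labels, fully seed-determined."""
    family_id = family_id or f"SYN{seed:05d}"
    pairs = sample_pair_topology(L, n_pairs, min_separation, nested, seed=seed)
    model = build_potts(pairs, beta, seed=seed + 1, L=L, min_separation=min_separation)
    msa = sample_msa(model, E, burn_in, thinning, seed=seed + 2,
                     n_chains=n_chains, family_id=family_id)
    return SyntheticFamily(msa, planted_labels(model), model, seed)


def enumerate_boltzmann(model: PottsModel) -> np.ndarray:
    """Exact Boltzmann distribution over all q^L states (oracle, L <= 3-ish)."""
    if model.L > 8:
        raise ValueError("exact enumeration is only for tiny models")
    shape = (Q,) * model.L
    logp = np.zeros(shape)
    for i in range(model.L):
        idx = [None] * model.L
        idx[i] = slice(None)
        logp += model.h[i][tuple(idx)]
    for (i, j), mat in model.J.items():
        expand = [None] * model.L
        expand[i] = slice(None)
        expand[j] = slice(None)
        # place the (q, q) block on axes (i, j)
        view = np.zeros(shape)
        mov = np.moveaxis(view, (i, j), (0, 1))
        mov += mat.reshape((Q, Q) + (1,) * (model.L - 2))
        logp += view
    p = np.exp(logp - logp.max())
    return p / p.sum()


def emit_dataset(out_dir, n_train: int = 8, n_test: int = 4,
                 L_range=(30, 30), E_range=(300, 300),
                 beta: float = DEFAULTS["beta"],
                 n_pairs: int = DEFAULTS["n_pairs"],
                 min_separation: int = DEFAULTS["min_separation"],
                 seed: int = 0, overwrite: bool = False) -> Path:
    """Write a train/test split of synthetic families to disk.

    Each family directory holds ``alignment.sto``, ``labels.txt`` and
    ``truth.json``; ``manifest.tsv`` records the split and per-family seeds.
    Regeneration under the same seed is bitwise identical."""
    from .msa import write_stockholm
    from .structure import write_labels

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{out} is not empty (pass overwrite=True)")
    out.mkdir(parents=True, exist_ok=True)
    manifest = ["split\tfamily\tseed\tL\tE\tn_pairs\tbeta"]
    rng = np.random.default_rng(seed)
    idx = 0
    for split, n in (("train", n_train), ("test", n_test)):
        for _ in range(n):
            fam_seed = int(rng.integers(0, 2**31 - 1000))
            L = int(rng.integers(L_range[0], L_range[1] + 1))
            E = int(rng.integers(E_range[0], E_range[1] + 1))
            fam_id = f"SYN{idx:04d}"
            fam = make_family(fam_seed, L=L, E=E, n_pairs=n_pairs, beta=beta,
                              min_separation=min_separation, family_id=fam_id)
            fam_dir = out / split / fam_id
            fam_dir.mkdir(parents=True, exist_ok=True)
            write_stockholm(fam.msa, fam_dir / "alignment.sto")
            write_labels(fam.labels, fam_dir / "labels.txt")
            truth = {
                "family_id": fam_id, "seed": fam_seed, "L": L, "E": E,
                "beta": beta, "n_pairs": n_pairs,
                "min_separation": min_separation,
                "planted_pairs": [[int(i), int(j)] for i, j in fam.truth.planted_pairs],
            }
            (fam_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
            manifest.append(f"{split}\t{fam_id}\t{fam_seed}\t{L}\t{E}\t{n_pairs}\t{beta:g}")
            idx += 1
    (out / "manifest.tsv").write_text("\n".join(manifest) + "\n")
    return out
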