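"""Binary contact labels: derivation from 3D structures and projection onto
alignment columns.

A contact map is the symmetric L×L binary matrix marking residue pairs whose
minimal heavy-atom distance falls below a cutoff; near-diagonal pairs (and
pairs touching unresolved residues or query gaps) are excluded from both
training and evaluation via ``excluded_mask``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .msa import Msa

logger = logging.getLogger(__name__)

__all__ = [
    "ContactLabels",
    "contacts_from_structure",
    "project_to_query",
    "separation_mask",
    "write_labels",
    "read_labels",
]

DEFAULT_THRESHOLD = 10.0  # minimal heavy-atom distance cutoff, Angstrom
DEFAULT_MIN_SEPARATION = 4  # |i - j| below this is excluded


def separation_mask(L: int, min_separation: int) -> np.ndarray:
    """Boolean L×L mask, True where |i-j| < min_separation (excluded)."""
    idx = np.arange(L)
    return np.abs(idx[:, None] - idx[None, :]) < min_separation


@dataclass
class ContactLabels:
    """Symmetric binary ground truth with an exclusion mask."""

    matrix: np.ndarray
    min_separation: int = DEFAULT_MIN_SEPARATION
    threshold_angstrom: float = DEFAULT_THRESHOLD
    excluded_mask: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        L = self.matrix.shape[0]
        if self.matrix.shape != (L, L):
            raise ValueError("label matrix must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("label matrix must be symmetric")
        if np.any(np.diag(self.matrix)):
            raise ValueError("label matrix must have a zero diagonal")
        sep = separation_mask(L, self.min_separation)
        if self.excluded_mask is None:
            self.excluded_mask = sep
        else:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool) | sep
        # excluded pairs carry no label
        self.matrix = np.where(self.excluded_mask, 0, self.matrix).astype(np.int8)

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    def included_pairs(self) -> np.ndarray:
        """Upper-triangle (i, j) pairs that carry a label, lexicographic."""
        L = self.L
        iu, ju = np.triu_indices(L, k=1)
        keep = ~self.excluded_mask[iu, ju]
        return np.stack([iu[keep], ju[keep]], axis=1)


def _heavy_atom_coords(residue) -> np.ndarray:
    coords = [a.coord for a in residue.get_atoms() if a.element != "H"]
    return np.asarray(coords, dtype=float)


def _load_chain(structure_path: str, chain_id: str):
    from Bio.PDB import MMCIFParser, PDBParser

    path = str(structure_path)
    if path.endswith((".cif", ".mmcif")):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    for chain in model:
        if chain.id == chain_id:
            return chain
    raise KeyError(f"chain {chain_id!r} not found in {structure_path}")


def contacts_from_structure(
    structure_path,
    chain: str,
    threshold_angstrom: float = DEFAULT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactLabels:
    """Derive contact labels from a PDB/mmCIF chain.

    Pair (i, j) is a contact iff the minimal distance between any two heavy
    atoms of the residues is below ``threshold_angstrom``.  Residues without
    coordinates are marked excluded (and logged); hetero/water records are
    skipped.
    """
    ch = _load_chain(structure_path, chain)
    residues = [r for r in ch.get_residues() if r.id[0] == " "]
    L = len(residues)
    coords = [_heavy_atom_coords(r) for r in residues]
    unresolved = np.array([c.shape[0] == 0 for c in coords])
    for r, bad in zip(residues, unresolved):
        if bad:
            logger.warning("residue %s has no heavy-atom coordinates; excluded", r.id)
    matrix = np.zeros((L, L), dtype=np.int8)
    for i in range(L):
        if unresolved[i]:
            continue
        for j in range(i + 1, L):
            if unresolved[j]:
                continue
            if cdist(coords[i], coords[j]).min() < threshold_angstrom:
                matrix[i, j] = matrix[j, i] = 1
    excluded = unresolved[:, None] | unresolved[None, :]
    return ContactLabels(matrix, min_separation, threshold_angstrom, excluded)


def project_to_query(labels: ContactLabels, msa: Msa) -> ContactLabels:
    """Re-index structure-residue labels to the query's alignment columns.

    Columns where the query carries a gap are excluded; contacts involving a
    residue aligned to a query gap cannot occur (residue positions map 1:1 to
    non-gap columns), so none are dropped by the map itself.
    """
    query = msa.query
    positions = [c for c, ch in enumerate(query) if ch != "-"]
    if len(positions) != labels.L:
        raise ValueError(
            f"ungapped query length {len(positions)} != label size {labels.L}"
        )
    L = len(query)
    matrix = np.zeros((L, L), dtype=np.int8)
    excluded = np.ones((L, L), dtype=bool)
    pos = np.asarray(positions)
    matrix[np.ix_(pos, pos)] = labels.matrix
    sub = excluded[np.ix_(pos, pos)]
    sub[...] = labels.excluded_mask
    excluded[np.ix_(pos, pos)] = sub
    n_dropped = int(labels.matrix.sum() // 2 - matrix.sum() // 2)
    if n_dropped:
        logger.info("dropped %d contacts at query gaps", n_dropped)
    return ContactLabels(matrix, labels.min_separation, labels.threshold_angstrom, excluded)


def write_labels(labels: ContactLabels, path) -> None:
    """Plain-text serialisation: 3 header lines (L, threshold, min_separation)
    then L rows of 0/1 (excluded pairs written as '.')."""
    with open(path, "w") as fh:
        fh.write(f"L {labels.L}\n")
        fh.write(f"threshold_angstrom {labels.threshold_angstrom:g}\n")
        fh.write(f"min_separation {labels.min_separation}\n")
        for i in range(labels.L):
            row = [
                "." if labels.excluded_mask[i, j] else str(int(labels.matrix[i, j]))
                for j in range(labels.L)
            ]
            fh.write("".join(row) + "\n")


def read_labels(path) -> ContactLabels:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    L = int(lines[0].split()[1])
    threshold = float(lines[1].split()[1])
    min_sep = int(lines[2].split()[1])
    matrix = np.zeros((L, L), dtype=np.int8)
    excluded = np.zeros((L, L), dtype=bool)
    for i, ln in enumerate(lines[3 : 3 + L]):
        for j, ch in enumerate(ln):
            if ch == ".":
                excluded[i, j] = True
            else:
                matrix[i, j] = int(ch)
    return ContactLabels(matrix, min_sep, threshold, excluded)
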