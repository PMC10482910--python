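"""CASP-RR-style contact record output.

Records are ``i j 0 <threshold> <p>`` with 1-based residue indices, i < j,
sorted by descending probability (ties lexicographic on the pair); the
header carries the query sequence.  All methods (learned heads and the DCA
baseline) emit this same format so evaluation is uniform.
"""

from __future__ import annotations

import numpy as np

from .metrics import ContactScores

__all__ = ["write_rr", "read_rr", "rr_to_scores"]


def write_rr(scores: ContactScores, query: str, path,
             threshold_angstrom: float = 10.0) -> None:
    L = scores.L
    iu, ju = np.triu_indices(L, k=1)
    keep = ~scores.excluded_mask[iu, ju]
    iu, ju = iu[keep], ju[keep]
    p = scores.matrix[iu, ju]
    order = np.lexsort((ju, iu, -p))
    with open(path, "w") as fh:
        fh.write("PFRMAT RR\n")
        fh.write(f"SEQRES {query}\n")
        for k in order:
            fh.write(f"{iu[k] + 1} {ju[k] + 1} 0 {threshold_angstrom:g} {p[k]:.6f}\n")
        fh.write("END\n")


def read_rr(path):
    """Returns (query sequence, list of (i, j, p) with 0-based i < j)."""
    query, records = "", []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line in ("PFRMAT RR", "END"):
                continue
            if line.startswith("SEQRES"):
                query = line.split(maxsplit=1)[1] if " " in line else ""
                continue
            i, j, _, _, p = line.split()
            records.append((int(i) - 1, int(j) - 1, float(p)))
    return query, records


def rr_to_scores(path, L: int, min_separation: int = 4) -> ContactScores:
    _, records = read_rr(path)
    m = np.zeros((L, L))
    for i, j, p in records:
        m[i, j] = m[j, i] = p
    return ContactScores(m, min_separation)
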