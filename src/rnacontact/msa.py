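"""Aligned RNA families: reading, tokenization and pre-processing.

An :class:`Msa` is an aligned family of homologous RNA sequences (rows) over
``{A, C, G, U, -}`` plus IUPAC ambiguity codes; a :class:`TokenGrid` is its
integer form over a fixed vocabulary, the input to the attention backbone and
to the coupling-analysis baseline.  ``L`` is the alignment length and ``E``
the evolutionary dimension (number of rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "Vocabulary",
    "DEFAULT_VOCAB",
    "Msa",
    "TokenGrid",
    "read_stockholm",
    "write_stockholm",
    "read_fasta",
    "tokenize",
    "detokenize",
    "crop_and_subsample",
]

# IUPAC nucleotide ambiguity codes (plus T, normalised to U on input).
AMBIGUITY = set("RYSWKMBDHVN")


class MsaError(ValueError):
    """Raised on malformed alignments or invariant violations."""


@dataclass(frozen=True)
class Vocabulary:
    """Bijection between characters and token ids.

    Canonical order: A, C, G, U, gap, then the special tokens UNK (ambiguity
    codes), MASK (inpainting) and PAD.
    """

    chars: tuple = ("A", "C", "G", "U", "-", "?", "*", "_")  # ?=UNK, *=MASK, _=PAD

    @property
    def size(self) -> int:
        return len(self.chars)

    @property
    def gap_id(self) -> int:
        return 4

    @property
    def unk_id(self) -> int:
        return 5

    @property
    def mask_id(self) -> int:
        return 6

    @property
    def pad_id(self) -> int:
        return 7

    @property
    def nucleotide_ids(self) -> tuple:
        return (0, 1, 2, 3)

    @property
    def legal_ids(self) -> tuple:
        """Non-special tokens an augmentation may write: A, C, G, U, gap."""
        return (0, 1, 2, 3, 4)

    def encode_char(self, c: str) -> int:
        c = c.upper()
        if c == ".":
            c = "-"
        if c == "T":
            c = "U"
        try:
            return self.chars.index(c)
        except ValueError:
            if c in AMBIGUITY:
                return self.unk_id
            raise MsaError(f"character {c!r} is not a nucleotide, gap or ambiguity code")

    def decode_id(self, i: int) -> str:
        return self.chars[i]


DEFAULT_VOCAB = Vocabulary()


@dataclass
class Msa:
    """An aligned RNA family.

    ``query_index`` marks the reference row whose (ungapped) sequence the
    contact labels refer to.
    """

    rows: list
    ids: list
    family_id: str = ""
    query_index: int = 0

    def __post_init__(self):
        if len(self.rows) == 0:
            raise MsaError("alignment must contain at least one row")
        L = len(self.rows[0])
        if L < 1:
            raise MsaError("alignment length must be >= 1")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise MsaError(
                    f"ragged alignment: row {rid!r} has length {len(row)}, expected {L}"
                )
        if len(self.ids) != len(self.rows):
            raise MsaError("ids and rows must have equal length")
        if not (0 <= self.query_index < len(self.rows)):
            raise MsaError("query_index out of range")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[self.query_index]

    def ungapped_query(self) -> str:
        return self.query.replace("-", "")


@dataclass
class TokenGrid:
    """E×L integer form of an alignment over a fixed vocabulary."""

    values: np.ndarray
    vocab: Vocabulary = field(default_factory=lambda: DEFAULT_VOCAB)
    family_id: str = ""
    query_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise MsaError("token grid must be 2-D (E, L)")
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) >= self.vocab.size:
            raise MsaError("token id outside vocabulary range")

    @property
    def depth(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "TokenGrid":
        return TokenGrid(self.values.copy(), self.vocab, self.family_id, self.query_index)


def _normalize_row(seq: str) -> str:
    s = seq.upper().replace(".", "-")
    if "T" in s:
        warnings.warn("sequence contains 'T'; reading as 'U'", stacklevel=3)
        s = s.replace("T", "U")
    return s


def _from_biopython(aln: MultipleSeqAlignment, family_id: str = "") -> Msa:
    return Msa(
        rows=[_normalize_row(str(rec.seq)) for rec in aln],
        ids=[rec.id for rec in aln],
        family_id=family_id,
    )


def _scan_accessions(path) -> list:
    """Per-alignment-block ``#=GF AC``/``ID`` values (AlignIO drops them)."""
    accs, current = [], ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#=GF AC") or (line.startswith("#=GF ID") and not current):
                parts = line.split(maxsplit=2)
                if len(parts) == 3:
                    current = parts[2].strip()
            elif line.strip() == "//":
                accs.append(current)
                current = ""
    return accs


def read_stockholm(path) -> list:
    """Read all alignment blocks of a Stockholm 1.0 file.

    Interleaved blocks of the same alignment are concatenated; ``.`` gaps are
    normalised to ``-`` and ``T`` to ``U``; ``#=GF AC`` becomes family_id.
    """
    try:
        alns = list(AlignIO.parse(str(path), "stockholm"))
    except ValueError as e:
        raise MsaError(f"malformed Stockholm file {path}: {e}") from e
    if not alns:
        raise MsaError(f"no alignments found in {path}")
    accs = _scan_accessions(path)
    accs += [""] * (len(alns) - len(accs))
    return [_from_biopython(a, acc) for a, acc in zip(alns, accs)]


def write_stockholm(msa: Msa, path) -> None:
    """Write one alignment in Stockholm 1.0 (row order and ids preserved)."""
    width = max(len(i) for i in msa.ids) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        if msa.family_id:
            fh.write(f"#=GF AC {msa.family_id}\n")
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f"{rid:<{width}}{row}\n")
        fh.write("//\n")


def read_fasta(path, family_id: str = "") -> Msa:
    """Read an aligned FASTA file into an Msa (all rows must align)."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as e:
        raise MsaError(f"malformed aligned FASTA {path}: {e}") from e
    m = _from_biopython(aln)
    if family_id:
        m.family_id = family_id
    return m


def tokenize(msa: Msa, vocab: Vocabulary = DEFAULT_VOCAB) -> TokenGrid:
    """Integer-encode an alignment; ambiguity codes map to the UNK token."""
    grid = np.empty((msa.depth, msa.length), dtype=np.int64)
    for i, row in enumerate(msa.rows):
        grid[i] = [vocab.encode_char(c) for c in row]
    return TokenGrid(grid, vocab, msa.family_id, msa.query_index)


def detokenize(grid: TokenGrid, ids=None) -> Msa:
    """Inverse of :func:`tokenize` up to ambiguity canonicalisation."""
    rows = ["".join(grid.vocab.decode_id(i) for i in r) for r in grid.values]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(rows))]
    return Msa(rows, list(ids), grid.family_id, grid.query_index)


def crop_and_subsample(grid: TokenGrid, max_L: int, max_E: int, seed: int) -> TokenGrid:
    """Contiguous column crop and row subsample, always keeping the query.

    The crop window start is uniform over valid positions; rows other than
    the query are drawn uniformly without replacement.  The query ends up as
    row 0 of the result.  Deterministic under ``seed``; a no-op (up to moving
    the query to row 0) when the grid already satisfies both limits.
    """
    if max_L < 1 or max_E < 1:
        raise MsaError("max_L and max_E must be >= 1")
    rng = np.random.default_rng(seed)
    E, L = grid.values.shape
    # column crop
    if L > max_L:
        start = int(rng.integers(0, L - max_L + 1))
        cols = slice(start, start + max_L)
    else:
        cols = slice(0, L)
    # row subsample (query always retained, placed first)
    others = [i for i in range(E) if i != grid.query_index]
    if E > max_E:
        keep = rng.choice(len(others), size=max_E - 1, replace=False)
        rows = [grid.query_index] + [others[i] for i in sorted(keep)]
    else:
        rows = [grid.query_index] + others
    out = grid.values[np.asarray(rows)][:, cols]
    return TokenGrid(out, grid.vocab, grid.family_id, query_index=0)
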