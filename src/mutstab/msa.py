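"""Alignment container and sequence reweighting for co-variation analysis.

Alignments are held as integer matrices over a 21-state alphabet (20 amino
acids + gap) with a designated query row. A2M input keeps match columns
(uppercase / ``-``) and drops insert states (lowercase / ``.``); plain
FASTA is treated as all-match. Redundant rows are down-weighted by the
standard 1/(number of neighbours at ≥ θ identity) scheme, giving the
effective sequence count Meff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

PROTEIN_GAP_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

__all__ = ["PROTEIN_GAP_ALPHABET", "Msa", "SequenceWeights", "read_alignment", "compute_weights"]


class Msa:
    """An aligned set of sequences with a query row and column→position map."""

    def __init__(
        self,
        sequences,
        ids=None,
        alphabet: str = PROTEIN_GAP_ALPHABET,
        query_index: int = 0,
        column_map: dict[int, int] | None = None,
    ):
        if isinstance(sequences, np.ndarray):
            matrix = np.asarray(sequences, dtype=np.int64)
        else:
            sequences = [str(s).upper() for s in sequences]
            if not sequences:
                raise ValueError("empty alignment")
            lengths = {len(s) for s in sequences}
            if len(lengths) != 1:
                raise ValueError(f"rows have differing lengths: {sorted(lengths)}")
            lookup = {c: i for i, c in enumerate(alphabet)}
            try:
                matrix = np.array([[lookup[c] for c in s] for s in sequences], dtype=np.int64)
            except KeyError as exc:
                raise ValueError(f"symbol {exc.args[0]!r} not in alphabet {alphabet!r}") from None
        if matrix.ndim != 2 or matrix.size == 0:
            raise ValueError("alignment matrix must be 2-D and non-empty")
        if matrix.min() < 0 or matrix.max() >= len(alphabet):
            raise ValueError("state indices outside the alphabet")
        self.matrix = matrix
        self.alphabet = alphabet
        self.ids = list(ids) if ids is not None else [f"seq{i}" for i in range(matrix.shape[0])]
        if not 0 <= query_index < matrix.shape[0]:
            raise ValueError("query_index outside the alignment")
        self.query_index = query_index
        if column_map is None:
            column_map = self._default_column_map()
        self.column_map = dict(column_map)
        self._pos_to_col = {pos: col for col, pos in self.column_map.items()}
        gap = alphabet.index("-") if "-" in alphabet else None
        if gap is not None:
            for col in self.column_map:
                if self.matrix[self.query_index, col] == gap:
                    raise ValueError(f"query row is gapped at mapped column {col}")

    def _default_column_map(self) -> dict[int, int]:
        """Map non-gap query columns to 1-based reference positions, in order."""
        gap = self.alphabet.index("-") if "-" in self.alphabet else None
        cmap, pos = {}, 0
        for col in range(self.matrix.shape[1]):
            if gap is None or self.matrix[self.query_index, col] != gap:
                pos += 1
                cmap[col] = pos
        return cmap

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    def query_row(self) -> np.ndarray:
        return self.matrix[self.query_index]

    def sequence_str(self, row: int) -> str:
        return "".join(self.alphabet[i] for i in self.matrix[row])

    def column_for_position(self, position: int) -> int | None:
        """Alignment column for a 1-based reference position (None if unmapped)."""
        return self._pos_to_col.get(position)


def read_alignment(path, fmt: str = "fasta", query_id: str | None = None, alphabet: str = PROTEIN_GAP_ALPHABET) -> Msa:
    """Read a FASTA or A2M alignment.

    ``fmt="a2m"`` keeps only match states (uppercase and ``-``), dropping
    lowercase inserts and ``.``; ``fmt="fasta"`` treats every column as a
    match column. The query defaults to the first record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids = [r.id for r in records]
    raw = [str(r.seq) for r in records]
    if fmt == "a2m":
        # match columns are where the first sequence is uppercase or '-'
        keep = [i for i, c in enumerate(raw[0]) if c == "-" or c.isupper()]
        seqs = []
        for s in raw:
            match_chars = [c for c in s if c == "-" or c.isupper()]
            if len(match_chars) != len(keep):
                raise ValueError(f"A2M rows disagree on match-column count in {path}")
            seqs.append("".join(match_chars).upper())
    elif fmt == "fasta":
        seqs = [s.upper().replace(".", "-") for s in raw]
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    query_index = ids.index(query_id) if query_id is not None else 0
    return Msa(seqs, ids=ids, alphabet=alphabet, query_index=query_index)


@dataclass(frozen=True)
class SequenceWeights:
    """Per-sequence weights w_s = 1/|{s′ : identity(s, s′) ≥ θ}| and Meff."""

    weights: np.ndarray
    identity_threshold: float

    @property
    def m_eff(self) -> float:
        return float(self.weights.sum())


def compute_weights(msa: Msa, theta: float = 0.8, chunk: int = 512) -> SequenceWeights:
    """Identity-based down-weighting at threshold ``theta``.

    Identity is the fraction of equal symbols over *all* columns, gaps
    included. Each sequence counts itself as a neighbour, so weights lie
    in (0, 1] and Meff never exceeds the number of sequences.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must lie in (0, 1]")
    X = msa.matrix
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least 2 sequences to weight")
    neighbours = np.zeros(n, dtype=np.int64)
    # keep the (chunk, n, L) comparison block under ~200 MB
    chunk = max(1, min(chunk, int(2e8 // max(1, n * L))))
    for start in range(0, n, chunk):
        block = X[start : start + chunk]  # (c, L)
        ident = (block[:, None, :] == X[None, :, :]).mean(axis=2)  # (c, n)
        neighbours[start : start + chunk] = (ident >= theta).sum(axis=1)
    return SequenceWeights(weights=1.0 / neighbours, identity_threshold=theta)
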