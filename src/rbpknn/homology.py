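"""Protein sequence similarity.

Pairwise similarity between RBPs is global-alignment percent identity:
identical aligned positions divided by full alignment length (gap columns
included in the denominator, so the measure is symmetric and bounded in
[0, 1]). Alignments use BLOSUM62 with affine gaps (open 10, extend 0.5),
ClustalW-like defaults. These similarities serve both as KNN weights and as
the protein side of the mirror-tree co-evolution statistic.

Users with externally computed similarities (e.g. from an MSA) can inject
them via :func:`read_similarity_tsv` / :class:`SimilarityMatrix` directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import InputError
from .motifs import RBPRecord

__all__ = [
    "SimilarityMatrix",
    "pairwise_identity",
    "build_similarity_matrix",
    "rank_neighbors",
    "read_similarity_tsv",
    "write_similarity_tsv",
]

_SYMTOL = 1e-12


def _make_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    return _ALIGNER


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarity in [0, 1] with unit diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        values = np.asarray(self.values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise InputError("similarity matrix labels must be unique")
        if values.shape != (n, n):
            raise InputError(f"values shape {values.shape} does not match {n} labels")
        if np.any(values < -_SYMTOL) or np.any(values > 1 + _SYMTOL):
            raise InputError("similarity values must lie in [0, 1]")
        if np.max(np.abs(values - values.T)) > _SYMTOL:
            raise InputError("similarity matrix must be symmetric")
        if np.max(np.abs(np.diag(values) - 1.0)) > _SYMTOL:
            raise InputError("similarity matrix diagonal must be 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries as a flat vector (n*(n-1)/2)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reordered(self, labels: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity between two amino-acid sequences."""
    if not seq_a or not seq_b:
        raise InputError("cannot align an empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_a == seq_b:
        return 1.0
    alignment = _aligner().align(seq_a, seq_b)[0]
    top, bottom = str(alignment[0]), str(alignment[1])
    matches = sum(1 for x, y in zip(top, bottom) if x == y and x != "-")
    return matches / len(top)


def build_similarity_matrix(records: Sequence[RBPRecord]) -> SimilarityMatrix:
    """All-against-all percent identity over a set of RBP records."""
    if len(records) < 2:
        raise InputError("need at least 2 records")
    ids = [r.rbp_id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate rbp_ids in record list")
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pairwise_identity(records[i].aa_sequence, records[j].aa_sequence)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(tuple(ids), values)


def rank_neighbors(
    query: RBPRecord, homologs: Sequence[RBPRecord]
) -> list[tuple[str, float]]:
    """Homologs sorted by similarity to the query, descending.

    Ties are broken by ascending rbp_id so the ranking is deterministic.
    Every homolog must carry a PWM (it is about to be averaged)."""
    if not homologs:
        raise InputError("empty homolog list")
    for h in homologs:
        if h.pwm is None:
            raise InputError(f"homolog {h.rbp_id!r} has no attached PWM")
        if h.rbp_id == query.rbp_id:
            raise InputError(f"query {query.rbp_id!r} present in its own homolog pool")
    sims = [
        (h.rbp_id, pairwise_identity(query.aa_sequence, h.aa_sequence)) for h in homologs
    ]
    return sorted(sims, key=lambda item: (-item[1], item[0]))


def write_similarity_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path, sep="\t"
    )


def read_similarity_tsv(path: str | Path) -> SimilarityMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))
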