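"""PWM-derived k-mer score table for the logistic sequence model.

Position-dependent k-mer models give every one of the 4^k k-mers its own
score phi_m; the logistic sequence preference of a k-mer is then

    F_seq(m) = 1 / (1 + exp(-b - phi_m))

with a single bias b. A position-independent PWM (4 x k parameters) is
converted into that richer parameterization by scoring each k-mer with the
product of the relevant PWM probabilities,

    phi_m = prod_l PWM[index(m_l), l]

and the resulting table is *frozen*: a downstream trainer (e.g. a
sequence-and-structure k-mer model) may optimize b and any parameters of its
own, but must not touch phi. :func:`freeze_contract_check` verifies that
contract across an external training step.

For a probability-scale PWM the phi table is a product measure, so the
entries sum to exactly 1 — a useful conservation check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterator

import numpy as np

from .exceptions import InputError
from .motifs import ALPHABET, PWM, base_indices

__all__ = [
    "KmerScoreTable",
    "pwm_to_phi",
    "f_seq",
    "freeze_contract_check",
    "write_phi_tsv",
    "read_phi_tsv",
]

MAX_K = 10  # 4^10 ~ 1M entries; larger tables are almost certainly a mistake


def all_kmers(k: int) -> Iterator[str]:
    """All 4^k k-mers in lexicographic order over A < C < G < U."""
    for tup in product(ALPHABET, repeat=k):
        yield "".join(tup)


def kmer_index(kmer: str) -> int:
    idx = base_indices(kmer)
    if np.any(idx < 0):
        raise InputError(f"k-mer {kmer!r} contains non-ACGU characters")
    return int(idx @ (4 ** np.arange(len(idx) - 1, -1, -1)))


@dataclass
class KmerScoreTable:
    """phi scores for all 4^k k-mers plus a trainable bias b.

    ``phi`` is stored as a dense vector in lexicographic k-mer order. When
    ``frozen`` is true, phi entries must never change; b remains mutable.
    """

    k: int
    phi: np.ndarray
    b: float = 0.0
    frozen: bool = True

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.k < 1 or self.k > MAX_K:
            raise InputError(f"k must be in 1..{MAX_K}")
        if self.phi.shape != (4**self.k,):
            raise InputError(f"phi must have exactly 4^{self.k} = {4**self.k} entries")

    def __len__(self) -> int:
        return len(self.phi)

    def __getitem__(self, kmer: str) -> float:
        if len(kmer) != self.k:
            raise InputError(f"k-mer length {len(kmer)} != k={self.k}")
        return float(self.phi[kmer_index(kmer)])

    def items(self) -> Iterator[tuple[str, float]]:
        for i, kmer in enumerate(all_kmers(self.k)):
            yield kmer, float(self.phi[i])

    def snapshot(self) -> tuple[int, bytes, float]:
        """Immutable image of the table for freeze-contract auditing."""
        return (self.k, self.phi.tobytes(), self.b)


def pwm_to_phi(pwm: PWM) -> KmerScoreTable:
    """Score every k-mer by the product of PWM entries; freeze the table."""
    k = pwm.width
    if k > MAX_K:
        raise InputError(f"PWM width {k} > {MAX_K}: 4^k table would not fit sanely")
    phi = np.ones(1)
    for j in range(k):
        phi = (phi[:, None] * pwm.weights[:, j][None, :]).ravel()
    return KmerScoreTable(k=k, phi=phi, b=0.0, frozen=True)


def f_seq(table: KmerScoreTable, kmer: str) -> float:
    """Logistic binding probability of one k-mer: 1/(1 + exp(-b - phi_m))."""
    val = table[kmer]
    return float(1.0 / (1.0 + np.exp(-table.b - val)))


def freeze_contract_check(
    before: tuple[int, bytes, float], after: tuple[int, bytes, float]
) -> bool:
    """True iff phi is bit-identical across the two snapshots (b may differ)."""
    k_before, phi_before, _ = before
    k_after, phi_after, _ = after
    if k_before != k_after:
        raise InputError(f"snapshot k mismatch: {k_before} vs {k_after}")
    return phi_before == phi_after


def write_phi_tsv(table: KmerScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# k={table.k}\tb={table.b!r}\n")
        for kmer, val in table.items():
            fh.write(f"{kmer}\t{val!r}\n")


def read_phi_tsv(path: str | Path) -> KmerScoreTable:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise InputError(f"{path}: missing '# k=... b=...' header")
    header = dict(
        tok.split("=", 1) for tok in lines[0].lstrip("#").split() if "=" in tok
    )
    k = int(header["k"])
    b = float(header["b"])
    phi = np.empty(4**k)
    seen = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        kmer, val = line.split("\t")
        phi[kmer_index(kmer)] = float(val)
        seen += 1
    if seen != 4**k:
        raise InputError(f"{path}: expected {4**k} k-mers, found {seen}")
    return KmerScoreTable(k=k, phi=phi, b=b, frozen=True)
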