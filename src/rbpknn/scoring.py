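"""PWM scan scoring of RNA sequences.

A k-wide PWM assigns each k-mer the product of its per-position entries. A
whole sequence s is scored by sliding the PWM over every window t = 0 ..
|s|-k and summing a gated transform of the window products:

    y = (1/|s|) * sum_t f(prod_l PWM[index(s[t+l]), l]),
    f(a) = arcsinh(a) if a > 1 else 0

The gate keeps only windows whose product exceeds the background, so y is
driven by high-affinity sites rather than by sequence length. This y is the
predicted binding intensity for an RNA probe.

Scoring requires the PWM on background_ratio scale: probability-scale
products of k entries are always <= 1 and the gate would zero every window.
Note the normalization is by sequence length |s|, not by the window count
|s|-k+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError, ScaleError
from .motifs import BACKGROUND_RATIO, PWM, base_indices

__all__ = [
    "ProbeSet",
    "score_kmer",
    "score_sequence",
    "score_probeset",
    "encode_probes",
    "score_encoded",
]


@dataclass(frozen=True)
class ProbeSet:
    """RNA probe sequences with continuous intensities and/or binary labels."""

    sequences: tuple[str, ...]
    intensities: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        seqs = tuple(s.upper().replace("T", "U") for s in self.sequences)
        object.__setattr__(self, "sequences", seqs)
        n = len(seqs)
        for name in ("intensities", "labels"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float if name == "intensities" else int)
                if len(arr) != n:
                    raise InputError(f"{name} length {len(arr)} != {n} sequences")
                object.__setattr__(self, name, arr)
        if self.labels is not None and not set(np.unique(self.labels)) <= {0, 1}:
            raise InputError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, indices: Sequence[int]) -> "ProbeSet":
        idx = np.asarray(indices, dtype=int)
        return ProbeSet(
            tuple(self.sequences[i] for i in idx),
            None if self.intensities is None else self.intensities[idx],
            None if self.labels is None else self.labels[idx],
        )


def _require_background_ratio(pwm: PWM, auto_convert: bool) -> PWM:
    if pwm.scale != BACKGROUND_RATIO:
        if auto_convert:
            return pwm.to_background_ratio()
        raise ScaleError(
            "scan scoring needs a background_ratio-scale PWM (probability-scale "
            "window products never pass the >1 gate); convert with "
            "pwm.to_background_ratio() or pass auto_convert=True"
        )
    return pwm


def score_kmer(pwm: PWM, kmer: str) -> float:
    """Product of the PWM entries matching each base of a k-mer."""
    if len(kmer) != pwm.width:
        raise InputError(f"k-mer length {len(kmer)} != PWM width {pwm.width}")
    idx = base_indices(kmer)
    if np.any(idx < 0):
        raise InputError(f"k-mer {kmer!r} contains non-ACGU characters")
    return float(np.prod(pwm.weights[idx, np.arange(pwm.width)]))


def _window_products(pwm: PWM, sequence: str) -> np.ndarray:
    """Products of PWM entries for every window; windows touching an unknown
    base (e.g. N) get product 0, which the gate then discards."""
    k = pwm.width
    idx = base_indices(sequence)
    n_windows = len(idx) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = np.all(windows >= 0, axis=1)
    prods = np.zeros(n_windows)
    if np.any(valid):
        safe = np.where(windows[valid] < 0, 0, windows[valid])
        prods[valid] = np.prod(pwm.weights[safe, np.arange(k)], axis=1)
    return prods


def score_sequence(pwm: PWM, sequence: str, auto_convert: bool = False) -> float:
    """Gated scan score y of one RNA sequence (predicted binding intensity)."""
    pwm = _require_background_ratio(pwm, auto_convert)
    seq = sequence.upper().replace("T", "U")
    if len(seq) < pwm.width:
        raise InputError(
            f"sequence length {len(seq)} shorter than PWM width {pwm.width}"
        )
    prods = _window_products(pwm, seq)
    gated = np.where(prods > 1.0, np.arcsinh(prods), 0.0)
    return float(gated.sum() / len(seq))


def encode_probes(sequences: Sequence[str]) -> list[np.ndarray]:
    """Pre-map probe sequences to PWM row indices (reusable across PWMs)."""
    return [base_indices(s.upper().replace("T", "U")) for s in sequences]


def score_encoded(pwm: PWM, encoded: Sequence[np.ndarray]) -> np.ndarray:
    """Scan score for pre-encoded probes; equal-length batches are vectorized."""
    k = pwm.width
    scores = np.empty(len(encoded))
    by_length: dict[int, list[int]] = {}
    for i, idx in enumerate(encoded):
        if len(idx) < k:
            raise InputError(f"probe {i}: length {len(idx)} shorter than PWM width {k}")
        by_length.setdefault(len(idx), []).append(i)
    cols = np.arange(k)
    for length, members in by_length.items():
        idx_mat = np.stack([encoded[i] for i in members])  # (m, length)
        windows = np.lib.stride_tricks.sliding_window_view(idx_mat, k, axis=1)
        valid = np.all(windows >= 0, axis=2)
        safe = np.where(windows < 0, 0, windows)
        prods = np.prod(pwm.weights[safe, cols], axis=2)
        prods[~valid] = 0.0
        gated = np.where(prods > 1.0, np.arcsinh(prods), 0.0)
        scores[members] = gated.sum(axis=1) / length
    return scores


def score_probeset(
    pwm: PWM, probes: ProbeSet | Sequence[str], auto_convert: bool = False
) -> np.ndarray:
    """Scan score for every probe, order preserved."""
    pwm = _require_background_ratio(pwm, auto_convert)
    sequences = probes.sequences if isinstance(probes, ProbeSet) else probes
    return score_encoded(pwm, encode_probes(sequences))


def read_probes_tsv(path) -> ProbeSet:
    """Read a probe TSV with header ``sequence`` plus optional ``intensity``
    and/or ``label`` columns."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sequence" not in cols:
        raise InputError(f"{path}: probe TSV needs a 'sequence' column")
    return ProbeSet(
        tuple(df[cols["sequence"]].astype(str)),
        intensities=df[cols["intensity"]].to_numpy() if "intensity" in cols else None,
        labels=df[cols["label"]].to_numpy() if "label" in cols else None,
    )


def write_probes_tsv(probes: ProbeSet, path) -> None:
    import pandas as pd

    data = {"sequence": probes.sequences}
    if probes.intensities is not None:
        data["intensity"] = probes.intensities
    if probes.labels is not None:
        data["label"] = probes.labels
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
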