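"""Motif containers and I/O.

RNA sequence preferences are represented as 4 x k position weight matrices
(PWMs) with rows fixed to the order A, C, G, U. Two scales are carried
explicitly:

``probability``
    each column is a base-composition distribution summing to 1;

``background_ratio``
    each entry is the probability divided by the uniform background 0.25, so
    a column's mean is 1 and informative entries exceed 1. Scan scoring
    (:mod:`rbpknn.scoring`) only makes sense on this scale, because its gate
    discards window products <= 1 and products of k probabilities never
    exceed 1.

DNA input (base T) is mapped to U at parse time everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import FormatError, InputError

ALPHABET = "ACGU"
ROW_INDEX = {b: i for i, b in enumerate(ALPHABET)}
ROW_INDEX["T"] = ROW_INDEX["U"]

PROBABILITY = "probability"
BACKGROUND_RATIO = "background_ratio"
_SCALES = (PROBABILITY, BACKGROUND_RATIO)

DEFAULT_WIDTH = 7
_BACKGROUND = 0.25
_COLTOL = 1e-9


def base_indices(sequence: str) -> np.ndarray:
    """Map an RNA/DNA string to PWM row indices; unknown bases (N, ...) -> -1."""
    return np.array([ROW_INDEX.get(b, -1) for b in sequence.upper()], dtype=np.intp)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Raw per-position base counts or frequencies (4 x L, rows A,C,G,U)."""

    counts: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise InputError(f"PFM must be 4 x L with L >= 1, got shape {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise InputError("PFM entries must be finite and non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: 4 x k, strictly positive, with an explicit scale."""

    weights: np.ndarray
    scale: str = PROBABILITY
    motif_id: str = ""

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 2 or weights.shape[0] != 4 or weights.shape[1] < 1:
            raise InputError(f"PWM must be 4 x k with k >= 1, got shape {weights.shape}")
        if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
            raise InputError("PWM entries must be finite and strictly positive (pseudocounted)")
        if self.scale not in _SCALES:
            raise InputError(f"unknown PWM scale {self.scale!r}; expected one of {_SCALES}")
        colsum = weights.sum(axis=0)
        if self.scale == PROBABILITY:
            if np.any(np.abs(colsum - 1.0) > _COLTOL):
                raise InputError("probability-scale PWM columns must sum to 1")
        else:
            if np.any(np.abs(colsum / 4.0 - 1.0) > _COLTOL):
                raise InputError("background_ratio-scale PWM columns must have mean 1")
        object.__setattr__(self, "weights", weights)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def to_probability(self) -> "PWM":
        if self.scale == PROBABILITY:
            return self
        return PWM(self.weights * _BACKGROUND, PROBABILITY, self.motif_id)

    def to_background_ratio(self) -> "PWM":
        if self.scale == BACKGROUND_RATIO:
            return self
        return PWM(self.weights / _BACKGROUND, BACKGROUND_RATIO, self.motif_id)

    def with_id(self, motif_id: str) -> "PWM":
        return replace(self, motif_id=motif_id)

    def information_content(self) -> float:
        """Total information content in bits against the uniform background."""
        p = self.to_probability().weights
        return float(np.sum(p * np.log2(p / _BACKGROUND)))


@dataclass(frozen=True)
class RBPRecord:
    """One RNA-binding protein: sequence, domain family, construct, optional PWM."""

    rbp_id: str
    aa_sequence: str
    family: str = "other"  # RRM | KH | other
    construct: str = "other"  # FL | RBR | other
    species: str = ""
    pwm: PWM | None = None

    _AA = set("ACDEFGHIKLMNPQRSTVWYX")

    def __post_init__(self) -> None:
        seq = self.aa_sequence.upper()
        if not seq:
            raise InputError(f"record {self.rbp_id!r}: empty amino-acid sequence")
        bad = set(seq) - self._AA
        if bad:
            raise InputError(
                f"record {self.rbp_id!r}: non-amino-acid characters {sorted(bad)}"
            )
        object.__setattr__(self, "aa_sequence", seq)

    def with_pwm(self, pwm: PWM) -> "RBPRecord":
        return replace(self, pwm=pwm)


# ---------------------------------------------------------------------------
# PFM -> PWM conversion


def _column_information(prob_cols: np.ndarray) -> np.ndarray:
    p = np.clip(prob_cols, 1e-12, None)
    return np.sum(p * np.log2(p / _BACKGROUND), axis=0)


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    target_width: int = DEFAULT_WIDTH,
    pseudocount: float = 1.0,
    scale: str = PROBABILITY,
) -> PWM:
    """Convert a PFM to a fixed-width PWM.

    Columns get ``pseudocount`` added to every base count and are normalized to
    probabilities. Width harmonization: a wider PFM keeps the contiguous
    ``target_width`` window of maximal total information content (ties ->
    leftmost; window choice made on pseudocount-free column distributions so it
    is invariant to uniform count scaling); a narrower one is padded with
    uniform columns, split symmetrically with the extra column on the right.
    """
    if target_width < 1:
        raise InputError("target_width must be >= 1")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsum == 0):
        raise InputError("all-zero PFM column with pseudocount=0 cannot be normalized")

    if pfm.width > target_width:
        # scale-invariant window choice: plain column frequencies
        with np.errstate(invalid="ignore"):
            freqs = np.where(colsum > 0, counts / np.where(colsum == 0, 1, colsum), _BACKGROUND)
        ic = _column_information(freqs)
        window_ic = np.convolve(ic, np.ones(target_width), mode="valid")
        start = int(np.argmax(window_ic))  # argmax takes the leftmost maximum
        counts = counts[:, start : start + target_width]

    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)

    if probs.shape[1] < target_width:
        missing = target_width - probs.shape[1]
        left = missing // 2
        right = missing - left
        uniform = np.full((4, 1), _BACKGROUND)
        probs = np.hstack([np.tile(uniform, (1, left)), probs, np.tile(uniform, (1, right))])

    pwm = PWM(probs, PROBABILITY, pfm.source_id)
    return pwm if scale == PROBABILITY else pwm.to_background_ratio()


# ---------------------------------------------------------------------------
# Record filtering


def filter_records(
    records: Iterable[RBPRecord],
    family: str | None = None,
    construct: str | None = None,
) -> list[RBPRecord]:
    """Keep records matching the requested family/construct tags, order preserved.

    This reproduces the curation predicates used to restrict a motif library to
    a single domain-family / construct combination (e.g. RRM + FL)."""
    out = []
    for rec in records:
        if family is not None and rec.family != family:
            continue
        if construct is not None and rec.construct != construct:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# PWM text format (tab-separated, header "Pos A C G U", 1-based positions)


def _renormalize(weights: np.ndarray, scale: str, path) -> np.ndarray:
    """Snap file-rounded columns back onto the exact scale invariant."""
    colsum = weights.sum(axis=0)
    if np.any(colsum <= 0):
        raise FormatError(f"{path}: PWM column with non-positive total")
    target = colsum if scale == PROBABILITY else colsum / 4.0
    if scale == PROBABILITY and np.any(np.abs(colsum - 1.0) > 1e-3):
        raise FormatError(f"{path}: probability columns sum to {colsum}, not 1")
    return weights / target


def write_pwm_text(pwm: PWM, path: str | Path) -> None:
    lines = [f"# scale: {pwm.scale}"]
    if pwm.motif_id:
        lines.append(f"# motif: {pwm.motif_id}")
    lines.append("Pos\tA\tC\tG\tU")
    for j in range(pwm.width):
        vals = "\t".join(f"{pwm.weights[i, j]:.10f}" for i in range(4))
        lines.append(f"{j + 1}\t{vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pwm_text(path: str | Path) -> PWM:
    scale = None
    motif_id = Path(path).stem
    rows: list[list[float]] = []
    seen_header = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("scale:"):
                scale = body.split(":", 1)[1].strip()
            elif body.startswith("motif:"):
                motif_id = body.split(":", 1)[1].strip()
            continue
        if not seen_header:
            header = line.split()
            if [h.upper().replace("T", "U") for h in header] != ["POS", "A", "C", "G", "U"]:
                raise FormatError(f"{path}: expected header 'Pos A C G U', got {line!r}")
            seen_header = True
            continue
        fields = line.split()
        if len(fields) != 5:
            raise FormatError(f"{path}: expected 5 columns (Pos A C G U), got {len(fields)}")
        try:
            vals = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric entry in row {fields[0]!r}") from exc
        if any(v < 0 for v in vals):
            raise FormatError(f"{path}: negative PWM entry in row {fields[0]!r}")
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no PWM rows found")
    weights = np.array(rows, dtype=float).T  # rows are positions on disk
    if scale is None:
        colsum = weights.sum(axis=0)
        scale = PROBABILITY if np.allclose(colsum, 1.0, atol=1e-6) else BACKGROUND_RATIO
    return PWM(_renormalize(weights, scale, path), scale, motif_id)


# ---------------------------------------------------------------------------
# MEME minimal motif format (RNA alphabet)


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write motifs in MEME minimal format; entries are written on probability scale."""
    chunks = [
        "MEME version 4",
        "",
        "ALPHABET= ACGU",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 U 0.25",
        "",
    ]
    for idx, pwm in enumerate(pwms):
        prob = pwm.to_probability()
        name = pwm.motif_id or f"motif_{idx + 1}"
        chunks.append(f"MOTIF {name}")
        chunks.append(
            f"letter-probability matrix: alength= 4 w= {prob.width} nsites= 20 E= 0"
        )
        for j in range(prob.width):
            chunks.append(" " + " ".join(f"{prob.weights[i, j]:.10f}" for i in range(4)))
        chunks.append("")
    Path(path).write_text("\n".join(chunks))


def read_meme(path: str | Path) -> list[PWM]:
    """Parse a MEME minimal motif file into probability-scale PWMs (T read as U)."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not any(l.strip().upper().startswith("ALPHABET") for l in lines):
        raise FormatError(f"{path}: missing ALPHABET line — not MEME minimal format")
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            name = parts[1]
            i += 1
            # seek the letter-probability header
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name!r} has no probability matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name!r} has no probability matrix")
            i += 1
            rows = []
            while i < len(lines):
                fields = lines[i].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise FormatError(f"{path}: empty probability matrix for motif {name!r}")
            weights = _renormalize(np.array(rows).T, PROBABILITY, path)
            pwms.append(PWM(weights, PROBABILITY, name))
        else:
            i += 1
    return pwms


# ---------------------------------------------------------------------------
# FASTA -> RBPRecord


def read_fasta_records(path: str | Path) -> list[RBPRecord]:
    """Read protein FASTA; `key=value` tokens in the description set
    family/construct/species tags (e.g. ``>P1 family=RRM construct=FL``)."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, val = token.split("=", 1)
                tags[key.lower()] = val
        records.append(
            RBPRecord(
                rbp_id=rec.id,
                aa_sequence=str(rec.seq),
                family=tags.get("family", "other"),
                construct=tags.get("construct", "other"),
                species=tags.get("species", ""),
            )
        )
    return records


def write_fasta_records(records: Sequence[RBPRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f">{rec.rbp_id} family={rec.family} construct={rec.construct}"
                f" species={rec.species}\n{rec.aa_sequence}\n"
            )
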