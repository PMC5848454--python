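"""Mirror-tree test of protein/motif co-evolution.

If RBPs and their binding motifs co-evolve, proteins that are similar in
sequence should also have similar motifs. The mirror-tree statistic makes
that precise: build a pairwise protein-similarity matrix and a pairwise
motif(PWM)-similarity matrix over the same set of RBPs, and compute the
Pearson correlation (PCC) between the two matrices over their off-diagonal
upper triangles.

Significance comes from two tests:

* a nonparametric permutation test — shuffle the motif-to-protein assignment,
  recompute the PCC, and rank the observed PCC among the permuted ones
  (add-one estimator, so p is never exactly 0). This is the default;
* a parametric one-sided Student-t test on the correlation. Matrix entries
  are not independent, so this test is anti-conservative and is reported as
  a secondary diagnostic only.

Motif similarity is the Pearson correlation between the two 4 x k weight
matrices flattened to vectors, mapped to [0, 1] via (r + 1) / 2. PWMs share
a fixed width by construction, so no offset search is needed. The metric is
pluggable (pass ``metric=`` to the matrix builder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateError, InputError
from .homology import SimilarityMatrix
from .motifs import PWM

__all__ = [
    "CoevolutionResult",
    "MirrorTree",
    "pwm_similarity",
    "build_motif_similarity",
    "mirror_tree_pcc",
    "permutation_test",
    "parametric_test",
]


def pwm_similarity(pwm_a: PWM, pwm_b: PWM) -> float:
    """Similarity in [0, 1] between two equal-width PWMs: (flat Pearson + 1)/2."""
    if pwm_a.width != pwm_b.width:
        raise InputError(f"PWM widths differ: {pwm_a.width} vs {pwm_b.width}")
    if pwm_a.scale != pwm_b.scale:
        raise InputError(f"PWM scales differ: {pwm_a.scale} vs {pwm_b.scale}")
    a = pwm_a.weights.ravel()
    b = pwm_b.weights.ravel()
    if a.std() == 0 or b.std() == 0:
        raise DegenerateError("flat PWM has no variance; similarity undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return (r + 1.0) / 2.0


def build_motif_similarity(
    pwms: Sequence[PWM],
    labels: Sequence[str],
    metric: Callable[[PWM, PWM], float] = pwm_similarity,
) -> SimilarityMatrix:
    """Pairwise motif similarity matrix over an ordered set of PWMs."""
    if len(pwms) != len(labels):
        raise InputError("pwms and labels must align")
    n = len(pwms)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = metric(pwms[i], pwms[j])
    return SimilarityMatrix(tuple(labels), values)


def mirror_tree_pcc(
    protein_sim: SimilarityMatrix, motif_sim: SimilarityMatrix
) -> tuple[float, int]:
    """PCC between the two matrices over n(n-1)/2 off-diagonal pairs."""
    if protein_sim.labels != motif_sim.labels:
        raise InputError("protein and motif similarity matrices have different labels")
    n = protein_sim.n
    if n < 3:
        raise InputError("mirror-tree PCC needs at least 3 proteins")
    a = protein_sim.upper_triangle()
    b = motif_sim.upper_triangle()
    if a.std() == 0 or b.std() == 0:
        raise DegenerateError("zero variance in a similarity triangle; PCC undefined")
    pcc = float(np.corrcoef(a, b)[0, 1])
    return pcc, len(a)


def _permuted_pccs(
    protein_tri: np.ndarray,
    motif_values: np.ndarray,
    n: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    a = protein_tri - protein_tri.mean()
    a_norm = np.sqrt((a**2).sum())
    rows = np.empty((n_perm, len(iu)))
    for p in range(n_perm):
        perm = rng.permutation(n)
        rows[p] = motif_values[perm[iu], perm[ju]]
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rows_c, axis=1) * a_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows_c @ a) / denom


def permutation_test(
    protein_sim: SimilarityMatrix,
    pwms: Sequence[PWM],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the mirror-tree PCC.

    The motif-to-protein assignment is shuffled ``n_perm`` times; each shuffle
    permutes rows and columns of the motif-similarity matrix jointly. The
    one-sided p-value uses the add-one estimator
    (1 + #{permuted PCC >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    motif_sim = build_motif_similarity(pwms, protein_sim.labels)
    return _permutation_p(protein_sim, motif_sim, n_perm, seed)


def _permutation_p(
    protein_sim: SimilarityMatrix,
    motif_sim: SimilarityMatrix,
    n_perm: int,
    seed: int,
) -> float:
    observed, _ = mirror_tree_pcc(protein_sim, motif_sim)
    rng = np.random.default_rng(seed)
    perm_pccs = _permuted_pccs(
        protein_sim.upper_triangle(), motif_sim.values, protein_sim.n, n_perm, rng
    )
    exceed = int(np.sum(perm_pccs[~np.isnan(perm_pccs)] >= observed))
    return (1 + exceed) / (1 + n_perm)


def parametric_test(pcc: float, n_pairs: int) -> float:
    """One-sided Student-t p-value for a positive correlation over n_pairs pairs.

    Treats the matrix entries as independent, which they are not — use as a
    quick diagnostic next to the permutation test, not instead of it.
    """
    if n_pairs < 3:
        raise InputError("n_pairs must be >= 3")
    if abs(pcc) >= 1.0:
        return 0.0 if pcc > 0 else 1.0
    df = n_pairs - 2
    t = pcc * np.sqrt(df / (1.0 - pcc**2))
    return float(stats.t.sf(t, df))


@dataclass(frozen=True)
class CoevolutionResult:
    """Mirror-tree co-evolution statistic with both significance tests."""

    pcc: float
    n_pairs: int
    p_permutation: float
    n_permutations: int
    p_parametric: float
    seed: int

    def summary(self) -> str:
        return "\n".join(
            [
                "Mirror-tree co-evolution test",
                "=" * 40,
                f"PCC (protein vs motif similarity): {self.pcc: .4f}",
                f"pairs:                             {self.n_pairs}",
                f"permutation p ({self.n_permutations} shuffles):     {self.p_permutation:.4g}",
                f"parametric p (one-sided t):        {self.p_parametric:.4g}",
                f"seed:                              {self.seed}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "pcc": self.pcc,
            "n_pairs": self.n_pairs,
            "p_permutation": self.p_permutation,
            "n_permutations": self.n_permutations,
            "p_parametric": self.p_parametric,
            "seed": self.seed,
        }


class MirrorTree:
    """Mirror-tree co-evolution model over one set of RBPs.

    Built either from a protein similarity matrix plus the aligned PWMs, or
    from two precomputed similarity matrices (``motif_sim=``).
    """

    def __init__(
        self,
        protein_sim: SimilarityMatrix,
        pwms: Sequence[PWM] | None = None,
        motif_sim: SimilarityMatrix | None = None,
        metric: Callable[[PWM, PWM], float] = pwm_similarity,
    ):
        if (pwms is None) == (motif_sim is None):
            raise InputError("supply exactly one of pwms or motif_sim")
        if motif_sim is None:
            if len(pwms) != protein_sim.n:
                raise InputError("one PWM per protein required")
            motif_sim = build_motif_similarity(pwms, protein_sim.labels, metric)
        if motif_sim.labels != protein_sim.labels:
            raise InputError("motif_sim labels must match protein_sim labels")
        self.protein_sim = protein_sim
        self.motif_sim = motif_sim

    def fit(self, n_perm: int = 1000, seed: int = 0) -> CoevolutionResult:
        pcc, n_pairs = mirror_tree_pcc(self.protein_sim, self.motif_sim)
        p_perm = _permutation_p(self.protein_sim, self.motif_sim, n_perm, seed)
        p_par = parametric_test(pcc, n_pairs)
        return CoevolutionResult(
            pcc=pcc,
            n_pairs=n_pairs,
            p_permutation=p_perm,
            n_permutations=n_perm,
            p_parametric=p_par,
            seed=seed,
        )
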