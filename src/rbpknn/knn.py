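"""KNN inference of an RBP's binding motif from homolog motifs.

The model assumes RBPs and their binding motifs co-evolve: a query protein's
PWM is predicted as the similarity-weighted average of the PWMs of its K
nearest homologs,

    PWM_x(i, j) = sum_p w_p * PWM_p(i, j) / sum_p w_p

where w_p is the global-alignment percent identity between the query and
homolog p. No binding data for the query is used. The number of neighbors K
is either supplied, chosen by cross-validation against the query's probe
intensities when those exist (the benchmarking path), or fixed to an
empirical default of 7 for novel proteins with no binding data at all.

Usage follows the model/results convention::

    model = KnnPwm(query, homologs)
    res = model.fit(probes=probe_set, seed=0)   # cross-validated K
    res.inferred_pwm, res.K, res.summary()
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateError, InputError
from .homology import rank_neighbors
from .motifs import PWM, RBPRecord
from .scoring import ProbeSet, encode_probes, score_encoded

__all__ = ["KnnPwm", "KnnPwmResults", "knn_infer_pwm", "select_opt_k", "infer_novel"]

DEFAULT_FIXED_K = 7  # empirical average of cross-validated K over benchmark runs
MAX_DEFAULT_K = 30


def _check_pool(homologs: Sequence[RBPRecord]) -> tuple[int, str]:
    widths = {h.pwm.width for h in homologs}
    scales = {h.pwm.scale for h in homologs}
    if len(widths) != 1 or len(scales) != 1:
        raise InputError(
            f"homolog PWMs must share one width and scale, got widths={sorted(widths)}"
            f" scales={sorted(scales)}"
        )
    return widths.pop(), scales.pop()


@dataclass(frozen=True)
class KnnPwmResults:
    """Fitted KNN motif: the inferred PWM plus the neighborhood that produced it."""

    query_id: str
    K: int
    neighbor_ids: tuple[str, ...]
    neighbor_weights: np.ndarray  # similarities, descending
    inferred_pwm: PWM
    k_source: str  # "given" | "cv" | "fixed"
    cv_table: pd.DataFrame | None = None

    def neighbor_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rbp_id": self.neighbor_ids, "similarity": self.neighbor_weights}
        )

    def summary(self) -> str:
        lines = [
            "KNN motif inference results",
            "=" * 40,
            f"query:        {self.query_id}",
            f"K:            {self.K} ({self.k_source})",
            f"motif width:  {self.inferred_pwm.width} ({self.inferred_pwm.scale})",
            "",
            "neighbors (similarity-weighted):",
            self.neighbor_table().to_string(index=False),
        ]
        if self.cv_table is not None:
            lines += ["", "cross-validation over K:", self.cv_table.to_string(index=False)]
        return "\n".join(lines)


def knn_infer_pwm(
    query: RBPRecord,
    homologs: Sequence[RBPRecord],
    K: int,
    _ranked: Sequence[tuple[str, float]] | None = None,
) -> KnnPwmResults:
    """Similarity-weighted average of the K nearest homologs' PWMs."""
    if not homologs:
        raise InputError("empty homolog list")
    if not 1 <= K <= len(homologs):
        raise InputError(f"K={K} outside 1..{len(homologs)} homologs")
    _, scale = _check_pool(homologs)
    ranked = list(_ranked) if _ranked is not None else rank_neighbors(query, homologs)
    top = ranked[:K]
    ids = tuple(rid for rid, _ in top)
    weights = np.array([w for _, w in top], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise DegenerateError(
            f"all top-{K} similarities are zero; cannot form a weighted average"
        )
    by_id = {h.rbp_id: h.pwm for h in homologs}
    stack = np.stack([by_id[rid].weights for rid in ids])  # (K, 4, k)
    norm = weights / total  # K=1 -> exactly 1.0, so the neighbor PWM is returned bit-exactly
    averaged = np.tensordot(norm, stack, axes=(0, 0))
    pwm = PWM(averaged, scale, f"{query.rbp_id}_knn{K}")
    return KnnPwmResults(
        query_id=query.rbp_id,
        K=K,
        neighbor_ids=ids,
        neighbor_weights=weights,
        inferred_pwm=pwm,
        k_source="given",
    )


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[f::folds] for f in range(folds)]


def select_opt_k(
    query: RBPRecord,
    homologs: Sequence[RBPRecord],
    probes: ProbeSet,
    k_grid: Sequence[int] | None = None,
    folds: int = 2,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose K by cross-validated scan-score/intensity correlation.

    For each candidate K the PWM is inferred from the homolog pool alone and
    each held-out probe fold is scored with the gated scan; the fold Pearson
    correlations against measured intensities are averaged and the K with the
    best mean wins (ties -> smallest K). Candidates whose scores are constant
    on some fold (undefined correlation) are dropped.
    """
    if probes.intensities is None:
        raise InputError("select_opt_k needs probes with continuous intensities")
    if folds < 2:
        raise InputError("folds must be >= 2")
    if len(probes) < folds:
        raise InputError(f"{len(probes)} probes cannot fill {folds} folds")
    if k_grid is None:
        k_grid = range(1, min(MAX_DEFAULT_K, len(homologs)) + 1)
    k_grid = list(k_grid)
    if not k_grid:
        raise InputError("empty k_grid")

    ranked = rank_neighbors(query, homologs)
    encoded = encode_probes(probes.sequences)
    fold_idx = _fold_indices(len(probes), folds, seed)

    rows = []
    for K in k_grid:
        pwm = knn_infer_pwm(query, homologs, K, _ranked=ranked).inferred_pwm
        pwm_bg = pwm.to_background_ratio()
        fold_pccs = []
        for idx in fold_idx:
            scores = score_encoded(pwm_bg, [encoded[i] for i in idx])
            truth = probes.intensities[idx]
            if scores.std() == 0 or truth.std() == 0:
                fold_pccs.append(np.nan)
            else:
                fold_pccs.append(float(np.corrcoef(scores, truth)[0, 1]))
        rows.append({"K": K, "mean_pcc": float(np.mean(fold_pccs))})
    cv_table = pd.DataFrame(rows)
    usable = cv_table.dropna(subset=["mean_pcc"])
    if usable.empty:
        raise DegenerateError("every candidate K gave constant scores on some fold")
    best = usable["mean_pcc"].max()
    opt_k = int(usable.loc[usable["mean_pcc"] >= best, "K"].min())
    return opt_k, cv_table


def infer_novel(
    query: RBPRecord, homologs: Sequence[RBPRecord], fixed_K: int = DEFAULT_FIXED_K
) -> KnnPwmResults:
    """Inference path for a novel RBP with no binding data: K fixed (clipped
    to the pool size), no cross-validation."""
    if not homologs:
        raise InputError("empty homolog list")
    if fixed_K < 1:
        raise InputError("fixed_K must be >= 1")
    K = min(fixed_K, len(homologs))
    res = knn_infer_pwm(query, homologs, K)
    return KnnPwmResults(
        query_id=res.query_id,
        K=res.K,
        neighbor_ids=res.neighbor_ids,
        neighbor_weights=res.neighbor_weights,
        inferred_pwm=res.inferred_pwm,
        k_source="fixed",
    )


class KnnPwm:
    """KNN motif-inference model for one query RBP against a homolog pool.

    Parameters
    ----------
    query : RBPRecord
        The protein whose motif is to be inferred; its own binding data is
        never consulted by the averaging step.
    homologs : sequence of RBPRecord
        Homologous proteins, each carrying a PWM of the shared width/scale.
    """

    def __init__(self, query: RBPRecord, homologs: Sequence[RBPRecord]):
        if not homologs:
            raise InputError("empty homolog list")
        _check_pool(homologs)
        self.query = query
        self.homologs = list(homologs)
        self.ranked = rank_neighbors(query, self.homologs)

    def fit(
        self,
        K: int | None = None,
        probes: ProbeSet | None = None,
        k_grid: Sequence[int] | None = None,
        folds: int = 2,
        seed: int = 0,
        fixed_K: int = DEFAULT_FIXED_K,
    ) -> KnnPwmResults:
        """Fit the model.

        With ``K`` given, average the top-K neighbors directly. With
        ``probes`` given (and no K), choose K by cross-validation. With
        neither, fall back to the fixed-K novel-protein path.
        """
        if K is not None:
            res = knn_infer_pwm(self.query, self.homologs, K, _ranked=self.ranked)
            return res
        if probes is not None:
            opt_k, cv_table = select_opt_k(
                self.query, self.homologs, probes, k_grid=k_grid, folds=folds, seed=seed
            )
            base = knn_infer_pwm(self.query, self.homologs, opt_k, _ranked=self.ranked)
            return KnnPwmResults(
                query_id=base.query_id,
                K=base.K,
                neighbor_ids=base.neighbor_ids,
                neighbor_weights=base.neighbor_weights,
                inferred_pwm=base.inferred_pwm,
                k_source="cv",
                cv_table=cv_table,
            )
        return infer_novel(self.query, self.homologs, fixed_K=fixed_K)
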