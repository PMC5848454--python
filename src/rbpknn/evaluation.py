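"""Benchmark harness: intensity pre-processing, splits, metrics, paired tests.

Continuous probe intensities are compared with scan scores by Pearson
correlation (PCC); binary bound/unbound labels are compared by ROC AUC.
Probe intensities are clamped at the 99.95th percentile before use, since
array-measured intensities have a heavy right tail of outliers. Methods are
compared across experiments with a paired Student t-test; per-RBP averaging
collapses multiple test sets of one RBP to a single entry first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import DegenerateError, InputError
from .scoring import ProbeSet

__all__ = [
    "EvalResult",
    "clamp_intensities",
    "split_ab",
    "eval_pcc",
    "eval_auc",
    "paired_ttest",
    "aggregate_mean_per_rbp",
]


@dataclass(frozen=True)
class EvalResult:
    metric: str  # "pcc" | "auc"
    value: float
    n: int
    method_id: str = ""


def clamp_intensities(
    intensities: Sequence[float], percentile: float = 99.95
) -> np.ndarray:
    """Cap outliers at the empirical percentile.

    The cap is the order statistic at the floor of the virtual percentile
    index (numpy's ``lower`` method). With no data between consecutive order
    statistics, this caps exactly the same set of values as the
    linear-interpolation (type-7) percentile would, while making the
    operation exactly idempotent — an interpolated cap shifts every time it
    is recomputed on already-clamped data.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.size == 0:
        raise InputError("empty intensity list")
    if not 0 < percentile < 100:
        raise InputError("percentile must be in (0, 100)")
    cap = np.percentile(arr, percentile, method="lower")
    return np.minimum(arr, cap)


def split_ab(probes: ProbeSet, seed: int = 0) -> tuple[ProbeSet, ProbeSet]:
    """Seeded disjoint ~50/50 split of a probe set into sets A and B."""
    n = len(probes)
    if n < 2:
        raise InputError("need at least 2 probes to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return probes.subset(np.sort(perm[:half])), probes.subset(np.sort(perm[half:]))


def eval_pcc(
    predicted: Sequence[float], observed: Sequence[float], method_id: str = ""
) -> EvalResult:
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise InputError("predicted and observed lengths differ")
    if pred.std() == 0 or obs.std() == 0:
        raise DegenerateError("zero variance; PCC undefined")
    r, _ = stats.pearsonr(pred, obs)
    return EvalResult("pcc", float(r), len(pred), method_id)


def eval_auc(
    scores: Sequence[float], labels: Sequence[int], method_id: str = ""
) -> EvalResult:
    """ROC AUC of scores against binary labels (midrank tie handling)."""
    from sklearn.metrics import roc_auc_score

    scr = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    if scr.shape != lab.shape:
        raise InputError("scores and labels lengths differ")
    classes = set(np.unique(lab))
    if not classes <= {0, 1}:
        raise InputError("labels must be binary 0/1")
    if len(classes) < 2:
        raise DegenerateError("AUC needs both classes present")
    return EvalResult("auc", float(roc_auc_score(lab, scr)), len(scr), method_id)


def paired_ttest(
    metric_a: Sequence[float], metric_b: Sequence[float], alternative: str = "two-sided"
) -> float:
    """Paired Student t-test p-value between two methods' per-experiment metrics."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired metrics must be equal-length vectors")
    if len(a) < 3:
        raise InputError("need at least 3 paired observations")
    if np.std(a - b) == 0:
        raise DegenerateError("paired differences have zero variance")
    res = stats.ttest_rel(a, b, alternative=alternative)
    return float(res.pvalue)


def aggregate_mean_per_rbp(
    entries: Iterable[tuple[str, float]]
) -> list[tuple[str, float]]:
    """Collapse (rbp_id, value) pairs to one mean per RBP, first-seen order."""
    entries = list(entries)
    if not entries:
        raise InputError("no entries to aggregate")
    order: list[str] = []
    sums: dict[str, list[float]] = {}
    for rbp_id, value in entries:
        if rbp_id not in sums:
            order.append(rbp_id)
            sums[rbp_id] = []
        sums[rbp_id].append(float(value))
    return [(rid, float(np.mean(sums[rid]))) for rid in order]
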