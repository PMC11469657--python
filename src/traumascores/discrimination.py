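"""Discrimination metrics for imbalanced binary outcomes.

AUROC is the Mann-Whitney estimator (ties count one half), AUPRC is
step-function average precision with tied scores collapsed into blocks,
confidence intervals come from a stratified percentile bootstrap, and
correlated AUROCs are compared with the DeLong placement-value
(structural-components) covariance and two-sided normal tests under a
Bonferroni family-wise alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "UndefinedMetricError",
    "DiscriminationResult",
    "PairwiseComparison",
    "auroc",
    "auprc",
    "bootstrap_ci",
    "delong_variance",
    "delong_test_all_pairs",
    "evaluate_scores",
]


class UndefinedMetricError(ValueError):
    """Metric undefined, e.g. single-class labels."""


@dataclass
class DiscriminationResult:
    """Point estimates and bootstrap CIs for one risk score."""

    name: str
    auroc: float
    auprc: float
    ci_auroc: tuple
    ci_auprc: tuple
    n_boot: int
    prevalence: float


@dataclass
class PairwiseComparison:
    """DeLong comparison of two correlated AUROCs."""

    score_a: str
    score_b: str
    auc_a: float
    auc_b: float
    auc_diff: float
    z: float
    p: float
    significant: bool
    alpha: float
    degenerate: bool = False


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise UndefinedMetricError("labels contain a single class")


def auroc(risk, labels) -> float:
    """Mann-Whitney AUROC: P(risk_pos > risk_neg) + P(risk_pos = risk_neg)/2.

    ``risk`` must be oriented so larger means predicted death.
    """
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    ranks = stats.rankdata(risk)
    m = int(labels.sum())
    n_neg = len(labels) - m
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - m * (m + 1) / 2) / (m * n_neg))


def auprc(risk, labels) -> float:
    """Average precision with tied-block handling.

    Scores are sorted descending; tied scores form one block whose recall
    increment gets the precision at the block's end.  A constant risk gives
    the prevalence; a perfect ranker gives 1.
    """
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    order = np.argsort(-risk, kind="stable")
    r, y = risk[order], labels[order]
    n_pos = y.sum()
    # block boundaries: last index of each run of tied scores
    boundary = np.nonzero(np.diff(r))[0]
    ends = np.concatenate([boundary, [len(r) - 1]])
    tp = np.cumsum(y)[ends]
    cnt = ends + 1
    precision = tp / cnt
    recall_inc = np.diff(np.concatenate([[0], tp])) / n_pos
    return float(np.sum(precision * recall_inc))


def bootstrap_ci(metric_fn, risk, labels, n_boot: int = 2000,
                 seed: int = 0, level: float = 0.95) -> tuple:
    """Stratified percentile bootstrap interval for a metric.

    Positives and negatives are resampled separately, preserving the
    prevalence, so no resample is single-class.  Deterministic given seed.
    """
    import warnings
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100; interval will be noisy")
    risk = np.asarray(risk, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    rng = np.random.default_rng(seed)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                              rng.choice(neg, size=len(neg), replace=True)])
        vals[b] = metric_fn(risk[idx], labels[idx])
    lo = (1.0 - level) / 2.0
    lower, upper = np.quantile(vals, [lo, 1.0 - lo])
    return float(lower), float(upper)


def delong_variance(risk_matrix, labels):
    """AUCs and DeLong covariance for k scores on the same patients.

    ``risk_matrix`` is (n_patients, k).  Placement values: for positive i,
    V10_i = fraction of negatives it outranks (ties half); for negative j,
    V01_j = fraction of positives above it (ties half).  The covariance of
    the AUC vector is S10/m + S01/n with empirical covariances (ddof=1).
    """
    X = np.atleast_2d(np.asarray(risk_matrix, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] != len(labels):
        X = X.T
    _check_labels(labels)
    pos = X[labels == 1]      # (m, k)
    neg = X[labels == 0]      # (n, k)
    m, k = pos.shape
    n = neg.shape[0]
    # Midrank identity: for positive i, the fraction of negatives it
    # outranks (ties half) is (combined midrank - within-positive midrank)/n,
    # and symmetrically for negatives.  O(N log N) per score.
    v10 = np.empty((m, k))
    v01 = np.empty((n, k))
    for s in range(k):
        combined = stats.rankdata(np.concatenate([pos[:, s], neg[:, s]]))
        r_pos = stats.rankdata(pos[:, s])
        r_neg = stats.rankdata(neg[:, s])
        v10[:, s] = (combined[:m] - r_pos) / n
        v01[:, s] = 1.0 - (combined[m:] - r_neg) / m
    aucs = v10.mean(axis=0)
    s10 = np.cov(v10, rowvar=False, ddof=1) if m > 1 else np.zeros((k, k))
    s01 = np.cov(v01, rowvar=False, ddof=1) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(s10) / m + np.atleast_2d(s01) / n
    return aucs, cov


def delong_test_all_pairs(risk_matrix, labels, names=None,
                          alpha_fw: float = 0.05) -> list:
    """All-pairs DeLong z-tests with a Bonferroni per-comparison alpha.

    For k scores there are k(k-1)/2 comparisons and the per-comparison
    alpha is alpha_fw / that count (0.05 with six scores gives 0.003...).
    Identical score vectors have zero difference variance; such pairs are
    reported as p = 1 with a degenerate flag rather than an error.
    """
    X = np.atleast_2d(np.asarray(risk_matrix, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if X.shape[0] != len(labels):
        X = X.T
    k = X.shape[1]
    if names is None:
        names = [f"score{i}" for i in range(k)]
    aucs, cov = delong_variance(X, labels)
    n_pairs = k * (k - 1) // 2
    alpha = alpha_fw / n_pairs if n_pairs else alpha_fw
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = aucs[i] - aucs[j]
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if var <= 0:
                z, p, degen = 0.0, 1.0, True
            else:
                z = diff / np.sqrt(var)
                p = float(2 * stats.norm.sf(abs(z)))
                degen = False
            out.append(PairwiseComparison(
                score_a=names[i], score_b=names[j],
                auc_a=float(aucs[i]), auc_b=float(aucs[j]),
                auc_diff=float(diff), z=float(z), p=p,
                significant=(not degen) and p < alpha,
                alpha=alpha, degenerate=degen))
    return out


def evaluate_scores(risk_frame, labels, n_boot: int = 2000,
                    seed: int = 0) -> list:
    """AUROC/AUPRC with bootstrap CIs for every column of a risk frame.

    ``risk_frame`` is a pandas DataFrame of oriented risks (larger = worse);
    each score gets its own bootstrap substream derived from ``seed``.
    """
    labels = np.asarray(labels, dtype=int)
    prevalence = float(labels.mean())
    results = []
    sub = np.random.SeedSequence(seed).generate_state(2 * len(risk_frame.columns))
    for idx, name in enumerate(risk_frame.columns):
        risk = risk_frame[name].to_numpy(dtype=float)
        results.append(DiscriminationResult(
            name=name,
            auroc=auroc(risk, labels),
            auprc=auprc(risk, labels),
            ci_auroc=bootstrap_ci(auroc, risk, labels, n_boot=n_boot,
                                  seed=int(sub[2 * idx] % (2**31))),
            ci_auprc=bootstrap_ci(auprc, risk, labels, n_boot=n_boot,
                                  seed=int(sub[2 * idx + 1] % (2**31))),
            n_boot=n_boot,
            prevalence=prevalence,
        ))
    return results
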