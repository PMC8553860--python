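"""Diagnostic-accuracy statistics for clustered paired designs.

The validation statistics used throughout the pipeline:

* nonparametric AUC (Az) with DeLong's structural-components variance and
  the paired DeLong z-test for comparing correlated AUCs measured on the
  same sites;
* sensitivity / specificity / accuracy from contingency tables, with
  standard errors from the cluster ratio estimator (sites are nested within
  teeth, so binomial SEs would be anti-conservative);
* McNemar's exact test (paired binary outcomes) and the McNemar-Bowker
  symmetry test (paired ordinal scores, e.g. in vivo vs. in vitro);
* Spearman's rank correlation with a clustered-bootstrap standard error;
* compact significance letter groups (A > B > C) for table displays;
* the Burderer minimum-sample-size formula for diagnostic studies.

DeLong's method: with positive scores ``X_1..X_m`` and negative scores
``Y_1..Y_n``, Az is the Mann-Whitney statistic (ties counted 1/2) and the
placement values ``V10_i = P-hat(Y < X_i)``, ``V01_j = P-hat(Y_j < X)`` give
``Var(Az) = S10/m + S01/n`` with empirical (co)variances of the placements;
the same components yield the covariance between two scores measured on the
same sites, hence the paired z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateLabelsError, DomainError

__all__ = [
    "RocResult",
    "ContingencyTable",
    "auc_delong",
    "delong_paired_test",
    "se_sp_acc",
    "cluster_se",
    "mcnemar",
    "mcnemar_counts",
    "mcnemar_bowker",
    "mcnemar_bowker_table",
    "paired_ordinal_table",
    "spearman_rs",
    "letter_groups",
    "burderer_n",
]


# -- AUC / DeLong ---------------------------------------------------------


@dataclass
class RocResult:
    """AUC with DeLong variance; placement values retained for paired tests."""

    az: float
    az_se: float
    n_pos: int
    n_neg: int
    v10: np.ndarray = field(repr=False)
    v01: np.ndarray = field(repr=False)


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ConfigurationError("scores and labels must be equal-length 1-d arrays")
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise DegenerateLabelsError(f"need both classes, got {m} positive / {n} negative")
    return scores[labels], scores[~labels], m, n


def auc_delong(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """Mann-Whitney AUC (ties 1/2) with DeLong structural-components SE."""
    x, y, m, n = _split_scores(scores, labels)
    r_all = sps.rankdata(np.concatenate([x, y]))
    r_x = sps.rankdata(x)
    r_y = sps.rankdata(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    az = float((r_all[:m].sum() - m * (m + 1) / 2) / (m * n))
    s10 = float(v10.var(ddof=1)) if m > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if n > 1 else 0.0
    return RocResult(
        az=az, az_se=math.sqrt(s10 / m + s01 / n), n_pos=m, n_neg=n, v10=v10, v01=v01
    )


def delong_paired_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """Two-sided paired comparison of two AUCs measured on the same sites.

    Sites missing either score are dropped (complete-case pairing); returns
    (z, p).  Identical scores give z = 0, p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b, labels = a[keep], b[keep], labels[keep]
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise DegenerateLabelsError("paired AUC test needs >= 2 sites per class after pairing")
    ra = auc_delong(a, labels)
    rb = auc_delong(b, labels)
    m, n = ra.n_pos, ra.n_neg
    cov10 = float(np.cov(ra.v10, rb.v10, ddof=1)[0, 1])
    cov01 = float(np.cov(ra.v01, rb.v01, ddof=1)[0, 1])
    var = ra.az_se**2 + rb.az_se**2 - 2.0 * (cov10 / m + cov01 / n)
    if var <= 0:
        return 0.0, 1.0
    z = (ra.az - rb.az) / math.sqrt(var)
    return float(z), float(2.0 * sps.norm.sf(abs(z)))


# -- contingency tables and proportions -----------------------------------


@dataclass
class ContingencyTable:
    """2x2 counts with a per-cluster (tooth) breakdown."""

    tp: int
    fp: int
    fn: int
    tn: int
    per_cluster: list[tuple[str, int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("contingency counts must be non-negative")
        if self.per_cluster:
            sums = np.array([c[1:] for c in self.per_cluster]).sum(axis=0)
            if tuple(sums) != (self.tp, self.fp, self.fn, self.tn):
                raise DomainError("per-cluster counts do not sum to the totals")

    @classmethod
    def from_predictions(cls, predicted, truth, clusters) -> "ContingencyTable":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        clusters = np.asarray(clusters)
        per_cluster = []
        for cid in pd_unique(clusters):
            sel = clusters == cid
            p, t = predicted[sel], truth[sel]
            per_cluster.append(
                (
                    str(cid),
                    int((p & t).sum()),
                    int((p & ~t).sum()),
                    int((~p & t).sum()),
                    int((~p & ~t).sum()),
                )
            )
        totals = np.array([c[1:] for c in per_cluster]).sum(axis=0)
        return cls(*map(int, totals), per_cluster=per_cluster)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def pd_unique(values: np.ndarray) -> np.ndarray:
    """First-appearance-order unique values (stable across runs)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def se_sp_acc(table: ContingencyTable) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); errors on empty margins."""
    if table.tp + table.fn == 0:
        raise DomainError("sensitivity undefined: no truly positive sites")
    if table.tn + table.fp == 0:
        raise DomainError("specificity undefined: no truly negative sites")
    se = table.tp / (table.tp + table.fn)
    sp = table.tn / (table.tn + table.fp)
    acc = (table.tp + table.tn) / table.n
    return se, sp, acc


def cluster_se(outcomes: Sequence[float], cluster_ids: Sequence) -> float:
    """Ratio-estimator SE of a proportion under cluster sampling.

    ``var = K/(K-1) * sum_k (a_k - p n_k)^2 / (sum_k n_k)^2`` with K clusters,
    a_k successes and n_k trials in cluster k.  Requires >= 2 clusters.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if outcomes.size == 0:
        raise DomainError("cluster_se needs at least one outcome")
    uniq = pd_unique(cluster_ids)
    k = len(uniq)
    if k < 2:
        raise DomainError("cluster ratio estimator requires >= 2 clusters")
    a = np.array([outcomes[cluster_ids == c].sum() for c in uniq])
    n = np.array([(cluster_ids == c).sum() for c in uniq])
    p = outcomes.mean()
    var = (k / (k - 1)) * float(np.sum((a - p * n) ** 2)) / float(n.sum()) ** 2
    return math.sqrt(var)


# -- paired tests ---------------------------------------------------------


def mcnemar_counts(b: int, c: int) -> float:
    """Exact two-sided McNemar p from the discordant-pair counts."""
    if b < 0 or c < 0:
        raise DomainError("discordant counts must be non-negative")
    n_d = b + c
    if n_d == 0:
        return 1.0
    return float(sps.binomtest(min(b, c), n_d, 0.5).pvalue)


def mcnemar(outcomes_a: Sequence[bool], outcomes_b: Sequence[bool]) -> float:
    """Exact McNemar test on paired binary outcomes."""
    a = np.asarray(outcomes_a, dtype=bool)
    b = np.asarray(outcomes_b, dtype=bool)
    if a.shape != b.shape:
        raise ConfigurationError("paired outcome vectors must have equal length")
    return mcnemar_counts(int((a & ~b).sum()), int((~a & b).sum()))


def paired_ordinal_table(
    scores_a: Sequence[int], scores_b: Sequence[int], k: int
) -> np.ndarray:
    """k x k cross table of paired ordinal scores."""
    a = np.asarray(scores_a, dtype=int)
    b = np.asarray(scores_b, dtype=int)
    if a.shape != b.shape:
        raise ConfigurationError("paired score vectors must have equal length")
    if a.size and (a.min() < 0 or b.min() < 0 or a.max() >= k or b.max() >= k):
        raise DomainError(f"ordinal scores must lie in 0..{k - 1}")
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def mcnemar_bowker_table(table: np.ndarray) -> tuple[float, int, float]:
    """Bowker symmetry test on a square paired table.

    Degrees of freedom count only the informative off-diagonal pairs
    (``n_ij + n_ji > 0``); an all-symmetric table gives (0, 0, 1).
    """
    table = np.asarray(table)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ConfigurationError(f"Bowker test needs a square table, got {table.shape}")
    k = table.shape[0]
    stat, df = 0.0, 0
    for i in range(k):
        for j in range(i + 1, k):
            s = table[i, j] + table[j, i]
            if s > 0:
                stat += (table[i, j] - table[j, i]) ** 2 / s
                df += 1
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return float(stat), df, p


def mcnemar_bowker(
    scores_a: Sequence[int], scores_b: Sequence[int], k: int
) -> tuple[float, int, float]:
    """Bowker symmetry test on paired ordinal scores with k categories."""
    return mcnemar_bowker_table(paired_ordinal_table(scores_a, scores_b, k))


# -- correlation ----------------------------------------------------------


def spearman_rs(
    a: Sequence[float],
    b: Sequence[float],
    cluster_ids: Sequence,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Tie-corrected Spearman correlation with a clustered-bootstrap SE.

    The bootstrap resamples clusters (teeth) with replacement, reflecting
    the same clustering that the SE/SP standard errors adjust for.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise DomainError("Spearman correlation undefined for a constant vector")
    rs = float(sps.spearmanr(a, b).statistic)
    if rng is None:
        rng = np.random.default_rng(0)
    uniq = pd_unique(cluster_ids)
    members = [np.flatnonzero(cluster_ids == c) for c in uniq]
    reps = np.full(n_boot, np.nan)
    for i in range(n_boot):
        pick = rng.integers(0, len(members), size=len(members))
        idx = np.concatenate([members[j] for j in pick])
        ar, br = a[idx], b[idx]
        if np.unique(ar).size < 2 or np.unique(br).size < 2:
            continue
        reps[i] = sps.spearmanr(ar, br).statistic
    se = float(np.nanstd(reps, ddof=1))
    return rs, se


# -- table annotations ----------------------------------------------------


def letter_groups(
    estimates: Sequence[float], p_matrix: np.ndarray, alpha: float = 0.05
) -> list[str]:
    """Compact letter display: methods sorted descending by estimate; a method
    joins the current letter group iff not significantly different from every
    member; groups are lettered A, B, C... in order.  Output is aligned with
    the input order and invariant to it (ties sort by estimate only).
    """
    estimates = np.asarray(estimates, dtype=float)
    p_matrix = np.asarray(p_matrix, dtype=float)
    k = len(estimates)
    if p_matrix.shape != (k, k):
        raise ConfigurationError("p-value matrix must be k x k")
    order = np.argsort(-estimates, kind="stable")
    letters = [""] * k
    group: list[int] = []
    current = ord("A")
    for idx in order:
        if group and any(p_matrix[idx, j] <= alpha for j in group):
            current += 1
            group = []
        group.append(int(idx))
        letters[idx] = chr(current)
    return letters


# -- sample size ----------------------------------------------------------


def burderer_n(
    expected_se: float,
    expected_sp: float,
    alpha: float = 0.05,
    max_error: float = 0.1,
    prevalence: float = 0.5,
) -> int:
    """Burderer minimum number of sites for a diagnostic accuracy study.

    ``n_SE = ceil(Z^2 SE(1-SE) / (d^2 prev))`` and
    ``n_SP = ceil(Z^2 SP(1-SP) / (d^2 (1-prev)))`` with Z the two-sided
    normal quantile at ``alpha`` and d the absolute error; the result is the
    larger of the two.  ``prevalence`` must lie in (0, 1); the sentinel value
    1.0 disables the prevalence adjustment in both terms.
    """
    for name, v in (("expected_se", expected_se), ("expected_sp", expected_sp)):
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"{name} must be in [0, 1]")
    if max_error <= 0 or not 0 < alpha < 1:
        raise DomainError("max_error must be > 0 and alpha in (0, 1)")
    if prevalence == 1.0:
        p_se, p_sp = 1.0, 1.0
    elif 0.0 < prevalence < 1.0:
        p_se, p_sp = prevalence, 1.0 - prevalence
    else:
        raise DomainError(f"prevalence must lie in (0, 1), got {prevalence}")
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    n_se = math.ceil(z**2 * expected_se * (1 - expected_se) / (max_error**2 * p_se))
    n_sp = math.ceil(z**2 * expected_sp * (1 - expected_sp) / (max_error**2 * p_sp))
    return max(n_se, n_sp)
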