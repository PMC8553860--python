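"""ROC-based calibration of the algorithms' ordinal cut-offs.

For each algorithm and each diagnostic level (>=E1, >=D1, and for the
four-point algorithms >=D2) the raw severity scores of a labeled calibration
cohort are dichotomized against histology and the cut-off maximizing
sensitivity + specificity (the Youden-optimal operating point) is selected
from the ROC curve.  A cut-off is flagged *reliable* when SE + SP > 1.7 at
the optimum; only levels passing this rule carry an independent cut-off in
the deployed scoring scale.

Candidate thresholds are midpoints between adjacent distinct scores plus the
two infinite endpoints, so ties with data values cannot occur; among equal
maximizers the highest threshold is returned (favoring specificity).  Under
noise the per-level optima can invert across levels; a pool-adjacent-
violators pass restores the non-decreasing order that a nested ordinal scale
requires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, ConfigurationError, DegenerateLabelsError
from .histology import DiagnosticLevel, algorithm_levels

__all__ = [
    "RELIABLE_MIN_SESP",
    "RocCurve",
    "CutoffEntry",
    "CutoffSet",
    "roc_points",
    "optimal_cutoff",
    "calibrate_algorithm",
]

RELIABLE_MIN_SESP = 1.7


@dataclass
class RocCurve:
    """Empirical ROC curve with the candidate cut-offs used for calibration.

    ``points`` holds one (threshold, sensitivity, 1-specificity) triple per
    distinct score value plus the two trivial endpoints, ordered from the
    all-negative to the all-positive corner.  ``candidates`` are midpoint
    thresholds (plus +/-inf) with their SE and SP.
    """

    points: np.ndarray        # (k, 3): threshold, tpr, fpr
    candidates: np.ndarray    # (m, 3): threshold, se, sp
    n_pos: int
    n_neg: int

    @property
    def auc(self) -> float:
        fpr = self.points[:, 2]
        tpr = self.points[:, 1]
        return float(np.trapezoid(tpr, fpr))


def _se_sp_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = scores >= threshold
    se = float(np.mean(pred[labels]))
    sp = float(np.mean(~pred[~labels]))
    return se, sp


def roc_points(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC curve of a score oriented higher = positive.

    Raises :class:`DegenerateLabelsError` unless both classes are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ConfigurationError("scores and labels must be equal-length 1-d arrays")
    if np.isnan(scores).any():
        raise ConfigurationError("scores must be complete (drop missing sites first)")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError(
            f"ROC needs both classes, got {n_pos} positive / {n_neg} negative"
        )

    distinct = np.unique(scores)[::-1]  # descending
    points = [(np.inf, 0.0, 0.0)]
    for t in distinct:
        se, sp = _se_sp_at(scores, labels, t)
        points.append((float(t), se, 1.0 - sp))
    if points[-1][1:] != (1.0, 1.0):
        points.append((-np.inf, 1.0, 1.0))

    mids = (distinct[:-1] + distinct[1:]) / 2.0
    cand_thresholds = np.concatenate(([np.inf], mids, [-np.inf]))
    candidates = np.array(
        [(t, *_se_sp_at(scores, labels, t)) for t in cand_thresholds]
    )
    return RocCurve(
        points=np.array(points), candidates=candidates, n_pos=n_pos, n_neg=n_neg
    )


def optimal_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """(threshold, SE, SP) maximizing SE + SP on the curve's candidates.

    Among equal maximizers the highest threshold wins.
    """
    cands = curve.candidates
    if len(cands) == 0:
        raise CalibrationError("degenerate ROC curve: no candidate thresholds")
    sums = cands[:, 1] + cands[:, 2]
    best = sums.max()
    # candidates are ordered by descending threshold, so the first maximizer
    # is the highest threshold
    idx = int(np.flatnonzero(sums == best)[0])
    t, se, sp = cands[idx]
    return float(t), float(se), float(sp)


@dataclass
class CutoffEntry:
    level: DiagnosticLevel
    threshold: float
    se_at_cutoff: float
    sp_at_cutoff: float
    reliable: bool


@dataclass
class CutoffSet:
    """Calibrated per-level thresholds for one algorithm, sorted by level."""

    algorithm: str
    entries: list[CutoffEntry] = field(default_factory=list)

    def check(self) -> None:
        expected = algorithm_levels(self.algorithm)
        got = tuple(e.level for e in self.entries)
        if got != expected:
            raise ConfigurationError(
                f"{self.algorithm} cut-off set must carry levels "
                f"{[l.name for l in expected]}, got {[l.name for l in got]}"
            )
        thresholds = [e.threshold for e in self.entries]
        if any(b < a for a, b in zip(thresholds, thresholds[1:])):
            raise ConfigurationError(
                f"{self.algorithm} thresholds must be non-decreasing, got {thresholds}"
            )

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "entries": [
                {
                    "level": e.level.name,
                    "threshold": e.threshold,
                    "se_at_cutoff": e.se_at_cutoff,
                    "sp_at_cutoff": e.sp_at_cutoff,
                    "reliable": e.reliable,
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CutoffSet":
        out = cls(algorithm=data["algorithm"])
        for e in data["entries"]:
            out.entries.append(
                CutoffEntry(
                    level=DiagnosticLevel[e["level"]],
                    threshold=float(e["threshold"]),
                    se_at_cutoff=float(e["se_at_cutoff"]),
                    sp_at_cutoff=float(e["sp_at_cutoff"]),
                    reliable=bool(e["reliable"]),
                )
            )
        out.check()
        return out


def save_cutoff_sets(cutoff_sets: dict[str, CutoffSet], path: str | Path) -> None:
    payload = {alg: cs.to_dict() for alg, cs in sorted(cutoff_sets.items())}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_cutoff_sets(path: str | Path) -> dict[str, CutoffSet]:
    payload = json.loads(Path(path).read_text())
    return {alg: CutoffSet.from_dict(d) for alg, d in payload.items()}


def _pava_non_decreasing(values: list[float]) -> list[float]:
    """Pool adjacent violators (equal weights): closest non-decreasing sequence."""
    blocks = [[v, 1] for v in values]  # [mean, weight]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0]:
            m = (blocks[i][0] * blocks[i][1] + blocks[i + 1][0] * blocks[i + 1][1]) / (
                blocks[i][1] + blocks[i + 1][1]
            )
            blocks[i] = [m, blocks[i][1] + blocks[i + 1][1]]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out: list[float] = []
    for mean, weight in blocks:
        out.extend([mean] * weight)
    return out


def calibrate_algorithm(
    raw_scores: Sequence[float],
    histology_codes: Sequence[int],
    algorithm: str,
    levels: Sequence[DiagnosticLevel] | None = None,
) -> CutoffSet:
    """Derive the algorithm's per-level cut-offs from a calibration sample.

    Each level is an independent dichotomization of the same raw scores;
    sites with missing raw scores are dropped (complete case).  Infinite
    thresholds only arise on degenerate samples and are kept as calibrated.
    """
    if levels is None:
        levels = algorithm_levels(algorithm)
    else:
        levels = tuple(levels)
        allowed = algorithm_levels(algorithm)
        for level in levels:
            if level not in allowed:
                raise ConfigurationError(
                    f"{algorithm} cannot be calibrated at level >= {level.name}"
                )
    raw = np.asarray(raw_scores, dtype=float)
    codes = np.asarray(histology_codes, dtype=int)
    keep = ~np.isnan(raw)
    raw, codes = raw[keep], codes[keep]

    entries = []
    for level in levels:
        labels = codes >= int(level)
        if labels.sum() < 2 or (~labels).sum() < 2:
            raise CalibrationError(
                f"{algorithm} level >= {level.name}: fewer than 2 sites in a class"
            )
        threshold, se, sp = optimal_cutoff(roc_points(raw, labels))
        entries.append(
            CutoffEntry(
                level=level,
                threshold=threshold,
                se_at_cutoff=se,
                sp_at_cutoff=sp,
                reliable=bool(se + sp > RELIABLE_MIN_SESP),
            )
        )
    adjusted = _pava_non_decreasing([e.threshold for e in entries])
    for entry, t in zip(entries, adjusted):
        if t != entry.threshold:
            entry.threshold = t
            entry.se_at_cutoff, entry.sp_at_cutoff = _se_sp_at(
                raw, codes >= int(entry.level), t
            )
            entry.reliable = bool(entry.se_at_cutoff + entry.sp_at_cutoff > RELIABLE_MIN_SESP)
    return CutoffSet(algorithm=algorithm, entries=entries)


def calibrate_from_scores(
    scores: pd.DataFrame,
    algorithm: str,
    condition: str = "in_vitro",
    levels: Sequence[DiagnosticLevel] | None = None,
) -> CutoffSet:
    """Calibrate from a tidy scores frame (as built by ``score_cohort``)."""
    sel = scores[(scores["algorithm"] == algorithm) & (scores["condition"] == condition)]
    return calibrate_algorithm(
        sel["raw_score"].to_numpy(), sel["histology_code"].to_numpy(), algorithm, levels
    )
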