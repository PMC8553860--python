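"""The four automated caries-scoring algorithms.

Each algorithm maps a site's five-channel signal vector (and, except for the
first, the same tooth's sound-reference vector) to a raw severity statistic
oriented so that higher means more severe, which calibrated cut-offs then
convert to the algorithm's ordinal caries score.

* ``ALG1`` — absolute green-fluorescence loss, ``1 - G_fluo``.  Deliberately
  not invariant to overall brightness.
* ``ALG2`` — green-fluorescence loss relative to the sound reference on the
  same tooth, ``1 - G_site / G_ref``.
* ``ALG3`` — sound-normalized red/green log-ratio,
  ``log((R_site/R_ref) / (G_site/G_ref))``, combining porphyrin red gain with
  green loss; invariant to overall brightness.
* ``ALG4`` — a ridge-penalized logistic model on the five log-ratio features
  ``log(c_site / c_ref)``; the raw score is the fitted probability of caries
  (histology >= E1).

The exact functional forms of the device's proprietary algorithms are not
public; the forms above are minimal reconstructions consistent with each
algorithm's published one-sentence description, and no numerical equivalence
with the device is claimed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cohort import CONDITIONS, SignalVector, ToothRecord, cohort_sites
from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientSignalError,
    InsufficientTrainingError,
    ReferenceMissingError,
)
from .histology import ALGORITHMS, DiagnosticLevel

__all__ = [
    "Alg4Model",
    "sound_reference",
    "alg1_raw",
    "alg2_raw",
    "alg3_raw",
    "alg4_features",
    "fit_alg4",
    "fit_alg4_features",
    "alg4_raw",
    "apply_cutoffs",
    "score_cohort",
    "SCORES_COLUMNS",
]

#: Feature order of the ALG4 logistic model (log ratios to the sound reference).
ALG4_FEATURES = ("delta_Gfluo", "delta_Rfluo", "delta_R", "delta_G", "delta_B")

#: Ridge strength (inverse) for the ALG4 fit; fixed so that fits are
#: deterministic and well defined even under perfect separation.
_ALG4_C = 1000.0

SCORES_COLUMNS = [
    "site_id",
    "tooth_id",
    "condition",
    "algorithm",
    "raw_score",
    "ordinal_score",
]


def sound_reference(tooth: ToothRecord, condition: str) -> SignalVector:
    """Per-channel mean signal over the tooth's sound reference region(s)."""
    ref = tooth.sound_reference(condition)
    if ref is None:
        raise ReferenceMissingError(
            f"tooth {tooth.tooth_id} has no sound reference for {condition}"
        )
    return ref


def alg1_raw(site_signals: SignalVector) -> float:
    """Absolute green-fluorescence loss: ``1 - G_fluo``."""
    return 1.0 - site_signals.g_fluo


def alg2_raw(site_signals: SignalVector, reference: SignalVector) -> float:
    """Relative green-fluorescence loss: ``1 - G_site / G_ref``.

    Negative when the site is brighter than the sound reference.
    """
    if reference.g_fluo <= 0:
        raise InsufficientSignalError("sound-reference G_fluo is non-positive")
    return 1.0 - site_signals.g_fluo / reference.g_fluo


def alg3_raw(site_signals: SignalVector, reference: SignalVector) -> float:
    """Sound-normalized red/green log-ratio; higher = more severe."""
    values = (
        site_signals.r_fluo,
        reference.r_fluo,
        site_signals.g_fluo,
        reference.g_fluo,
    )
    if any(v <= 0 for v in values):
        raise InsufficientSignalError("non-positive fluorescence intensity in ratio")
    return math.log(
        (site_signals.r_fluo / reference.r_fluo)
        / (site_signals.g_fluo / reference.g_fluo)
    )


def alg4_features(site_signals: SignalVector, reference: SignalVector) -> np.ndarray:
    """Log-ratio features ``log(c_site / c_ref)`` in :data:`ALG4_FEATURES` order."""
    site = site_signals.as_array()
    ref = reference.as_array()
    if np.any(site <= 0) or np.any(ref <= 0):
        raise InsufficientSignalError("non-positive intensity in ALG4 feature ratio")
    # signal arrays are (R_fluo, G_fluo, R, G, B); reorder to feature order
    logr = np.log(site / ref)
    return logr[[1, 0, 2, 3, 4]]


@dataclass
class Alg4Model:
    """Fitted logistic caries model: intercept plus one weight per feature."""

    intercept: float
    coefficients: np.ndarray  # length 5, ALG4_FEATURES order
    n_train: int
    condition: str = "in_vitro"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ConfigurationError("ALG4 model needs exactly 5 feature weights")

    def predict_proba(self, features: np.ndarray) -> float:
        eta = self.intercept + float(np.dot(self.coefficients, features))
        return 1.0 / (1.0 + math.exp(-eta))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "coefficients": dict(zip(ALG4_FEATURES, self.coefficients.tolist())),
                    "n_train": self.n_train,
                    "condition": self.condition,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Alg4Model":
        data = json.loads(Path(path).read_text())
        return cls(
            intercept=float(data["intercept"]),
            coefficients=np.array([data["coefficients"][f] for f in ALG4_FEATURES]),
            n_train=int(data["n_train"]),
            condition=data.get("condition", "in_vitro"),
        )


def fit_alg4_features(features: np.ndarray, labels: np.ndarray) -> Alg4Model:
    """Fit the ALG4 logistic model on a prepared feature matrix.

    A fixed small ridge penalty keeps the fit defined and deterministic under
    perfect separation.  Requires at least 10 sites per class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if min(n_pos, n_neg) < 10:
        raise InsufficientTrainingError(
            f"need >= 10 sites per class to fit ALG4, got {n_pos} positive / {n_neg} negative"
        )
    clf = LogisticRegression(C=_ALG4_C, solver="lbfgs", max_iter=20000, tol=1e-10)
    clf.fit(features, labels.astype(int))
    return Alg4Model(
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].copy(),
        n_train=len(labels),
    )


def fit_alg4(cohort: Iterable[ToothRecord], condition: str = "in_vitro") -> Alg4Model:
    """Fit ALG4 on a labeled cohort: features are the log ratios of a site's
    signals to its tooth's sound reference; the label is histology >= E1."""
    if condition not in CONDITIONS:
        raise DomainError(f"unknown condition {condition!r}")
    rows, labels = [], []
    for tooth in cohort:
        ref = sound_reference(tooth, condition)
        for site in tooth.sites:
            sig = site.signals(condition)
            if sig is None:
                continue
            try:
                rows.append(alg4_features(sig, ref))
            except InsufficientSignalError:
                continue
            labels.append(int(site.histology_class) >= int(DiagnosticLevel.E1))
    model = fit_alg4_features(np.array(rows), np.array(labels))
    model.condition = condition
    return model


def alg4_raw(
    site_signals: SignalVector, reference: SignalVector, model: Alg4Model
) -> float:
    """Fitted caries probability in (0, 1); higher = more severe."""
    return model.predict_proba(alg4_features(site_signals, reference))


def apply_cutoffs(raw_score: float | None, cutoffs) -> int | None:
    """Ordinal score = number of calibrated cut-offs met or exceeded.

    ``None`` (insufficient) propagates.  The cut-off set must be sorted by
    level severity with non-decreasing thresholds and the algorithm's arity
    (two entries for ALG1/2, three for ALG3/4).
    """
    from .calibration import CutoffSet  # local import to avoid a cycle

    if not isinstance(cutoffs, CutoffSet):
        raise ConfigurationError("apply_cutoffs expects a CutoffSet")
    cutoffs.check()
    if raw_score is None or (isinstance(raw_score, float) and math.isnan(raw_score)):
        return None
    return sum(raw_score >= entry.threshold for entry in cutoffs.entries)


def _raw_score(
    algorithm: str,
    sig: SignalVector,
    ref: SignalVector | None,
    alg4_model: Alg4Model | None,
) -> float:
    if algorithm == "ALG1":
        return alg1_raw(sig)
    if ref is None:
        raise ReferenceMissingError(f"{algorithm} requires a sound reference")
    if algorithm == "ALG2":
        return alg2_raw(sig, ref)
    if algorithm == "ALG3":
        return alg3_raw(sig, ref)
    if alg4_model is None:
        raise ConfigurationError("ALG4 scoring requires a fitted Alg4Model")
    return alg4_raw(sig, ref, alg4_model)


def score_cohort(
    cohort: Iterable[ToothRecord],
    algorithms: tuple[str, ...] = ALGORITHMS,
    alg4_model: Alg4Model | None = None,
    cutoff_sets: dict | None = None,
) -> pd.DataFrame:
    """Raw (and, given cut-off sets, ordinal) scores for every site,
    algorithm and condition.

    Sites with missing or unusable signals propagate as NaN raw scores and
    "insufficient" ordinal scores; nothing is imputed.  Returns a tidy frame
    with :data:`SCORES_COLUMNS` plus ``histology_class`` and ``icdas`` for
    downstream analyses.
    """
    for algorithm in algorithms:
        if algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {algorithm!r}")
    rows = []
    for tooth in cohort:
        for condition in CONDITIONS:
            try:
                ref = sound_reference(tooth, condition)
            except ReferenceMissingError:
                ref = None
            for site in tooth.sites:
                sig = site.signals(condition)
                for algorithm in algorithms:
                    raw: float = math.nan
                    if sig is not None:
                        try:
                            raw = _raw_score(algorithm, sig, ref, alg4_model)
                        except (InsufficientSignalError, ReferenceMissingError):
                            raw = math.nan
                    ordinal: int | None = None
                    if cutoff_sets is not None and algorithm in cutoff_sets:
                        ordinal = apply_cutoffs(
                            None if math.isnan(raw) else raw, cutoff_sets[algorithm]
                        )
                    rows.append(
                        {
                            "site_id": site.site_id,
                            "tooth_id": site.tooth_id,
                            "condition": condition,
                            "algorithm": algorithm,
                            "raw_score": raw,
                            "ordinal_score": ordinal,
                            "histology_class": site.histology_class.name,
                            "histology_code": int(site.histology_class),
                            "icdas": site.icdas,
                        }
                    )
    return pd.DataFrame(rows)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Scores CSV: ordinal "NA" marks insufficient sites."""
    out = scores[SCORES_COLUMNS].copy()
    out.to_csv(path, index=False, na_rep="NA")
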