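"""Histological reference scoring of occlusal caries lesions.

The gold standard grades each examination site from sectioned-tooth
measurements: the maximum lesion depth together with the enamel and dentin
thickness at the same position.  Lesions confined to enamel are graded by the
fraction ``depth / enamel_thickness`` (outer vs. inner half, the inner half
including the dentin-enamel junction, DEJ); lesions past the DEJ are graded by
the fraction of dentin penetrated, ``(depth - enamel) / dentin_thickness``
(outer, middle or inner third).

The resulting six-point ordinal scale:

====== ==== ==========================================
label  code meaning
====== ==== ==========================================
E0     0    sound
E1     1    outer half of enamel (fraction < 0.5)
E2     2    inner half of enamel incl. DEJ (>= 0.5)
D1     3    outer third of dentin (fraction < 0.33)
D2     4    middle third of dentin (0.33 <= f < 0.66)
D3     5    inner third of dentin (fraction >= 0.66)
====== ==== ==========================================

Diagnostic analyses dichotomize this scale at three levels -- any caries
(>=E1), caries in dentin (>=D1), caries in the middle-inner third of dentin
(>=D2) -- and the automated scoring algorithms collapse it onto coarser
ordinal scales (0-2 for the two green-fluorescence algorithms, 0-3 for the
algorithms that separate outer from middle-inner dentin).

The dentin fraction is computed from the depth *beyond* the DEJ, which keeps
the fraction inside [0, 1]; the split points 0.5, 0.33 and 0.66 are exact
decimal constants, closed on the more severe side.
"""

from __future__ import annotations

from enum import IntEnum

from .errors import ConfigurationError, DomainError

__all__ = [
    "HistologyClass",
    "DiagnosticLevel",
    "histology_class",
    "dichotomize",
    "map_to_algorithm_scale",
    "algorithm_levels",
    "level_positivity_threshold",
    "ALGORITHMS",
]

ALGORITHMS = ("ALG1", "ALG2", "ALG3", "ALG4")

ENAMEL_SPLIT = 0.5
DENTIN_SPLIT_OUTER = 0.33
DENTIN_SPLIT_MIDDLE = 0.66


class HistologyClass(IntEnum):
    """Ordinal histological severity class; integer value is the ordinal code."""

    E0 = 0
    E1 = 1
    E2 = 2
    D1 = 3
    D2 = 4
    D3 = 5


class DiagnosticLevel(IntEnum):
    """Dichotomization threshold; value is the minimum positive ordinal code."""

    E1 = 1
    D1 = 3
    D2 = 4


def histology_class(
    lesion_depth: float, enamel_thickness: float, dentin_thickness: float
) -> HistologyClass:
    """Grade a site from its section geometry (all lengths in mm).

    Raises
    ------
    DomainError
        If a thickness is non-positive or the depth lies outside
        ``[0, enamel_thickness + dentin_thickness]``.
    """
    if enamel_thickness <= 0 or dentin_thickness <= 0:
        raise DomainError(
            f"tissue thicknesses must be positive, got enamel={enamel_thickness}, "
            f"dentin={dentin_thickness}"
        )
    if lesion_depth < 0 or lesion_depth > enamel_thickness + dentin_thickness:
        raise DomainError(
            f"lesion depth {lesion_depth} outside [0, {enamel_thickness + dentin_thickness}]"
        )
    if lesion_depth == 0:
        return HistologyClass.E0
    if lesion_depth < enamel_thickness:
        fraction = lesion_depth / enamel_thickness
        return HistologyClass.E1 if fraction < ENAMEL_SPLIT else HistologyClass.E2
    if lesion_depth == enamel_thickness:
        # lesion reaching the DEJ belongs to the inner half of enamel
        return HistologyClass.E2
    dentin_fraction = (lesion_depth - enamel_thickness) / dentin_thickness
    if dentin_fraction < DENTIN_SPLIT_OUTER:
        return HistologyClass.D1
    if dentin_fraction < DENTIN_SPLIT_MIDDLE:
        return HistologyClass.D2
    return HistologyClass.D3


def dichotomize(cls: HistologyClass, level: DiagnosticLevel) -> bool:
    """True iff the class is at or above the diagnostic level."""
    return int(cls) >= int(level)


def map_to_algorithm_scale(cls: HistologyClass, algorithm: str) -> int:
    """Collapse a histology class onto an algorithm's ordinal scoring scale.

    ALG1/ALG2 score 0 (sound) / 1 (caries in enamel) / 2 (caries in dentin);
    ALG3/ALG4 additionally separate the outer third of dentin (2) from the
    middle-inner thirds (3).
    """
    _check_algorithm(algorithm)
    code = int(cls)
    score = int(code >= 1) + int(code >= 3)
    if algorithm in ("ALG3", "ALG4"):
        score += int(code >= 4)
    return score


def algorithm_levels(algorithm: str) -> tuple[DiagnosticLevel, ...]:
    """Diagnostic levels at which an algorithm carries an independent cut-off."""
    _check_algorithm(algorithm)
    if algorithm in ("ALG1", "ALG2"):
        return (DiagnosticLevel.E1, DiagnosticLevel.D1)
    return (DiagnosticLevel.E1, DiagnosticLevel.D1, DiagnosticLevel.D2)


def level_positivity_threshold(level: DiagnosticLevel, algorithm: str) -> int:
    """Minimum ordinal score counted positive at a level, on the algorithm scale."""
    if level not in algorithm_levels(algorithm):
        raise ConfigurationError(
            f"{algorithm} has no independent cut-off at level >= {level.name}"
        )
    return map_to_algorithm_scale(HistologyClass(int(level)), algorithm)


def _check_algorithm(algorithm: str) -> None:
    if algorithm not in ALGORITHMS:
        raise ConfigurationError(f"unknown algorithm {algorithm!r}")
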