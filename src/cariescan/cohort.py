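"""Synthetic cohort generator for occlusal-caries validation studies.

Emulates the data structure of a clinical validation study of a
fluorescence-enabled intraoral scanner: extracted-tooth candidates carrying
one to three occlusal examination sites each, a histological severity class
per site, paired signal vectors captured chairside (in vivo) and after
extraction in a dark room (in vitro), an ICDAS visual score, tooth-level
random effects that cluster sites, and occasional "insufficient scan"
missingness.

The generative driver is a continuous latent severity on [0, 6): the ordinal
histology code plus the site's fractional position inside its histology band.
Severity determines the section geometry exactly (so the histology rule
applied to the geometry always returns the assigned class) and drives the
five signal channels:

* green fluorescence ``G_fluo`` decays exponentially with severity (the QLF
  premise: demineralized tissue loses green autofluorescence under 415 nm
  excitation);
* red fluorescence ``R_fluo`` rises exponentially once the lesion reaches
  dentin (porphyrin fluorescence from bacterial invasion), with an additive
  biofilm excess possible only in vivo (plaque also fluoresces red-orange);
* white-light color channels drift monotonically toward stain: R up,
  G and B down.

All channels carry a shared tooth-level log-scale random effect and
independent log-normal measurement noise, then are clipped to [0, 1].
Every tooth also carries a per-condition sound reference vector (the mean of
a few severity-zero patches on the same tooth), which the ratio-based scoring
algorithms use to cancel the tooth effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigurationError, DomainError
from .histology import HistologyClass, histology_class

__all__ = [
    "CONDITIONS",
    "CohortConfig",
    "SignalVector",
    "SiteRecord",
    "ToothRecord",
    "generate_cohort",
    "signal_model",
    "icdas_observer",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "study_config",
    "cohort_sites",
    "SOUND_REF_ID",
    "COHORT_COLUMNS",
]

CONDITIONS = ("in_vivo", "in_vitro")
SOUND_REF_ID = "SOUND_REF"

#: Fixed, documented cohort CSV header (one row per site per condition; sound
#: references stored as rows with site_id == "SOUND_REF").
COHORT_COLUMNS = [
    "site_id",
    "tooth_id",
    "condition",
    "R_fluo",
    "G_fluo",
    "R",
    "G",
    "B",
    "lesion_depth_mm",
    "enamel_thickness_mm",
    "dentin_thickness_mm",
    "histology_class",
    "icdas",
    "missing",
    "latent_severity",
    "tooth_effect",
]

_CHANNELS = ("R_fluo", "G_fluo", "R", "G", "B")

# histology band edges on the latent severity scale (code + fraction position)
_DENTIN_ONSET_SEVERITY = 3.0


@dataclass(frozen=True)
class SignalVector:
    """One site's five measured channels, normalized intensities in [0, 1]."""

    r_fluo: float
    g_fluo: float
    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array([self.r_fluo, self.g_fluo, self.r, self.g, self.b])

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "SignalVector":
        return cls(*(float(v) for v in values))


def mean_signal(vectors: Sequence[SignalVector]) -> SignalVector:
    """Per-channel arithmetic mean, e.g. over a tooth's sound patches."""
    if not vectors:
        raise DomainError("mean_signal needs at least one vector")
    return SignalVector.from_array(
        np.mean([v.as_array() for v in vectors], axis=0)
    )


@dataclass
class SiteRecord:
    site_id: str
    tooth_id: str
    lesion_depth: float
    enamel_thickness: float
    dentin_thickness: float
    histology_class: HistologyClass
    latent_severity: float
    signals_in_vivo: SignalVector | None
    signals_in_vitro: SignalVector | None
    icdas: int
    missing_in_vivo: bool
    missing_in_vitro: bool

    def signals(self, condition: str) -> SignalVector | None:
        return self.signals_in_vivo if condition == "in_vivo" else self.signals_in_vitro

    def missing(self, condition: str) -> bool:
        return self.missing_in_vivo if condition == "in_vivo" else self.missing_in_vitro


@dataclass
class ToothRecord:
    tooth_id: str
    tooth_effect: float
    sound_reference_in_vivo: SignalVector
    sound_reference_in_vitro: SignalVector
    sites: list[SiteRecord] = field(default_factory=list)

    def sound_reference(self, condition: str) -> SignalVector:
        if condition == "in_vivo":
            return self.sound_reference_in_vivo
        return self.sound_reference_in_vitro


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    ``class_targets`` is either a 6-vector of integer counts per histology
    class E0..D3 (realized exactly, by dealing classes without replacement)
    or a 6-vector of float probabilities summing to 1 (classes drawn i.i.d.).
    The study preset uses counts.
    """

    n_teeth: int = 53
    sites_per_tooth: tuple[int, int] = (1, 3)
    class_targets: tuple = (17, 40, 39, 8, 9, 5)
    # section geometry (mm): occlusal enamel ~1.2 mm, dentin ~3 mm
    enamel_thickness: tuple[float, float] = (1.2, 0.15)
    dentin_thickness: tuple[float, float] = (3.0, 0.4)
    # baseline normalized intensities at severity zero
    g0: float = 0.80
    r0: float = 0.10
    color_baseline: tuple[float, float, float] = (0.75, 0.72, 0.65)
    # green-fluorescence decay and red-fluorescence gain per severity unit
    gamma_g: float = 0.14
    gamma_r: float = 0.06
    dentin_onset: float = _DENTIN_ONSET_SEVERITY
    # color stain drift per severity unit: R up, G down, B down (log scale)
    stain_slopes: tuple[float, float, float] = (0.03, 0.04, 0.05)
    tooth_effect_sd: float = 0.15
    # per-condition measurement SD, scalar or per-channel 5-vector in
    # (R_fluo, G_fluo, R, G, B) order; in vitro scanning (dark room) is
    # slightly less noisy, red fluorescence is measured more stably than green
    noise_sd: Mapping[str, object] = field(
        default_factory=lambda: {
            "in_vivo": (0.11, 0.22, 0.22, 0.22, 0.22),
            "in_vitro": (0.10, 0.20, 0.20, 0.20, 0.20),
        }
    )
    plaque_prob_in_vivo: float = 0.15
    plaque_excess: float = 0.06
    p_missing: Mapping[str, float] = field(
        default_factory=lambda: {"in_vivo": 0.04, "in_vitro": 0.02}
    )
    icdas_spread: float = 0.8
    n_sound_refs: int = 3
    seed: int = 0

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        lo, hi = self.sites_per_tooth
        if not (1 <= lo <= hi <= 3):
            raise ConfigurationError(
                f"sites_per_tooth must satisfy 1 <= min <= max <= 3, got {self.sites_per_tooth}"
            )
        if self.n_teeth < 1:
            raise ConfigurationError("n_teeth must be >= 1")
        for name, value in [
            ("plaque_prob_in_vivo", self.plaque_prob_in_vivo),
            *((f"p_missing[{k}]", v) for k, v in self.p_missing.items()),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        for name, value in [
            ("g0", self.g0),
            ("r0", self.r0),
            *zip(("color_R", "color_G", "color_B"), self.color_baseline),
            ("enamel_thickness mean", self.enamel_thickness[0]),
            ("dentin_thickness mean", self.dentin_thickness[0]),
        ]:
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if len(self.class_targets) != 6:
            raise ConfigurationError("class_targets must have 6 entries (E0..D3)")
        counts, targets = self._class_spec()
        if counts:
            total = int(sum(targets))
            if not lo * self.n_teeth <= total <= hi * self.n_teeth:
                raise ConfigurationError(
                    f"class_targets sum to {total} sites, infeasible for "
                    f"{self.n_teeth} teeth with {lo}-{hi} sites each"
                )
        else:
            if any(p < 0 for p in targets) or not math.isclose(sum(targets), 1.0):
                raise ConfigurationError("class probabilities must be >= 0 and sum to 1")

    def _class_spec(self) -> tuple[bool, tuple]:
        """(as_counts, targets); counts iff every entry is an integer type."""
        as_counts = all(isinstance(x, (int, np.integer)) for x in self.class_targets)
        return as_counts, tuple(self.class_targets)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        kwargs = dict(data)
        for key in ("sites_per_tooth", "class_targets", "enamel_thickness",
                    "dentin_thickness", "color_baseline", "stain_slopes"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        unknown = set(kwargs) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigurationError(f"unknown cohort config fields: {sorted(unknown)}")
        return cls(**kwargs)


def study_config(seed: int = 0, **overrides) -> CohortConfig:
    """The study-replica preset: 53 teeth, 118 sites, composition 17/79/8/14
    (grouped as sound / enamel / outer dentin / middle-inner dentin)."""
    return replace(CohortConfig(seed=seed), **overrides)


# -- signal and observer models ------------------------------------------


def signal_model(
    latent_severity: float,
    condition: str,
    tooth_effect: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SignalVector:
    """Draw one site's five-channel signal vector.

    Deterministic and identical across conditions when noise, tooth effect
    and the in vivo plaque probability are all zero.
    """
    if latent_severity < 0:
        raise DomainError(f"latent severity must be >= 0, got {latent_severity}")
    if condition not in CONDITIONS:
        raise DomainError(f"unknown condition {condition!r}")
    sd = np.broadcast_to(np.asarray(config.noise_sd[condition], dtype=float), (5,))
    eps = rng.normal(0.0, 1.0, size=5) * sd if sd.any() else np.zeros(5)
    te = tooth_effect
    s = latent_severity
    g_fluo = config.g0 * math.exp(-config.gamma_g * s + te + eps[1])
    r_fluo = config.r0 * math.exp(
        config.gamma_r * max(0.0, s - config.dentin_onset) + te + eps[0]
    )
    if condition == "in_vivo" and rng.random() < config.plaque_prob_in_vivo:
        r_fluo += config.plaque_excess
    s_r, s_g, s_b = config.stain_slopes
    c_r, c_g, c_b = config.color_baseline
    r = c_r * math.exp(+s_r * s + te + eps[2])
    g = c_g * math.exp(-s_g * s + te + eps[3])
    b = c_b * math.exp(-s_b * s + te + eps[4])
    clip = lambda v: min(1.0, max(0.0, v))
    return SignalVector(clip(r_fluo), clip(g_fluo), clip(r), clip(g), clip(b))


_ICDAS_MAP = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4, 5: 5}  # E0..D3 -> ICDAS 0..5


def icdas_observer(
    cls: HistologyClass, icdas_spread: float, rng: np.random.Generator
) -> int:
    """Simulated visual examiner: monotone base mapping E0..D3 -> 0..5 plus a
    symmetric rounded-Gaussian perturbation, clipped to the 0..6 ICDAS range."""
    base = _ICDAS_MAP[int(cls)]
    perturb = int(round(rng.normal(0.0, icdas_spread))) if icdas_spread > 0 else 0
    return min(6, max(0, base + perturb))


# -- cohort generation ----------------------------------------------------

# severity band (lo, width) per class on the within-band fraction scale
_BAND_GEOMETRY = {
    1: (0.0, 0.5),    # E1: enamel fraction in (0, 0.5)
    2: (0.5, 0.5),    # E2: enamel fraction in [0.5, 1)
    3: (0.0, 0.33),   # D1: dentin fraction in (0, 0.33)
    4: (0.33, 0.33),  # D2: dentin fraction in [0.33, 0.66)
    5: (0.66, 0.34),  # D3: dentin fraction in [0.66, 1)
}

# keep sampled fractions strictly inside the open parts of each band
_FRACTION_MARGIN = (0.02, 0.98)


def _geometry_for_class(
    code: int, enamel: float, dentin: float, u: float
) -> tuple[float, float]:
    """(lesion_depth, latent_severity) for a class code and band position u."""
    if code == 0:
        return 0.0, 0.0
    lo, width = _BAND_GEOMETRY[code]
    fraction = lo + width * u
    if code <= 2:
        depth = enamel * fraction
    else:
        depth = enamel + dentin * fraction
    return depth, code + u


def generate_cohort(config: CohortConfig) -> list[ToothRecord]:
    """Generate a seeded cohort of teeth with examination sites.

    Deterministic given ``config.seed``.  When ``class_targets`` are counts
    the realized histology composition matches them exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.sites_per_tooth
    as_counts, targets = config._class_spec()

    n_sites = rng.integers(lo, hi + 1, size=config.n_teeth)
    if as_counts:
        total = int(sum(targets))
        while n_sites.sum() > total:
            idx = rng.choice(np.flatnonzero(n_sites > lo))
            n_sites[idx] -= 1
        while n_sites.sum() < total:
            idx = rng.choice(np.flatnonzero(n_sites < hi))
            n_sites[idx] += 1
        labels = rng.permutation(np.repeat(np.arange(6), targets))
    else:
        total = int(n_sites.sum())
        labels = rng.choice(6, size=total, p=np.asarray(targets, dtype=float))

    teeth: list[ToothRecord] = []
    k = 0
    for t in range(config.n_teeth):
        tooth_id = f"T{t + 1:03d}"
        te = rng.normal(0.0, config.tooth_effect_sd) if config.tooth_effect_sd > 0 else 0.0
        refs = {
            condition: mean_signal(
                [
                    signal_model(0.0, condition, te, config, rng)
                    for _ in range(config.n_sound_refs)
                ]
            )
            for condition in CONDITIONS
        }
        tooth = ToothRecord(
            tooth_id=tooth_id,
            tooth_effect=float(te),
            sound_reference_in_vivo=refs["in_vivo"],
            sound_reference_in_vitro=refs["in_vitro"],
        )
        for s in range(int(n_sites[t])):
            code = int(labels[k])
            k += 1
            enamel = max(float(rng.normal(*config.enamel_thickness)), 0.3)
            dentin = max(float(rng.normal(*config.dentin_thickness)), 1.0)
            u = float(rng.uniform(*_FRACTION_MARGIN))
            depth, severity = _geometry_for_class(code, enamel, dentin, u)
            cls = histology_class(depth, enamel, dentin)
            assert cls == HistologyClass(code)  # generator invariant
            missing = {c: bool(rng.random() < config.p_missing[c]) for c in CONDITIONS}
            signals = {
                c: None if missing[c] else signal_model(severity, c, te, config, rng)
                for c in CONDITIONS
            }
            tooth.sites.append(
                SiteRecord(
                    site_id=f"{tooth_id}_S{s + 1}",
                    tooth_id=tooth_id,
                    lesion_depth=depth,
                    enamel_thickness=enamel,
                    dentin_thickness=dentin,
                    histology_class=cls,
                    latent_severity=severity,
                    signals_in_vivo=signals["in_vivo"],
                    signals_in_vitro=signals["in_vitro"],
                    icdas=icdas_observer(cls, config.icdas_spread, rng),
                    missing_in_vivo=missing["in_vivo"],
                    missing_in_vitro=missing["in_vitro"],
                )
            )
        teeth.append(tooth)
    return teeth


def cohort_sites(cohort: Iterable[ToothRecord]) -> list[SiteRecord]:
    return [site for tooth in cohort for site in tooth.sites]


# -- CSV round trip -------------------------------------------------------


def cohort_to_frame(cohort: Iterable[ToothRecord]) -> pd.DataFrame:
    rows = []
    for tooth in cohort:
        for condition in CONDITIONS:
            ref = tooth.sound_reference(condition)
            rows.append(
                {
                    "site_id": SOUND_REF_ID,
                    "tooth_id": tooth.tooth_id,
                    "condition": condition,
                    **dict(zip(_CHANNELS, ref.as_array())),
                    "missing": 0,
                    "tooth_effect": tooth.tooth_effect,
                }
            )
        for site in tooth.sites:
            for condition in CONDITIONS:
                sig = site.signals(condition)
                row = {
                    "site_id": site.site_id,
                    "tooth_id": site.tooth_id,
                    "condition": condition,
                    "lesion_depth_mm": site.lesion_depth,
                    "enamel_thickness_mm": site.enamel_thickness,
                    "dentin_thickness_mm": site.dentin_thickness,
                    "histology_class": site.histology_class.name,
                    "icdas": site.icdas,
                    "missing": int(site.missing(condition)),
                    "latent_severity": site.latent_severity,
                    "tooth_effect": tooth.tooth_effect,
                }
                if sig is not None:
                    row.update(dict(zip(_CHANNELS, sig.as_array())))
                rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


_FLOAT_COLUMNS = (
    *_CHANNELS,
    "lesion_depth_mm",
    "enamel_thickness_mm",
    "dentin_thickness_mm",
    "latent_severity",
    "tooth_effect",
)


def write_cohort(cohort: Iterable[ToothRecord], path: str | Path) -> None:
    """Write the cohort CSV (lossless round trip via :func:`read_cohort`)."""
    frame = cohort_to_frame(cohort)
    for col in _FLOAT_COLUMNS:
        # shortest round-trip repr keeps the file lossless to the bit
        frame[col] = frame[col].map(
            lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        )
    frame.to_csv(path, index=False, na_rep="")


def read_cohort(path: str | Path) -> list[ToothRecord]:
    """Read a cohort CSV, enforcing the cohort invariants.

    Raises :class:`CohortValidationError` naming the offending row for
    missing columns, duplicate site/condition rows, or a histology class
    inconsistent with the stored geometry.
    """
    frame = pd.read_csv(
        path,
        dtype={"site_id": str, "tooth_id": str, "condition": str},
        float_precision="round_trip",
    )
    missing_cols = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortValidationError(f"cohort file {path} lacks columns {missing_cols}")
    if frame.empty:
        return []

    is_ref = frame["site_id"] == SOUND_REF_ID
    site_rows = frame[~is_ref]
    dup = site_rows.duplicated(subset=["site_id", "condition"])
    if dup.any():
        bad = site_rows[dup].iloc[0]
        raise CohortValidationError(
            f"duplicate rows for site {bad['site_id']} / {bad['condition']}"
        )

    teeth: dict[str, ToothRecord] = {}
    for tooth_id, group in frame.groupby("tooth_id", sort=False):
        refs = {}
        for condition in CONDITIONS:
            sel = group[(group["site_id"] == SOUND_REF_ID) & (group["condition"] == condition)]
            if len(sel) != 1:
                raise CohortValidationError(
                    f"tooth {tooth_id} must carry exactly one {condition} sound reference"
                )
            refs[condition] = SignalVector.from_array(sel.iloc[0][list(_CHANNELS)])
        teeth[tooth_id] = ToothRecord(
            tooth_id=tooth_id,
            tooth_effect=float(group.iloc[0]["tooth_effect"]),
            sound_reference_in_vivo=refs["in_vivo"],
            sound_reference_in_vitro=refs["in_vitro"],
        )

    for site_id, group in site_rows.groupby("site_id", sort=False):
        first = group.iloc[0]
        tooth_id = first["tooth_id"]
        try:
            cls = HistologyClass[first["histology_class"]]
        except KeyError as exc:
            raise CohortValidationError(
                f"site {site_id}: unknown histology class {first['histology_class']!r}"
            ) from exc
        try:
            derived = histology_class(
                float(first["lesion_depth_mm"]),
                float(first["enamel_thickness_mm"]),
                float(first["dentin_thickness_mm"]),
            )
        except DomainError as exc:
            raise CohortValidationError(f"site {site_id}: invalid geometry ({exc})") from exc
        if derived != cls:
            raise CohortValidationError(
                f"site {site_id}: histology_class {cls.name} contradicts geometry "
                f"(rule gives {derived.name})"
            )
        by_cond = {}
        for condition in CONDITIONS:
            sel = group[group["condition"] == condition]
            if len(sel) != 1:
                raise CohortValidationError(
                    f"site {site_id} must have exactly one {condition} row"
                )
            row = sel.iloc[0]
            missing = bool(int(row["missing"]))
            sig = None if missing else SignalVector.from_array(row[list(_CHANNELS)])
            by_cond[condition] = (missing, sig)
        teeth[tooth_id].sites.append(
            SiteRecord(
                site_id=site_id,
                tooth_id=tooth_id,
                lesion_depth=float(first["lesion_depth_mm"]),
                enamel_thickness=float(first["enamel_thickness_mm"]),
                dentin_thickness=float(first["dentin_thickness_mm"]),
                histology_class=cls,
                latent_severity=float(first["latent_severity"]),
                signals_in_vivo=by_cond["in_vivo"][1],
                signals_in_vitro=by_cond["in_vitro"][1],
                icdas=int(first["icdas"]),
                missing_in_vivo=by_cond["in_vivo"][0],
                missing_in_vitro=by_cond["in_vitro"][0],
            )
        )
    return list(teeth.values())
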