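"""Seeded, config-driven pipeline: generate -> calibrate -> score -> validate -> report.

Mirrors the design of a clinical validation study: cut-offs are calibrated
on one cohort (the "prior study" sample) and validated on an independent
blind cohort; the validation statistics are computed per method, condition
and diagnostic level and assembled into a Table-2-style report with
significance letter groups.  The visual (ICDAS) method is assessed in vivo
only, at the >=E1 and >=D2 levels — no ICDAS score reliably separates
enamel lesions from initial outer-dentin lesions, so the >=D1 level is
guarded against.

Reruns with the same configuration and seed reproduce byte-identical CSV
outputs; a manifest records the configuration hash, seed and library
versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CutoffSet, calibrate_from_scores, save_cutoff_sets
from .cohort import (
    CONDITIONS,
    CohortConfig,
    ToothRecord,
    cohort_sites,
    generate_cohort,
    study_config,
    write_cohort,
)
from .errors import ConfigurationError
from .histology import (
    ALGORITHMS,
    DiagnosticLevel,
    level_positivity_threshold,
)
from .scoring import Alg4Model, fit_alg4, score_cohort, write_scores
from .stats import (
    ContingencyTable,
    auc_delong,
    cluster_se,
    delong_paired_test,
    letter_groups,
    mcnemar,
    mcnemar_bowker,
    se_sp_acc,
    spearman_rs,
)

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "diagnostic_summary",
    "condition_agreement",
    "format_report",
    "study_run_config",
    "VISUAL",
    "VISUAL_POSITIVITY",
]

log = logging.getLogger("cariescan")

VISUAL = "VISUAL"
#: ICDAS score counted positive at each visual level (>=D1 is never assessed).
VISUAL_POSITIVITY = {DiagnosticLevel.E1: 1, DiagnosticLevel.D2: 3}
VISUAL_LEVELS = (DiagnosticLevel.E1, DiagnosticLevel.D2)

_LEVELS = (DiagnosticLevel.E1, DiagnosticLevel.D1, DiagnosticLevel.D2)
_ALG_SCALE = {"ALG1": 3, "ALG2": 3, "ALG3": 4, "ALG4": 4}

SUMMARY_COLUMNS = [
    "condition",
    "level",
    "method",
    "metric",
    "estimate",
    "se",
    "letter",
    "n_used",
    "n_missing",
]


@dataclass
class RunConfig:
    calibration: CohortConfig = field(default_factory=CohortConfig)
    validation: CohortConfig = field(default_factory=CohortConfig)
    algorithms: tuple[str, ...] = ALGORITHMS
    include_visual: bool = True
    alpha: float = 0.05
    bootstrap_reps: int = 2000
    calibrate_in_sample: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.bootstrap_reps < 2:
            raise ConfigurationError("bootstrap_reps must be >= 2")
        for algorithm in self.algorithms:
            if algorithm not in ALGORITHMS:
                raise ConfigurationError(f"unknown algorithm {algorithm!r}")

    def resolved_cohort_configs(self) -> tuple[CohortConfig, CohortConfig]:
        """Cohort configs with seeds derived from the run seed: calibration
        uses the seed itself, validation an offset draw (independent sample)."""
        cal = dataclasses.replace(self.calibration, seed=self.seed)
        val = dataclasses.replace(self.validation, seed=self.seed + 104729)
        if self.calibrate_in_sample:
            val = cal
        return cal, val

    def to_dict(self) -> dict:
        raw = {
            "calibration": dataclasses.asdict(self.calibration),
            "validation": dataclasses.asdict(self.validation),
            "algorithms": list(self.algorithms),
            "include_visual": self.include_visual,
            "alpha": self.alpha,
            "bootstrap_reps": self.bootstrap_reps,
            "calibrate_in_sample": self.calibrate_in_sample,
            "seed": self.seed,
        }
        # canonical JSON types (tuples -> lists) so YAML/JSON round trips
        # and the manifest hash are stable
        return json.loads(json.dumps(raw))

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        for key in ("calibration", "validation"):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = CohortConfig.from_dict(kwargs[key])
        if "algorithms" in kwargs:
            kwargs["algorithms"] = tuple(kwargs["algorithms"])
        unknown = set(kwargs) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ConfigurationError(f"unknown run config fields: {sorted(unknown)}")
        return cls(**kwargs)


def study_run_config(seed: int = 0, **overrides) -> RunConfig:
    """Study-replica run: independent calibration and validation cohorts
    drawn from the default preset (53 teeth / 118 sites each)."""
    return RunConfig(
        calibration=study_config(), validation=study_config(), seed=seed, **overrides
    )


# -- per-method site frames ----------------------------------------------


def _method_frame(
    method: str, condition: str, cohort: Sequence[ToothRecord], scores: pd.DataFrame
) -> pd.DataFrame:
    """One row per site: raw score (ROC input), ordinal score, histology."""
    if method == VISUAL:
        if condition != "in_vivo":
            raise ConfigurationError("the visual examination is only performed in vivo")
        sites = cohort_sites(cohort)
        return pd.DataFrame(
            {
                "site_id": [s.site_id for s in sites],
                "tooth_id": [s.tooth_id for s in sites],
                "raw": [float(s.icdas) for s in sites],
                "ordinal": [float(s.icdas) for s in sites],
                "histology_code": [int(s.histology_class) for s in sites],
            }
        )
    sel = scores[(scores["algorithm"] == method) & (scores["condition"] == condition)]
    return pd.DataFrame(
        {
            "site_id": sel["site_id"].to_numpy(),
            "tooth_id": sel["tooth_id"].to_numpy(),
            "raw": sel["raw_score"].to_numpy(dtype=float),
            "ordinal": sel["ordinal_score"].to_numpy(dtype=float),
            "histology_code": sel["histology_code"].to_numpy(dtype=int),
        }
    )


def _positivity(method: str, level: DiagnosticLevel, ordinal: np.ndarray) -> np.ndarray:
    if method == VISUAL:
        return ordinal >= VISUAL_POSITIVITY[level]
    return ordinal >= level_positivity_threshold(level, method)


def _method_levels(method: str) -> tuple[DiagnosticLevel, ...]:
    if method == VISUAL:
        return VISUAL_LEVELS
    from .histology import algorithm_levels

    return algorithm_levels(method)


# -- summary --------------------------------------------------------------


def diagnostic_summary(
    cohort: Sequence[ToothRecord],
    scores: pd.DataFrame,
    algorithms: tuple[str, ...] = ALGORITHMS,
    include_visual: bool = True,
    alpha: float = 0.05,
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """The validation table: per condition, method and level, Az (DeLong SE),
    SE and SP (cluster-adjusted SEs), ACC, plus per-method Spearman r_s with
    clustered-bootstrap SE and significance letter groups within each row."""
    rng = np.random.default_rng(seed + 7919)
    rows: list[dict] = []
    for condition in CONDITIONS:
        methods = list(algorithms)
        if include_visual and condition == "in_vivo":
            methods.append(VISUAL)
        frames = {m: _method_frame(m, condition, cohort, scores) for m in methods}

        for method in methods:
            f = frames[method]
            ok = ~f["ordinal"].isna()
            rs, rs_se = spearman_rs(
                f.loc[ok, "ordinal"],
                f.loc[ok, "histology_code"],
                f.loc[ok, "tooth_id"],
                n_boot=bootstrap_reps,
                rng=rng,
            )
            rows.append(
                dict(
                    condition=condition,
                    level="",
                    method=method,
                    metric="rs",
                    estimate=rs,
                    se=rs_se,
                    letter="",
                    n_used=int(ok.sum()),
                    n_missing=int((~ok).sum()),
                )
            )

        for level in _LEVELS:
            level_methods = [m for m in methods if level in _method_levels(m)]
            if not level_methods:
                continue
            cells: dict[str, dict] = {}
            for method in level_methods:
                f = frames[method]
                ok = ~f["raw"].isna()
                labels = (f["histology_code"].to_numpy() >= int(level))[ok]
                raw = f["raw"].to_numpy(dtype=float)[ok]
                teeth = f["tooth_id"].to_numpy()[ok]
                pred = _positivity(method, level, f["ordinal"].to_numpy(dtype=float)[ok])
                roc = auc_delong(raw, labels)
                table = ContingencyTable.from_predictions(pred, labels, teeth)
                se, sp, acc = se_sp_acc(table)
                cells[method] = dict(
                    az=roc.az,
                    az_se=roc.az_se,
                    se=se,
                    se_se=cluster_se(pred[labels], teeth[labels]),
                    sp=sp,
                    sp_se=cluster_se(~pred[~labels], teeth[~labels]),
                    acc=acc,
                    n_used=int(ok.sum()),
                    n_missing=int((~ok).sum()),
                )

            letters = _row_letters(level_methods, frames, level, alpha)
            for method in level_methods:
                c = cells[method]
                common = dict(condition=condition, level=level.name, method=method)
                rows += [
                    dict(**common, metric="Az", estimate=c["az"], se=c["az_se"],
                         letter=letters["Az"][method], n_used=c["n_used"],
                         n_missing=c["n_missing"]),
                    dict(**common, metric="SE", estimate=c["se"], se=c["se_se"],
                         letter=letters["SE"][method], n_used=c["n_used"],
                         n_missing=c["n_missing"]),
                    dict(**common, metric="SP", estimate=c["sp"], se=c["sp_se"],
                         letter=letters["SP"][method], n_used=c["n_used"],
                         n_missing=c["n_missing"]),
                    dict(**common, metric="ACC", estimate=c["acc"], se=np.nan,
                         letter="", n_used=c["n_used"], n_missing=c["n_missing"]),
                ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _row_letters(
    methods: list[str],
    frames: dict[str, pd.DataFrame],
    level: DiagnosticLevel,
    alpha: float,
) -> dict[str, dict[str, str]]:
    """Letter groups per metric across methods at one condition x level."""
    k = len(methods)
    merged = None
    for method in methods:
        f = frames[method][["site_id", "tooth_id", "histology_code", "raw", "ordinal"]]
        f = f.rename(columns={"raw": f"raw_{method}", "ordinal": f"ord_{method}"})
        merged = f if merged is None else merged.merge(
            f, on=["site_id", "tooth_id", "histology_code"], how="outer"
        )
    labels_all = merged["histology_code"].to_numpy() >= int(level)

    estimates = {metric: np.zeros(k) for metric in ("Az", "SE", "SP")}
    pmats = {metric: np.ones((k, k)) for metric in ("Az", "SE", "SP")}
    for i, method in enumerate(methods):
        raw = merged[f"raw_{method}"].to_numpy(dtype=float)
        ordinal = merged[f"ord_{method}"].to_numpy(dtype=float)
        ok = ~np.isnan(raw)
        pred = _positivity(method, level, ordinal[ok])
        lab = labels_all[ok]
        estimates["Az"][i] = auc_delong(raw[ok], lab).az
        estimates["SE"][i] = float(pred[lab].mean())
        estimates["SP"][i] = float((~pred[~lab]).mean())
    for i in range(k):
        raw_i = merged[f"raw_{methods[i]}"].to_numpy(dtype=float)
        ord_i = merged[f"ord_{methods[i]}"].to_numpy(dtype=float)
        for j in range(i + 1, k):
            raw_j = merged[f"raw_{methods[j]}"].to_numpy(dtype=float)
            ord_j = merged[f"ord_{methods[j]}"].to_numpy(dtype=float)
            ok = ~(np.isnan(raw_i) | np.isnan(raw_j))
            lab = labels_all[ok]
            _, p_az = delong_paired_test(raw_i[ok], raw_j[ok], lab)
            pred_i = _positivity(methods[i], level, ord_i[ok])
            pred_j = _positivity(methods[j], level, ord_j[ok])
            p_se = mcnemar(pred_i[lab], pred_j[lab])
            p_sp = mcnemar(~pred_i[~lab], ~pred_j[~lab])
            for metric, p in (("Az", p_az), ("SE", p_se), ("SP", p_sp)):
                pmats[metric][i, j] = pmats[metric][j, i] = p
    out: dict[str, dict[str, str]] = {}
    for metric in ("Az", "SE", "SP"):
        lg = letter_groups(estimates[metric], pmats[metric], alpha)
        out[metric] = dict(zip(methods, lg))
    return out


# -- condition agreement --------------------------------------------------


def condition_agreement(scores: pd.DataFrame, algorithms=ALGORITHMS) -> pd.DataFrame:
    """In vivo vs. in vitro comparison per algorithm: McNemar-Bowker symmetry
    of the paired ordinal scores, paired DeLong Az comparison per level, and
    McNemar on the binary >=E1 calls among truly carious sites (where a
    biofilm red-fluorescence excess can inflate the in vivo sensitivity)."""
    rows = []
    for algorithm in algorithms:
        sel = scores[scores["algorithm"] == algorithm]
        wide = sel.pivot_table(
            index=["site_id", "tooth_id", "histology_code"],
            columns="condition",
            values=["raw_score", "ordinal_score"],
            aggfunc="first",
        ).reset_index()
        ord_vivo = wide[("ordinal_score", "in_vivo")].to_numpy(dtype=float)
        ord_vitro = wide[("ordinal_score", "in_vitro")].to_numpy(dtype=float)
        ok = ~(np.isnan(ord_vivo) | np.isnan(ord_vitro))
        stat, df, p = mcnemar_bowker(
            ord_vivo[ok].astype(int), ord_vitro[ok].astype(int), _ALG_SCALE[algorithm]
        )
        rows.append(
            dict(algorithm=algorithm, comparison="bowker_ordinal", level="",
                 statistic=stat, df=df, p=p, n=int(ok.sum()))
        )
        raw_vivo = wide[("raw_score", "in_vivo")].to_numpy(dtype=float)
        raw_vitro = wide[("raw_score", "in_vitro")].to_numpy(dtype=float)
        codes = wide["histology_code"].to_numpy(dtype=int)
        from .histology import algorithm_levels

        for level in algorithm_levels(algorithm):
            labels = codes >= int(level)
            z, p_az = delong_paired_test(raw_vivo, raw_vitro, labels)
            rows.append(
                dict(algorithm=algorithm, comparison="delong_az", level=level.name,
                     statistic=z, df=np.nan, p=p_az, n=int(ok.sum()))
            )
        e1 = DiagnosticLevel.E1
        thr = level_positivity_threshold(e1, algorithm)
        pos = codes >= int(e1)
        both = ok & pos
        p_se = mcnemar(ord_vivo[both] >= thr, ord_vitro[both] >= thr)
        rows.append(
            dict(algorithm=algorithm, comparison="mcnemar_se_E1", level="E1",
                 statistic=np.nan, df=np.nan, p=p_se, n=int(both.sum()))
        )
    return pd.DataFrame(rows)


# -- report ---------------------------------------------------------------


def _fmt(est: float, se: float | None = None, letter: str = "") -> str:
    s = f"{est:.2f}"
    if se is not None and not (isinstance(se, float) and np.isnan(se)):
        s += f" ({se:.2f})"
    if letter:
        s += f"^{letter}"
    return s


def format_report(summary: pd.DataFrame) -> str:
    """Plain-text report mirroring the validation table layout: one section
    per condition, an r_s row, then Az/SE/SP/ACC blocks per diagnostic level."""
    lines: list[str] = []
    width = 18
    for tag, condition in (("(a) In vivo", "in_vivo"), ("(b) In vitro", "in_vitro")):
        part = summary[summary["condition"] == condition]
        if part.empty:
            continue
        methods = list(dict.fromkeys(part["method"]))
        lines.append(tag)
        lines.append("".join(["        "] + [m.ljust(width) for m in methods]))
        cells = []
        for m in methods:
            row = part[(part["metric"] == "rs") & (part["method"] == m)]
            cells.append(_fmt(row.iloc[0]["estimate"], row.iloc[0]["se"]) if len(row) else "N/A")
        lines.append("".join(["r_s     "] + [c.ljust(width) for c in cells]))
        for level in ("E1", "D1", "D2"):
            block = part[part["level"] == level]
            if block.empty:
                continue
            for metric in ("Az", "SE", "SP", "ACC"):
                cells = []
                for m in methods:
                    row = block[(block["metric"] == metric) & (block["method"] == m)]
                    if len(row):
                        r = row.iloc[0]
                        cells.append(_fmt(r["estimate"], r["se"], r["letter"]))
                    else:
                        cells.append("N/A")
                label = f">={level} {metric}" if metric == "Az" else f"     {metric}"
                lines.append("".join([label.ljust(8)] + [c.ljust(width) for c in cells]))
        lines.append("")
    return "\n".join(lines)


# -- orchestration --------------------------------------------------------


@dataclass
class PipelineResult:
    config: RunConfig
    calibration_cohort: list[ToothRecord]
    validation_cohort: list[ToothRecord]
    alg4_model: Alg4Model
    cutoff_sets: dict[str, CutoffSet]
    calibration_scores: pd.DataFrame
    validation_scores: pd.DataFrame
    summary: pd.DataFrame
    agreement: pd.DataFrame
    report: str


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage and (optionally) write all artifacts under ``out_dir``."""
    cal_cfg, val_cfg = config.resolved_cohort_configs()

    log.info("stage=generate calibration seed=%d validation seed=%d", cal_cfg.seed, val_cfg.seed)
    calibration = generate_cohort(cal_cfg)
    validation = calibration if config.calibrate_in_sample else generate_cohort(val_cfg)
    log.info(
        "stage=generate calibration sites=%d validation sites=%d",
        len(cohort_sites(calibration)), len(cohort_sites(validation)),
    )

    alg4_model = fit_alg4(calibration) if "ALG4" in config.algorithms else None
    cal_scores = score_cohort(calibration, config.algorithms, alg4_model)
    cutoff_sets = {
        alg: calibrate_from_scores(cal_scores, alg) for alg in config.algorithms
    }
    for alg, cs in cutoff_sets.items():
        log.info(
            "stage=calibrate %s thresholds=%s reliable=%s",
            alg,
            [round(e.threshold, 4) for e in cs.entries],
            [e.reliable for e in cs.entries],
        )

    val_scores = score_cohort(validation, config.algorithms, alg4_model, cutoff_sets)
    n_insufficient = int(val_scores["raw_score"].isna().sum())
    log.info("stage=score validation rows=%d insufficient=%d", len(val_scores), n_insufficient)

    summary = diagnostic_summary(
        validation,
        val_scores,
        algorithms=config.algorithms,
        include_visual=config.include_visual,
        alpha=config.alpha,
        bootstrap_reps=config.bootstrap_reps,
        seed=config.seed,
    )
    agreement = condition_agreement(val_scores, config.algorithms)
    report = format_report(summary)

    result = PipelineResult(
        config=config,
        calibration_cohort=calibration,
        validation_cohort=validation,
        alg4_model=alg4_model,
        cutoff_sets=cutoff_sets,
        calibration_scores=cal_scores,
        validation_scores=val_scores,
        summary=summary,
        agreement=agreement,
        report=report,
    )
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(result.calibration_cohort, out / "calibration_cohort.csv")
    write_cohort(result.validation_cohort, out / "validation_cohort.csv")
    write_scores(result.calibration_scores, out / "scores_calibration.csv")
    write_scores(result.validation_scores, out / "scores_validation.csv")
    save_cutoff_sets(result.cutoff_sets, out / "cutoffs.json")
    if result.alg4_model is not None:
        result.alg4_model.to_json(out / "alg4_model.json")
    result.summary.to_csv(out / "summary.csv", index=False, na_rep="NA")
    result.agreement.to_csv(out / "condition_agreement.csv", index=False, na_rep="NA")
    (out / "report.txt").write_text(result.report)
    config_dict = result.config.to_dict()
    manifest = {
        "seed": result.config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "config": config_dict,
        "versions": _versions(),
        "n_sites_validation": len(cohort_sites(result.validation_cohort)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("stage=report wrote artifacts to %s", out)


def _versions() -> dict[str, str]:
    import sklearn
    import scipy

    from . import __version__

    return {
        "cariescan": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }
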