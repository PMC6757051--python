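"""End-to-end per-site analysis orchestration.

A site run executes, in fixed order: preprocessing of both timepoint
matrices, 20w/15w ratio construction, the clinical univariate table and
stepwise clinical model, the per-comparison metabolite screen, metabolite
augmentation of the clinical model with ROC comparison, the three
permutation tests, sparse PLS-DA selection/significance, and (for the
37-week run) the outcome-threshold sensitivity table.  Sites never mix.

Everything is reproducible from one master seed: each stage draws its own
seed from a spawned stream, so no two stages share randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import models, preprocess, splsda, validate
from .screen import clinical_univariate, screen as run_screen
from .containers import (
    IntensityMatrix,
    ROLE_SAMPLE,
    check_subjects_covered,
    read_clinical_csv,
)
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger("ptbmetab")


@dataclass
class RunConfig:
    """One site's analysis configuration.

    Exactly one of ``sim`` (synthetic cohort) or the three input paths
    must be provided.
    """

    site: str = "site"
    sim: SimConfig | None = None
    clinical_csv: str | None = None
    matrix15_csv: str | None = None
    matrix20_csv: str | None = None
    thresholds: tuple[float, ...] = (37.0, 34.0)
    alpha: float = 0.05
    B: int = 1000                  # linear-predictor and forest permutations
    splsda_B: int = 100            # BER permutations (selection rerun each time)
    cv_folds: int = 10
    cv_repeats: int = 10
    max_ncomp: int = 3
    keep_x: int = 5
    contaminant_ratio: float = 0.5
    min_presence: float = 0.7
    n_estimators: int = 500
    sensitivity_thresholds: tuple[float, ...] = (36.0, 35.0, 34.0)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        paths = [self.clinical_csv, self.matrix15_csv, self.matrix20_csv]
        have_paths = all(p is not None for p in paths)
        if (self.sim is None) == (not have_paths):
            raise ValueError("provide exactly one of sim config or all three input paths")
        if have_paths:
            missing = [p for p in paths if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("sim") is not None:
            raw["sim"] = SimConfig.from_dict(raw["sim"])
        for key in ("thresholds", "sensitivity_thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    site: str
    seed: int
    config_hash: str
    preprocessing: dict
    per_threshold: dict[str, dict]
    artifacts: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        raw = dataclasses.asdict(self)
        raw.pop("artifacts", None)  # local paths: not part of the report body
        return json.dumps(_jsonable(raw), indent=2, sort_keys=True)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        clinical, m15, m20 = generate_cohort(config.sim)
    else:
        clinical = read_clinical_csv(config.clinical_csv)
        m15 = IntensityMatrix.from_csv(config.matrix15_csv)
        m20 = IntensityMatrix.from_csv(config.matrix20_csv)
    check_subjects_covered(m15, clinical)
    check_subjects_covered(m20, clinical)
    return clinical, m15, m20


def _subject_frame(matrix: IntensityMatrix, index, suffix: str) -> pd.DataFrame:
    study = matrix.role_mask(ROLE_SAMPLE)
    vals = matrix.values.loc[study].copy()
    vals.index = matrix.sample_meta.loc[study, "subject_id"].to_numpy()
    vals = vals.reindex(index)
    vals.columns = [f"{c}@{suffix}" for c in vals.columns]
    return vals


def splsda_block(frame: pd.DataFrame, log15, log20, logratio) -> pd.DataFrame:
    """Concatenated candidate-predictor block: clinical variables plus
    log intensities at both timepoints and the log 20w/15w ratios.
    Missing cells are mean-imputed (the fit needs column-complete X)."""
    idx = frame.index
    clin, _ = models.build_design(frame, models.DEFAULT_CANDIDATES)
    blocks = [clin]
    for matrix, suffix in ((log15, "15w"), (log20, "20w"), (logratio, "ratio")):
        if matrix is not None:
            blocks.append(_subject_frame(matrix, idx, suffix))
    X = pd.concat(blocks, axis=1)
    X = X.loc[:, X.notna().any(axis=0)]
    return X.fillna(X.mean(axis=0))


def run_site(config: RunConfig) -> AnalysisReport:
    """Execute the full per-site analysis and (optionally) persist it."""
    config.validate()
    clinical, m15_raw, m20_raw = _load_inputs(config)
    master = np.random.SeedSequence(config.seed)
    stage_seed = [int(s % (2**31)) for s in master.generate_state(16)]

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        clinical.to_csv(outdir / "clinical.csv", index=False)
        m15_raw.to_csv(outdir / "intensity_15w_raw.csv")
        m20_raw.to_csv(outdir / "intensity_20w_raw.csv")

    stage = "preprocess"
    try:
        norm15 = preprocess.standard_pipeline(
            m15_raw, config.contaminant_ratio, config.min_presence)
        norm20 = preprocess.standard_pipeline(
            m20_raw, config.contaminant_ratio, config.min_presence)
        ratio = preprocess.timepoint_ratio(norm15, norm20)
        log15 = preprocess.log_transform(norm15)
        log20 = preprocess.log_transform(norm20)
        logratio = preprocess.log_transform(ratio)
        preproc_info = {
            "provenance_15w": norm15.provenance,
            "provenance_20w": norm20.provenance,
            "qc_cv_15w": preprocess.qc_cv_report(m15_raw)["median_cv"].median(),
            "qc_cv_20w": preprocess.qc_cv_report(m20_raw)["median_cv"].median(),
            "n_compounds_retained": len(norm20.compound_names),
        }
        if outdir:
            norm15.to_csv(outdir / "intensity_15w_normalized.csv")
            norm20.to_csv(outdir / "intensity_20w_normalized.csv")
            ratio.to_csv(outdir / "intensity_ratio.csv")

        comparisons = {"15w": (norm15, log15), "20w": (norm20, log20),
                       "ratio": (ratio, logratio)}
        per_threshold: dict[str, dict] = {}
        for ti, t in enumerate(config.thresholds):
            stage = f"threshold {t}"
            section: dict[str, Any] = {}
            section["clinical_univariate"] = clinical_univariate(clinical, t)

            frame = models.clinical_model_frame(clinical, t)
            clin_fit = models.stepwise_select(frame["case"], frame)
            section["clinical_model"] = {
                "terms": clin_fit.terms,
                "odds_ratios": clin_fit.odds_ratios().reset_index(names="predictor"),
                "aic": clin_fit.aic,
                "trace_steps": len(clin_fit.trace),
                "flags": clin_fit.flags,
            }
            if outdir:
                (outdir / f"clinical_model_trace_lt{int(t)}.json").write_text(
                    json.dumps(_jsonable(clin_fit.trace), indent=2))

            screens = {}
            for name, (raw_m, _log_m) in comparisons.items():
                res = run_screen(raw_m, clinical, name, t, config.alpha)
                screens[name] = res
                section.setdefault("screens", {})[name] = res.table
                if outdir:
                    res.table.to_csv(
                        outdir / f"screen_{name}_lt{int(t)}.csv", index=False)

            hits = pd.concat(
                [screens[c].significant.assign(comparison=c) for c in screens]
            )
            section["n_discoveries"] = int(len(hits))

            if len(hits):
                stage = f"augmentation at {t}"
                best = hits.sort_values(["q", "p"]).iloc[0]
                comp, comparison = str(best["compound"]), str(best["comparison"])
                log_m = comparisons[comparison][1]
                augmented = models.add_metabolite(clin_fit, comp, log_m)
                idx = augmented.X.index
                base_cmp = models.fit_logistic(
                    clin_fit.y.loc[idx], clin_fit.X.loc[idx],
                    clin_fit.terms, clin_fit.term_map)
                roc_a, roc_b, dauc = validate.compare_aucs(base_cmp, augmented)
                name = f"log({comp})"
                ors = augmented.odds_ratios()
                lp = validate.lp_difference_test(
                    augmented.y.to_numpy(), augmented.X,
                    B=config.B, seed=stage_seed[4 + ti])
                rf_features = augmented.X
                rf = validate.rf_oob_test(
                    rf_features, augmented.y.to_numpy(), B=config.B,
                    seed=stage_seed[6 + ti], n_estimators=config.n_estimators)
                section["augmented_model"] = {
                    "compound": comp,
                    "comparison": comparison,
                    "per_sd_or": float(ors.loc[name, "or"]),
                    "per_sd_or_ci": [float(ors.loc[name, "or_lo"]),
                                     float(ors.loc[name, "or_hi"])],
                    "p": float(ors.loc[name, "p"]),
                    "auc_clinical": roc_a.auc,
                    "auc_augmented": roc_b.auc,
                    "delta_auc": dauc,
                    "flags": augmented.flags,
                }
                section["roc"] = {
                    "clinical": {"fpr": roc_a.fpr, "tpr": roc_a.tpr, "auc": roc_a.auc},
                    "augmented": {"fpr": roc_b.fpr, "tpr": roc_b.tpr, "auc": roc_b.auc},
                }
                section["lp_permutation"] = _perm_dict(lp)
                section["rf_permutation"] = _perm_dict(rf)
                if t >= 37.0:
                    stage = "threshold sensitivity"
                    section["threshold_sensitivity"] = models.threshold_sensitivity(
                        clinical, log_m, comp, clin_fit.terms,
                        list(config.sensitivity_thresholds))

            stage = f"sPLS-DA at {t}"
            X = splsda_block(frame, log15, log20, logratio)
            y = frame["case"].to_numpy().astype(int)
            perm = splsda.permutation_significance(
                X.to_numpy(), y, B=config.splsda_B, seed=stage_seed[8 + ti],
                max_ncomp=config.max_ncomp, keep_x=config.keep_x,
                folds=config.cv_folds, repeats=config.cv_repeats)
            refit = splsda.fit(X.to_numpy(), y,
                               ncomp=perm.extra["selected_ncomp"],
                               keep_x=config.keep_x)
            selected = [
                [str(X.columns[j]) for j in np.flatnonzero(refit.weights[:, h])]
                for h in range(refit.ncomp)
            ]
            section["splsda"] = {
                "selected_ncomp": perm.extra["selected_ncomp"],
                "ber_by_ncomp": perm.extra["cv"],
                "ber": perm.observed,
                "permutation_p": perm.p,
                "component_predictors": selected,
                "flags": refit.flags,
            }
            per_threshold[f"<{t:g}w"] = section
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {stage}") from err

    cfg_hash = config.sim.config_hash() if config.sim else "external-data"
    report = AnalysisReport(
        site=config.site,
        seed=config.seed,
        config_hash=cfg_hash,
        preprocessing=preproc_info,
        per_threshold=per_threshold,
    )
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
        report.artifacts["report"] = str(outdir / "report.json")
        make_figures(report, outdir, log20, clinical)
    return report


def _perm_dict(res: validate.PermutationResult) -> dict:
    return {
        "statistic": res.statistic,
        "observed": res.observed,
        "p": res.p,
        "B": res.B,
        "n_beaten": res.n_beaten,
        "direction": res.direction,
        "extra": {k: v for k, v in res.extra.items() if k != "forest_params"},
    }


def make_figures(report: AnalysisReport, outdir: str | Path,
                 log20: IntensityMatrix | None = None,
                 clinical: pd.DataFrame | None = None) -> list[Path]:
    """ROC-pair figure and, for each flagged compound, a per-group log2
    intensity strip plot.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for label, section in report.per_threshold.items():
        if "roc" not in section:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        for key, style in (("clinical", "--"), ("augmented", "-")):
            roc = section["roc"][key]
            ax.plot(np.asarray(roc["fpr"]), np.asarray(roc["tpr"]), style,
                    label=f"{key} (AUC {roc['auc']:.2f})")
        ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"{report.site}: sPTB {label}")
        ax.legend(loc="lower right")
        path = outdir / f"roc_{label.strip('<>')}.svg"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    if log20 is not None:
        for label, section in report.per_threshold.items():
            aug = section.get("augmented_model")
            if not aug:
                continue
            comp = aug["compound"]
            if comp not in log20.values.columns:
                continue
            vals = (models.subject_log_intensity(log20, comp) / np.log(2)).dropna()
            fig, ax = plt.subplots(figsize=(4, 5))
            ax.set_ylabel(f"log2 intensity ({comp})")
            ax.set_title(f"{report.site}: {comp}, sPTB {label}")
            if clinical is not None:
                t = float(label.strip("<>w"))
                ga = clinical.set_index("subject_id")["ga_delivery"].reindex(vals.index)
                groups = [vals[ga.to_numpy() >= 37.0], vals[ga.to_numpy() < t]]
                rng = np.random.default_rng(0)
                for k, (g, name) in enumerate(zip(groups, ["term", "preterm"])):
                    ax.plot(k + 1 + rng.uniform(-0.08, 0.08, len(g)), g, "o",
                            ms=3, alpha=0.5)
                ax.set_xticks([1, 2], ["term", "preterm"])
            else:
                ax.violinplot([vals.to_numpy()], showmedians=True)
            path = outdir / f"intensity_{comp}_{label.strip('<>')}.svg"
            fig.savefig(path)
            plt.close(fig)
            written.append(path)
    return written
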