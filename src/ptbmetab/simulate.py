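"""Synthetic case-control serum-metabolome cohort generator.

Emulates the structure of a two-timepoint GC-MS case-control study of
spontaneous preterm birth: cases matched to controls on maternal age and
BMI, binary clinical covariates with configurable control prevalence and
case-control odds ratio, and two injection-batched intensity matrices
(15- and 20-week serum) with

* log-normal compound baselines and residual biological noise,
* a multiplicative per-batch, per-compound technical factor,
* a multiplicative per-injection recovery factor shared by every compound
  in that injection (what the internal-standard spike corrects),
* optional planted case effects on log intensity — expressed in
  control-SD units so a planted effect of ``ln(r)`` induces a per-SD
  odds ratio of ``r`` — with configurable inter-compound correlation,
* background contaminant compounds that show up in negative controls at
  intensities comparable to study samples.

Everything is driven by one integer seed; identical configuration gives
bit-identical output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .containers import (
    BINARY_COVARIATES,
    CLINICAL_COLUMNS,
    GRAVIDITY_LEVELS,
    IS_CHANNEL,
    META_COLUMNS,
    ROLE_NEG,
    ROLE_QC,
    ROLE_SAMPLE,
    SMOKING_LEVELS,
    IntensityMatrix,
    case_labels,
)


@dataclass(frozen=True)
class ClinicalEffect:
    """A binary covariate with a planted case-control association."""

    name: str
    control_prevalence: float
    odds_ratio: float

    def case_prevalence(self) -> float:
        odds = self.control_prevalence / (1.0 - self.control_prevalence)
        odds *= self.odds_ratio
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class PlantedEffect:
    """A set of compounds elevated (or depressed) in cases at one timepoint.

    ``effect_size`` is on the log-intensity scale in units of the control
    standard deviation; ``correlation`` is the pairwise correlation of the
    compounds' residual log-intensity noise (applied at both timepoints,
    the mean shift only at ``timepoint``).
    """

    compound_indices: tuple[int, ...]
    timepoint: str
    effect_size: float
    correlation: float = 0.0


@dataclass
class SimConfig:
    """Study-design and noise parameters for one synthetic site."""

    n_cases: int = 55
    controls_per_case: int = 2
    site: str = "SiteA"
    age_range: tuple[float, float] = (18.0, 42.0)
    bmi_range: tuple[float, float] = (17.0, 35.0)
    match_age_tol: float = 3.0
    match_bmi_tol: float = 5.0
    n_compounds: int = 176
    batch_size_samples: int = 18
    qc_per_batch: int = 4
    clinical_effects: list[ClinicalEffect] = field(default_factory=list)
    planted_compounds: list[PlantedEffect] = field(default_factory=list)
    contaminant_compounds: tuple[int, ...] = ()
    batch_sd: float = 0.3
    noise_sd: float = 0.4
    recovery_sd: float = 0.15
    qc_noise_sd: float = 0.05
    smoking_control_probs: tuple[float, float, float] = (0.80, 0.12, 0.08)
    smoking_current_or: float = 1.0
    gravidity_probs: tuple[float, float, float] = (0.80, 0.14, 0.06)
    male_prob: float = 0.55
    pprom_prob: float = 0.5
    compound_name_overrides: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "controls_per_case", "n_compounds",
                     "batch_size_samples", "qc_per_batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.match_age_tol <= 0 or self.match_bmi_tol <= 0:
            raise ValueError("matching tolerances must be > 0")
        for name in ("age_range", "bmi_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"infeasible matching: {name}=({lo}, {hi}) is empty")
        for eff in self.clinical_effects:
            if not 0.0 < eff.control_prevalence < 1.0:
                raise ValueError(f"prevalence of {eff.name} must be in (0,1)")
            if eff.odds_ratio <= 0:
                raise ValueError(f"odds ratio of {eff.name} must be > 0")
            if eff.name not in BINARY_COVARIATES:
                raise ValueError(f"unknown binary covariate {eff.name!r}")
        planted: set[int] = set()
        for pe in self.planted_compounds:
            if pe.timepoint not in ("15w", "20w"):
                raise ValueError(f"planted timepoint must be 15w/20w, got {pe.timepoint!r}")
            if not -1.0 < pe.correlation < 1.0:
                raise ValueError("planted correlation must be in (-1, 1)")
            planted.update(pe.compound_indices)
        contaminants = set(self.contaminant_compounds)
        for idx in planted | contaminants:
            if not 0 <= idx < self.n_compounds:
                raise ValueError(f"compound index {idx} outside [0, {self.n_compounds})")
        if planted & contaminants:
            raise ValueError("planted and contaminant compound sets must be disjoint")

    # --------------------------------------------------------------- config IO
    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["clinical_effects"] = [asdict(e) for e in self.clinical_effects]
        raw["planted_compounds"] = [asdict(p) for p in self.planted_compounds]
        Path(path).write_text(yaml.safe_dump(_to_builtin(raw), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        raw["clinical_effects"] = [ClinicalEffect(**e) for e in raw.get("clinical_effects", [])]
        raw["planted_compounds"] = [
            PlantedEffect(**{**p, "compound_indices": tuple(p["compound_indices"])})
            for p in raw.get("planted_compounds", [])
        ]
        for key in ("age_range", "bmi_range", "contaminant_compounds",
                    "smoking_control_probs", "gravidity_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "compound_name_overrides" in raw:
            raw["compound_name_overrides"] = {
                int(k): v for k, v in raw["compound_name_overrides"].items()
            }
        return cls(**raw)

    def config_hash(self) -> str:
        raw = asdict(self)
        return hashlib.sha256(repr(sorted(raw.items(), key=lambda kv: kv[0])).encode()).hexdigest()[:12]


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def cork_like_config(seed: int = 0, **overrides) -> SimConfig:
    """Default study conditions: 55 cases, 1:2 matching, 176 compounds,
    vaginal bleeding planted at control prevalence 21% with OR 2.7, and a
    correlated alkane-like trio elevated in cases at 20 weeks with a
    per-SD odds ratio of 1.9."""
    cfg = SimConfig(
        n_cases=55,
        controls_per_case=2,
        site="Cork-like",
        clinical_effects=[ClinicalEffect("vaginal_bleeding_15w", 0.21, 2.7)],
        planted_compounds=[PlantedEffect((10, 11, 12), "20w", float(np.log(1.9)), 0.9)],
        contaminant_compounds=(171, 172, 173, 174, 175),
        compound_name_overrides={10: "decane", 11: "undecane", 12: "dodecane"},
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Same structure as the default site but with no planted effects."""
    return cork_like_config(
        seed=seed,
        clinical_effects=[],
        planted_compounds=[],
        compound_name_overrides={},
        **overrides,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_clinical(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_cases = config.n_cases
    n_controls = config.n_cases * config.controls_per_case
    n = n_cases + n_controls
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True

    # outcome: cases skewed toward late preterm, controls centred near 40.3 w
    ga_case = 37.0 - np.clip(rng.gamma(1.5, 1.5, size=n_cases), 0.1, 12.0)
    ga_ctrl = _truncated_normal(rng, 40.3, 1.3, 37.05, 42.8, n_controls)

    age_lo, age_hi = config.age_range
    bmi_lo, bmi_hi = config.bmi_range
    age_case = _truncated_normal(rng, 30.0, 4.0, age_lo, age_hi, n_cases)
    bmi_case = _truncated_normal(rng, 24.0, 3.0, bmi_lo, bmi_hi, n_cases)

    # matched controls: jitter within tolerance, clipped to the admissible
    # range (clipping moves toward the case, so the tolerance still holds)
    age_ctrl = np.repeat(age_case, config.controls_per_case)
    age_ctrl = np.clip(
        age_ctrl + rng.uniform(-config.match_age_tol, config.match_age_tol, n_controls),
        age_lo, age_hi,
    )
    bmi_ctrl = np.repeat(bmi_case, config.controls_per_case)
    bmi_ctrl = np.clip(
        bmi_ctrl + rng.uniform(-config.match_bmi_tol, config.match_bmi_tol, n_controls),
        bmi_lo, bmi_hi,
    )

    clinical = pd.DataFrame(
        {
            "subject_id": [f"{config.site}-{i:04d}" for i in range(n)],
            "site": config.site,
            "ga_delivery": np.concatenate([ga_case, ga_ctrl]),
            "age": np.concatenate([age_case, age_ctrl]),
            "bmi": np.concatenate([bmi_case, bmi_ctrl]),
            "matched_case": [f"{config.site}-{i:04d}" for i in range(n_cases)]
            + [f"{config.site}-{i // config.controls_per_case:04d}" for i in range(n_controls)],
        }
    )
    clinical["height"] = _truncated_normal(rng, 165.0, 5.5, 145, 190, n)

    effects = {e.name: e for e in config.clinical_effects}
    for name in BINARY_COVARIATES:
        if name == "infant_sex":
            p0 = p1 = config.male_prob
        else:
            defaults = {"vaginal_bleeding_15w": 0.21, "infection_15w": 0.30,
                        "prev_miscarriage": 0.14, "fertility_treatment": 0.08}
            p0 = defaults[name]
            p1 = p0
        if name in effects:
            p0 = effects[name].control_prevalence
            p1 = effects[name].case_prevalence()
        p = np.where(is_case, p1, p0)
        clinical[name] = (rng.random(n) < p).astype(int)

    smk0 = np.asarray(config.smoking_control_probs, dtype=float)
    smk0 = smk0 / smk0.sum()
    smk1 = smk0 * np.array([1.0, 1.0, config.smoking_current_or])
    smk1 = smk1 / smk1.sum()
    smoking = np.empty(n, dtype=object)
    draws = rng.random(n)
    for i in range(n):
        probs = smk1 if is_case[i] else smk0
        smoking[i] = SMOKING_LEVELS[int(np.searchsorted(np.cumsum(probs), draws[i]))]
    clinical["smoking"] = smoking

    grav = np.asarray(config.gravidity_probs, dtype=float)
    grav = grav / grav.sum()
    gidx = np.searchsorted(np.cumsum(grav), rng.random(n))
    clinical["gravidity"] = [GRAVIDITY_LEVELS[min(i, 2)] for i in gidx]
    clinical["pprom"] = np.where(is_case, (rng.random(n) < config.pprom_prob), 0).astype(int)
    return clinical[CLINICAL_COLUMNS + ["matched_case"]]


def _compound_names(config: SimConfig) -> list[str]:
    names = [f"cmpd_{j:03d}" for j in range(config.n_compounds)]
    for idx, name in config.compound_name_overrides.items():
        names[idx] = name
    return names


def _noise_cholesky(config: SimConfig) -> np.ndarray | None:
    """Cholesky factor of the compound-noise correlation, or None if I."""
    if not any(pe.correlation for pe in config.planted_compounds):
        return None
    corr = np.eye(config.n_compounds)
    for pe in config.planted_compounds:
        idx = np.asarray(pe.compound_indices)
        block = np.full((len(idx), len(idx)), pe.correlation)
        np.fill_diagonal(block, 1.0)
        corr[np.ix_(idx, idx)] = block
    return np.linalg.cholesky(corr)


def _build_matrix(
    config: SimConfig,
    rng: np.random.Generator,
    clinical: pd.DataFrame,
    timepoint: str,
    mu: np.ndarray,
    chol: np.ndarray | None,
) -> IntensityMatrix:
    names = _compound_names(config)
    n_subj = len(clinical)
    p = config.n_compounds
    is_case = case_labels(clinical, 37.0).to_numpy()

    z = rng.standard_normal((n_subj, p))
    if chol is not None:
        z = z @ chol.T
    log_int = mu[None, :] + config.noise_sd * z
    for pe in config.planted_compounds:
        if pe.timepoint == timepoint:
            idx = np.asarray(pe.compound_indices)
            log_int[np.ix_(is_case, idx)] += pe.effect_size * config.noise_sd

    order = rng.permutation(n_subj)
    mu_is = 12.0

    rows, meta_rows, index = [], [], []
    batch_starts = range(0, n_subj, config.batch_size_samples)
    for b, start in enumerate(batch_starts):
        batch_id = f"{timepoint}_b{b:02d}"
        batch_factor = np.exp(rng.normal(0.0, config.batch_sd, size=p))
        members = order[start : start + config.batch_size_samples]
        for s in members:
            recovery = float(np.exp(rng.normal(0.0, config.recovery_sd)))
            vals = np.exp(log_int[s]) * batch_factor * recovery
            rows.append(np.append(vals, np.exp(mu_is) * recovery))
            meta_rows.append((clinical["subject_id"].iat[s], timepoint, batch_id, ROLE_SAMPLE))
            index.append(f"{batch_id}_s{s:04d}")
        for q in range(config.qc_per_batch):
            recovery = float(np.exp(rng.normal(0.0, config.recovery_sd)))
            vals = np.exp(mu + rng.normal(0.0, config.qc_noise_sd, size=p)) * batch_factor * recovery
            rows.append(np.append(vals, np.exp(mu_is) * recovery))
            meta_rows.append(("", timepoint, batch_id, ROLE_QC))
            index.append(f"{batch_id}_qc{q}")
        recovery = float(np.exp(rng.normal(0.0, config.recovery_sd)))
        neg = np.zeros(p)
        for j in config.contaminant_compounds:
            neg[j] = np.exp(mu[j] + rng.normal(0.0, config.noise_sd)) * batch_factor[j] * recovery
        rows.append(np.append(neg, np.exp(mu_is) * recovery))
        meta_rows.append(("", timepoint, batch_id, ROLE_NEG))
        index.append(f"{batch_id}_neg")

    values = pd.DataFrame(np.vstack(rows), index=index, columns=names + [IS_CHANNEL])
    meta = pd.DataFrame(meta_rows, index=index, columns=META_COLUMNS)
    return IntensityMatrix(values, meta, IS_CHANNEL)


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, IntensityMatrix, IntensityMatrix]:
    """Generate (clinical table, 15-week matrix, 20-week matrix).

    The clinical table carries a bookkeeping column ``matched_case`` naming
    the case each control was matched to; it is not a model covariate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clinical = _draw_clinical(config, rng)
    mu = rng.normal(10.0, 1.5, size=config.n_compounds)
    chol = _noise_cholesky(config)
    m15 = _build_matrix(config, rng, clinical, "15w", mu, chol)
    m20 = _build_matrix(config, rng, clinical, "20w", mu, chol)
    return clinical, m15, m20


def realized_effects(clinical: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Empirical 2x2 cross-product odds ratio of each configured clinical
    effect at the 37-week threshold; zero cells give a flagged non-finite
    estimate rather than an error."""
    is_case = case_labels(clinical, 37.0)
    records = []
    for eff in config.clinical_effects:
        x = clinical[eff.name].astype(int)
        a = int(((x == 1) & is_case).sum())     # exposed cases
        b = int(((x == 0) & is_case).sum())
        c = int(((x == 1) & ~is_case).sum())    # exposed controls
        d = int(((x == 0) & ~is_case).sum())
        if min(a, b, c, d) == 0:
            or_hat, finite = float("nan"), False
        else:
            or_hat, finite = (a * d) / (b * c), True
        records.append(
            {
                "covariate": eff.name,
                "configured_or": eff.odds_ratio,
                "empirical_or": or_hat,
                "finite": finite,
                "case_prevalence": a / max(a + b, 1),
                "control_prevalence": c / max(c + d, 1),
            }
        )
    return pd.DataFrame.from_records(records)


def matching_violations(clinical: pd.DataFrame, config: SimConfig) -> int:
    """Number of matched pairs outside the age/BMI tolerances (0 expected)."""
    cases = clinical.set_index("subject_id")
    bad = 0
    for _, row in clinical.iterrows():
        if row["subject_id"] == row["matched_case"]:
            continue
        case = cases.loc[row["matched_case"]]
        if abs(row["age"] - case["age"]) > config.match_age_tol + 1e-9:
            bad += 1
        elif abs(row["bmi"] - case["bmi"]) > config.match_bmi_tol + 1e-9:
            bad += 1
    return bad
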