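"""Core data containers for the case-control metabolome pipeline.

Two tabular objects travel through every stage:

* a *clinical table* — one row per participant, with the continuous
  pregnancy outcome (gestational age at delivery, weeks) and the maternal
  covariates recorded at the 15-week visit.  Case status is always derived
  from the outcome at an explicit threshold, never stored.
* an :class:`IntensityMatrix` — injections x compounds of non-negative
  GC-MS peak areas, with per-injection metadata (subject, timepoint,
  analytical batch, injection role) and an internal-standard channel.

Both round-trip through plain comma-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

# injection roles
ROLE_SAMPLE = "sample"
ROLE_QC = "QC"
ROLE_NEG = "negative_control"
ROLE_ALKANE = "alkane_series"
ROLE_STD = "standard_mix"
ROLES = (ROLE_SAMPLE, ROLE_QC, ROLE_NEG, ROLE_ALKANE, ROLE_STD)

TIMEPOINTS = ("15w", "20w")

#: default internal-standard compound label (deuterated alanine spike)
IS_CHANNEL = "Alanine-d4"

META_COLUMNS = ["subject_id", "timepoint", "batch_id", "injection_role"]

CLINICAL_COLUMNS = [
    "subject_id",
    "site",
    "ga_delivery",
    "age",
    "bmi",
    "height",
    "smoking",
    "vaginal_bleeding_15w",
    "infection_15w",
    "gravidity",
    "prev_miscarriage",
    "fertility_treatment",
    "infant_sex",
    "pprom",
]

SMOKING_LEVELS = ("no smoking", "quit", "current")
GRAVIDITY_LEVELS = ("1", "2", "3+")

#: binary clinical covariates (coded 0/1)
BINARY_COVARIATES = [
    "vaginal_bleeding_15w",
    "infection_15w",
    "prev_miscarriage",
    "fertility_treatment",
    "infant_sex",
]


class ProvenanceError(RuntimeError):
    """A preprocessing step was applied out of order or twice."""


def case_labels(clinical: pd.DataFrame, threshold: float) -> pd.Series:
    """Boolean case indicator at a gestational-age threshold (weeks).

    A participant is a case iff ``ga_delivery < threshold``.  The label is
    always derived on demand so the same cohort supports the <37-week
    primary definition and the <34-week early-delivery subgroup.
    """
    return clinical["ga_delivery"] < float(threshold)


def analysis_subset(clinical: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Rows entering a case-control comparison at ``threshold`` weeks.

    Controls are always term deliveries (ga >= 37); cases are ga < threshold.
    For thresholds below 37 the in-between deliveries are excluded from both
    groups (early cases are compared against the entire term control group).
    """
    ga = clinical["ga_delivery"]
    keep = (ga < float(threshold)) | (ga >= 37.0)
    return clinical.loc[keep]


def validate_clinical(clinical: pd.DataFrame) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if clinical["subject_id"].duplicated().any():
        dup = clinical.loc[clinical["subject_id"].duplicated(), "subject_id"]
        raise ValueError(f"duplicate subject ids: {sorted(set(dup))[:5]}")
    ga = clinical["ga_delivery"]
    if not ((ga > 20) & (ga < 43)).all():
        raise ValueError("ga_delivery outside the plausible (20, 43)-week window")


@dataclass
class IntensityMatrix:
    """Injections x compounds peak-area matrix with injection metadata.

    Parameters
    ----------
    values
        Non-negative peak areas (NaN marks a missing peak), indexed by
        injection id; columns are compound names.
    sample_meta
        Per-injection metadata aligned to ``values`` (same index), with
        columns ``subject_id`` (empty string for non-study injections),
        ``timepoint``, ``batch_id`` and ``injection_role``.
    is_channel
        Compound label of the internal-standard channel, or ``None`` once
        the channel has been consumed by normalization.
    provenance
        Ordered, append-only record of the transforms applied so far.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    is_channel: str | None = IS_CHANNEL
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the same injection index")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        bad_roles = set(self.sample_meta["injection_role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown injection roles: {sorted(bad_roles)}")
        if self.is_channel is not None and self.is_channel not in self.values.columns:
            raise ValueError(f"internal-standard channel {self.is_channel!r} not in compounds")
        logged = any(step.get("step") == "log_transform" for step in self.provenance)
        if not logged:
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise ValueError("peak areas must be non-negative")

    # ------------------------------------------------------------------ views
    @property
    def compound_names(self) -> list[str]:
        return list(self.values.columns)

    def role_mask(self, role: str) -> pd.Series:
        return self.sample_meta["injection_role"] == role

    @property
    def study_values(self) -> pd.DataFrame:
        return self.values.loc[self.role_mask(ROLE_SAMPLE)]

    @property
    def study_meta(self) -> pd.DataFrame:
        return self.sample_meta.loc[self.role_mask(ROLE_SAMPLE)]

    def rows(self, mask: pd.Series) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[mask].copy(),
            self.sample_meta.loc[mask].copy(),
            self.is_channel,
            list(self.provenance),
        )

    def with_step(self, name: str, **params) -> list[dict]:
        """New provenance list with one step appended (originals untouched)."""
        return [*self.provenance, {"step": name, **params}]

    def has_step(self, name: str) -> bool:
        return any(step["step"] == name for step in self.provenance)

    def require_absent(self, name: str) -> None:
        if self.has_step(name):
            raise ProvenanceError(f"step {name!r} already applied (provenance guard)")

    def require_present(self, name: str) -> None:
        if not self.has_step(name):
            raise ProvenanceError(f"step {name!r} must run first")

    # ------------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write metadata columns followed by the intensity block."""
        out = pd.concat([self.sample_meta[META_COLUMNS], self.values], axis=1)
        out.index.name = "injection_id"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, is_channel: str | None = IS_CHANNEL) -> "IntensityMatrix":
        raw = pd.read_csv(path, index_col="injection_id")
        raw.index.name = None
        meta = raw[META_COLUMNS].copy()
        meta["subject_id"] = meta["subject_id"].fillna("").astype(str)
        meta["batch_id"] = meta["batch_id"].astype(str)
        values = raw.drop(columns=META_COLUMNS).astype(float)
        return cls(values, meta, is_channel)


def write_clinical_csv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    clinical = pd.read_csv(path, dtype={"subject_id": str, "smoking": str, "gravidity": str})
    validate_clinical(clinical)
    return clinical


def check_subjects_covered(matrix: IntensityMatrix, clinical: pd.DataFrame) -> None:
    """Every study injection must map to a clinical row; blanks map to none."""
    known = set(clinical["subject_id"].astype(str))
    study = set(matrix.study_meta["subject_id"].astype(str))
    orphans = study - known
    if orphans:
        raise ValueError(f"study injections without clinical rows: {sorted(orphans)[:5]}")
    neg = matrix.sample_meta.loc[matrix.role_mask(ROLE_NEG), "subject_id"]
    if (neg.astype(str) != "").any():
        raise ValueError("negative-control injections must not carry a subject_id")


def intensity_long_names(names: Iterable[str], suffix: str) -> list[str]:
    """Qualified predictor names, e.g. ``undecane@20w`` for model blocks."""
    return [f"{n}@{suffix}" for n in names]
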