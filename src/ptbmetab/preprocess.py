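"""Post-integration treatment of GC-MS peak-area tables.

Fixed stage order, recorded in each matrix's provenance:

    internal-standard normalization -> analytical-batch median centering
    -> negative-control contaminant filter -> (20w/15w ratio | log)

Internal-standard division removes per-injection recovery and injection
volume variation; batch median centering (multiplicative, per compound,
computed over study samples only) removes the remaining per-batch
technical factor; the contaminant filter drops compounds whose blank
intensity is comparable to the study samples.  QC and blank injections
are carried through each transform but never enter median computations.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, ProvenanceError, ROLE_NEG, ROLE_QC, ROLE_SAMPLE

logger = logging.getLogger("ptbmetab")

STEP_IS = "internal_standard_normalization"
STEP_BATCH = "batch_median_centering"
STEP_CONTAM = "contaminant_filter"
STEP_LOG = "log_transform"
STEP_RATIO = "timepoint_ratio"
STEP_PRESENCE = "presence_filter"


def normalize_internal_standard(m: IntensityMatrix) -> IntensityMatrix:
    """Divide every compound in an injection by that injection's
    internal-standard value, then drop the IS channel."""
    m.require_absent(STEP_IS)
    if m.is_channel is None:
        raise ProvenanceError("matrix has no internal-standard channel")
    is_values = m.values[m.is_channel]
    study_or_qc = m.role_mask(ROLE_SAMPLE) | m.role_mask(ROLE_QC)
    bad = study_or_qc & ~(is_values > 0)
    if bad.any():
        raise ValueError(
            "internal standard missing or zero in injections: "
            f"{list(m.values.index[bad])}"
        )
    # blanks with no IS signal cannot be scaled; keep them untouched-by-zero
    scale = is_values.replace(0.0, np.nan)
    values = m.values.drop(columns=[m.is_channel]).div(scale, axis=0)
    return IntensityMatrix(
        values, m.sample_meta.copy(), None,
        m.with_step(STEP_IS, channel=m.is_channel),
    )


def batch_median_center(m: IntensityMatrix) -> IntensityMatrix:
    """Rescale each compound so every batch's study-sample median equals the
    global study-sample median.

    QC and negative-control rows are transformed with their batch's factor
    but excluded from the medians.  A compound whose batch median is zero
    (or undefined) in some batch is left uncentered and flagged.
    """
    m.require_present(STEP_IS)
    m.require_absent(STEP_BATCH)
    study = m.role_mask(ROLE_SAMPLE)
    counts = m.sample_meta.loc[study, "batch_id"].value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"batches with fewer than 3 study samples: {small}")

    values = m.values.copy()
    global_med = values.loc[study].median(axis=0, skipna=True)
    uncentered: list[str] = []
    factors: dict[str, pd.Series] = {}
    for batch_id, batch_study in values.loc[study].groupby(
        m.sample_meta.loc[study, "batch_id"]
    ):
        batch_med = batch_study.median(axis=0, skipna=True)
        factor = global_med / batch_med
        bad = ~np.isfinite(factor) | (batch_med <= 0)
        uncentered.extend(values.columns[bad])
        factor[bad] = 1.0
        factors[batch_id] = factor
    uncentered = sorted(set(uncentered))
    if uncentered:
        logger.warning("batch centering skipped for %d compounds with a zero "
                       "batch median: %s", len(uncentered), uncentered[:5])
    for batch_id, factor in factors.items():
        rows = m.sample_meta["batch_id"] == batch_id
        values.loc[rows] = values.loc[rows] * factor
    return IntensityMatrix(
        values, m.sample_meta.copy(), None,
        m.with_step(STEP_BATCH, uncentered=uncentered),
    )


def filter_contaminants(
    m: IntensityMatrix,
    negative_controls: IntensityMatrix | None = None,
    ratio_threshold: float = 0.5,
) -> IntensityMatrix:
    """Drop compounds whose mean blank intensity is at least
    ``ratio_threshold`` times their mean study-sample intensity.

    ``negative_controls`` defaults to the blank rows of ``m`` itself.
    """
    m.require_absent(STEP_CONTAM)
    neg_source = negative_controls if negative_controls is not None else m
    neg = neg_source.values.loc[neg_source.role_mask(ROLE_NEG)]
    if m.is_channel is None and negative_controls is not None and \
            negative_controls.is_channel in neg.columns:
        neg = neg.drop(columns=[negative_controls.is_channel])
    if len(neg) == 0:
        raise ValueError("no negative-control injections available")
    neg = neg.reindex(columns=m.values.columns)
    study_mean = m.values.loc[m.role_mask(ROLE_SAMPLE)].mean(axis=0, skipna=True)
    blank_mean = neg.mean(axis=0, skipna=True).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = blank_mean / study_mean
    removed = list(m.values.columns[ratio.to_numpy() >= ratio_threshold])
    if len(removed) == len(m.values.columns):
        raise ValueError(
            f"contaminant filter at threshold {ratio_threshold} removed every compound"
        )
    values = m.values.drop(columns=removed)
    logger.info("contaminant filter removed %d compounds", len(removed))
    return IntensityMatrix(
        values, m.sample_meta.copy(), None,
        m.with_step(STEP_CONTAM, threshold=ratio_threshold, removed=removed),
    )


def presence_filter(m: IntensityMatrix, min_presence: float = 0.7) -> IntensityMatrix:
    """Drop compounds detected (value > 0) in fewer than ``min_presence``
    of study samples; zeros in retained compounds become missing (NaN)."""
    m.require_absent(STEP_PRESENCE)
    study = m.values.loc[m.role_mask(ROLE_SAMPLE)]
    detected = (study > 0).mean(axis=0)
    removed = list(m.values.columns[detected < min_presence])
    values = m.values.drop(columns=removed).replace(0.0, np.nan)
    if values.shape[1] == 0:
        raise ValueError("presence filter removed every compound")
    return IntensityMatrix(
        values, m.sample_meta.copy(), None,
        m.with_step(STEP_PRESENCE, min_presence=min_presence, removed=removed),
    )


def log_transform(m: IntensityMatrix, base: str = "e") -> IntensityMatrix:
    """Elementwise logarithm (base e or 2); zeros are treated as missing."""
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' or '2'")
    m.require_absent(STEP_LOG)
    arr = m.values.to_numpy(dtype=float).copy()
    arr[arr == 0.0] = np.nan
    if np.any(arr < 0):
        raise ValueError("negative intensities cannot be log transformed")
    with np.errstate(invalid="ignore"):
        out = np.log(arr) if base == "e" else np.log2(arr)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return IntensityMatrix(
        values, m.sample_meta.copy(), None, m.with_step(STEP_LOG, base=base)
    )


def timepoint_ratio(m15: IntensityMatrix, m20: IntensityMatrix) -> IntensityMatrix:
    """Per-subject 20-week / 15-week intensity ratio on the raw scale.

    Subjects present at only one timepoint are dropped (and counted in the
    provenance); a zero 15-week denominator makes that cell missing.
    """
    for m in (m15, m20):
        m.require_absent(STEP_LOG)
        m.require_absent(STEP_RATIO)
    common_compounds = [c for c in m20.values.columns if c in set(m15.values.columns)]
    if not common_compounds:
        raise ValueError("no shared compounds between timepoints")

    def by_subject(m: IntensityMatrix) -> pd.DataFrame:
        study = m.role_mask(ROLE_SAMPLE)
        vals = m.values.loc[study, common_compounds].copy()
        vals.index = m.sample_meta.loc[study, "subject_id"].to_numpy()
        return vals

    v15, v20 = by_subject(m15), by_subject(m20)
    common_subjects = [s for s in v20.index if s in set(v15.index)]
    dropped = sorted((set(v15.index) | set(v20.index)) - set(common_subjects))
    denom = v15.loc[common_subjects].replace(0.0, np.nan)
    ratio = v20.loc[common_subjects] / denom
    zero_denominators = int(denom.isna().to_numpy().sum())

    meta = pd.DataFrame(
        {
            "subject_id": common_subjects,
            "timepoint": "ratio",
            "batch_id": "ratio",
            "injection_role": ROLE_SAMPLE,
        },
        index=ratio.index,
    )
    ratio.index = [f"ratio_{s}" for s in common_subjects]
    meta.index = ratio.index
    if dropped:
        logger.info("timepoint ratio dropped %d subjects missing a timepoint", len(dropped))
    prov = m20.with_step(
        STEP_RATIO,
        dropped_subjects=len(dropped),
        zero_denominators=zero_denominators,
    )
    return IntensityMatrix(_nonneg(ratio), meta, None, prov)


def _nonneg(df: pd.DataFrame) -> pd.DataFrame:
    # ratios of non-negative inputs are non-negative; guard against -0.0
    return df.abs().where(~df.isna())


def qc_cv_report(m: IntensityMatrix) -> pd.DataFrame:
    """Per-batch QC coefficient of variation (monitoring only)."""
    qc = m.role_mask(ROLE_QC)
    if not qc.any():
        return pd.DataFrame(columns=["batch_id", "median_cv"])
    vals = m.values.loc[qc]
    batches = m.sample_meta.loc[qc, "batch_id"]
    records = []
    for batch_id, group in vals.groupby(batches):
        cv = group.std(axis=0, ddof=1) / group.mean(axis=0)
        records.append({"batch_id": batch_id, "median_cv": float(cv.median(skipna=True))})
    return pd.DataFrame.from_records(records)


def standard_pipeline(
    m: IntensityMatrix,
    ratio_threshold: float = 0.5,
    min_presence: float = 0.7,
) -> IntensityMatrix:
    """IS normalization -> batch centering -> contaminant and presence
    filters, in the fixed order (pre-log; ratios/logs are formed later)."""
    out = normalize_internal_standard(m)
    out = batch_median_center(out)
    out = filter_contaminants(out, ratio_threshold=ratio_threshold)
    return presence_filter(out, min_presence=min_presence)
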