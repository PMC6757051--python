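"""Univariate case-control screening.

Per-compound two-sided Mann-Whitney tests at each timepoint (and on
20w/15w ratios) with Benjamini-Hochberg FDR control applied within each
comparison, plus the conventional univariate clinical-covariate tests
(Mann-Whitney for continuous covariates, continuity-corrected chi-squared
for well-filled 2x2 tables, Fisher's exact test otherwise).

Controls are always the term deliveries (ga >= 37 weeks); for an early
threshold (e.g. <34 weeks) the late-preterm deliveries are excluded from
the comparison rather than relabelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    BINARY_COVARIATES,
    IntensityMatrix,
    ROLE_SAMPLE,
    analysis_subset,
    case_labels,
)

#: combined sample size at or below which the exact Mann-Whitney null
#: distribution is enumerated (when there are no ties)
EXACT_N = 20


def mann_whitney(x_case, x_control) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; U is reported for the case group.

    Uses the exact null distribution when the combined sample size is at
    most ``EXACT_N`` and there are no ties, and the normal approximation
    with tie and continuity corrections otherwise.
    """
    x = np.asarray(x_case, dtype=float)
    y = np.asarray(x_control, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty after missing-value removal")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= EXACT_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, returned in the input
    order; m is the length of the vector, i.e. the number of tests in the
    comparison being adjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ScreenResult:
    """Per-compound screen for one comparison (timepoint or ratio)."""

    table: pd.DataFrame
    comparison: str
    threshold: float
    alpha: float
    n_case: int
    n_control: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]


def screen(
    matrix: IntensityMatrix,
    clinical: pd.DataFrame,
    comparison: str,
    threshold: float = 37.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Mann-Whitney screen of every compound in ``matrix``.

    ``matrix`` holds one study row per subject (a preprocessed timepoint
    matrix or a ratio matrix); missing cells are excluded pairwise.
    Benjamini-Hochberg adjustment is applied across exactly the compounds
    tested here.
    """
    study = matrix.role_mask(ROLE_SAMPLE)
    vals = matrix.values.loc[study]
    subjects = matrix.sample_meta.loc[study, "subject_id"]
    sub = analysis_subset(clinical, threshold).set_index("subject_id")
    keep = subjects.isin(sub.index).to_numpy()
    vals = vals.loc[keep]
    subjects = subjects.loc[keep]
    is_case = case_labels(sub.loc[subjects], threshold).to_numpy()
    n_case, n_control = int(is_case.sum()), int((~is_case).sum())
    if n_case < 5:
        raise ValueError(
            f"threshold {threshold} leaves only {n_case} cases; refusing to screen"
        )

    rows = []
    for name in vals.columns:
        col = vals[name].to_numpy(dtype=float)
        x, y = col[is_case], col[~is_case]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            rows.append((name, len(x), len(y), np.nan, np.nan, "untestable"))
            continue
        u, p = mann_whitney(x, y)
        direction = "higher in cases" if np.median(x) > np.median(y) else "lower in cases"
        rows.append((name, len(x), len(y), u, p, direction))
    table = pd.DataFrame(
        rows, columns=["compound", "n_case", "n_control", "U", "p", "direction"]
    )
    testable = table["p"].notna()
    q = np.full(len(table), np.nan)
    if testable.any():
        q[testable.to_numpy()] = bh_adjust(table.loc[testable, "p"].to_numpy())
    table["q"] = q
    table["comparison"] = comparison
    table["threshold"] = threshold
    table["significant"] = table["q"] < alpha
    table = table.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    return ScreenResult(table, comparison, threshold, alpha, n_case, n_control)


# --------------------------------------------------------------------------
# clinical covariate tests
# --------------------------------------------------------------------------

CONTINUOUS_COVARIATES = ["age", "bmi", "height"]


def _two_by_two(x: pd.Series, is_case: np.ndarray) -> np.ndarray:
    return np.array(
        [
            [int(((x == 1) & is_case).sum()), int(((x == 0) & is_case).sum())],
            [int(((x == 1) & ~is_case).sum()), int(((x == 0) & ~is_case).sum())],
        ]
    )


def categorical_test(table: np.ndarray) -> tuple[float, str]:
    """Chi-squared (with continuity correction on 2x2) when all expected
    counts are at least 5, otherwise Fisher's exact test (2x2 only)."""
    table = np.asarray(table)
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        _, p, _, _ = stats.chi2_contingency(table, correction=(table.shape == (2, 2)))
        return float(p), "chi2"
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return float(p), "fisher"
    # sparse r x c: chi-squared anyway, flagged
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p), "chi2_sparse"


def clinical_univariate(clinical: pd.DataFrame, threshold: float = 37.0) -> pd.DataFrame:
    """Per-covariate case-control tests mirroring the usual baseline table."""
    sub = analysis_subset(clinical, threshold)
    is_case = case_labels(sub, threshold).to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("need at least one case and one control")
    records = []

    def add(name, p, test, note=""):
        records.append({"covariate": name, "p": p, "test": test, "note": note})

    for name in CONTINUOUS_COVARIATES:
        col = sub[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            add(name, np.nan, "none", "constant covariate")
            continue
        _, p = mann_whitney(col[is_case], col[~is_case])
        add(name, p, "mann_whitney")

    for name in BINARY_COVARIATES:
        x = sub[name].astype(int)
        if x.nunique() < 2:
            add(name, np.nan, "none", "constant covariate")
            continue
        p, test = categorical_test(_two_by_two(x, is_case))
        add(name, p, test)

    # smoking: 3-category test and current-vs-never 2x2
    smk = sub["smoking"]
    tab3 = np.array(
        [
            [int(((smk == lvl) & grp).sum()) for lvl in ("no smoking", "quit", "current")]
            for grp in (is_case, ~is_case)
        ]
    )
    if (tab3.sum(axis=0) > 0).sum() >= 2:
        p, test = categorical_test(tab3[:, tab3.sum(axis=0) > 0])
        add("smoking (3-category)", p, test)
        cur = smk.isin(["no smoking", "current"])
        tab2 = _two_by_two((smk == "current").astype(int)[cur], is_case[cur.to_numpy()])
        if (tab2.sum(axis=1) > 0).all() and (tab2.sum(axis=0) > 0).all():
            p, test = categorical_test(tab2)
            add("smoking (current vs no smoking)", p, test)
    else:
        add("smoking (3-category)", np.nan, "none", "constant covariate")

    grav = sub["gravidity"]
    tabg = np.array(
        [
            [int(((grav == lvl) & grp).sum()) for lvl in ("1", "2", "3+")]
            for grp in (is_case, ~is_case)
        ]
    )
    if (tabg.sum(axis=0) > 0).sum() >= 2:
        p, test = categorical_test(tabg[:, tabg.sum(axis=0) > 0])
        add("gravidity", p, test)
    else:
        add("gravidity", np.nan, "none", "constant covariate")
    return pd.DataFrame.from_records(records)
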