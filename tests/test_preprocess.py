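"""Normalization-stage contracts: IS division, batch medians, filters."""

import numpy as np
import pandas as pd
import pytest

import ptbmetab as p
from ptbmetab.containers import IS_CHANNEL, META_COLUMNS, IntensityMatrix, ProvenanceError


def toy_matrix(values, roles=None, batches=None, is_col=True):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    names = [f"c{j}" for j in range(k - (1 if is_col else 0))]
    if is_col:
        names.append(IS_CHANNEL)
    idx = [f"inj{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "timepoint": "15w",
            "batch_id": batches if batches is not None else ["b0"] * n,
            "injection_role": roles if roles is not None else ["sample"] * n,
        },
        index=idx,
    )
    meta.loc[meta["injection_role"] != "sample", "subject_id"] = ""
    return IntensityMatrix(
        pd.DataFrame(values, index=idx, columns=names),
        meta,
        IS_CHANNEL if is_col else None,
    )


class TestInternalStandard:
    def test_self_normalization_gives_ones(self):
        m = toy_matrix([[5.0, 5.0, 5.0], [2.0, 2.0, 2.0]])
        out = p.normalize_internal_standard(m)
        assert np.allclose(out.values.to_numpy(), 1.0)
        assert IS_CHANNEL not in out.values.columns

    def test_invariant_to_per_injection_scaling(self):
        m = toy_matrix([[3.0, 7.0, 2.0], [1.0, 4.0, 5.0]])
        scaled = toy_matrix([[30.0, 70.0, 20.0], [1.0, 4.0, 5.0]])
        a = p.normalize_internal_standard(m).values.to_numpy()
        b = p.normalize_internal_standard(scaled).values.to_numpy()
        assert np.allclose(a, b)

    def test_zero_is_in_study_row_fails_listing_injection(self):
        m = toy_matrix([[3.0, 7.0, 0.0], [1.0, 4.0, 5.0]])
        with pytest.raises(ValueError, match="inj0"):
            p.normalize_internal_standard(m)

    def test_reduces_between_injection_cv_of_null_compound(self, cork_cohort):
        _, _, m15, _ = cork_cohort
        study = m15.role_mask("sample")
        raw = m15.values.loc[study, "cmpd_100"]
        norm = p.normalize_internal_standard(m15)
        after = norm.values.loc[study, "cmpd_100"]
        cv = lambda x: x.std(ddof=1) / x.mean()
        assert cv(after) < cv(raw)

    def test_reapplication_raises(self):
        m = toy_matrix([[3.0, 7.0, 2.0]])
        out = p.normalize_internal_standard(m)
        with pytest.raises(ProvenanceError):
            p.normalize_internal_standard(out)


class TestBatchMedianCentering:
    def _normed(self, values, **kw):
        m = toy_matrix(values, **kw)
        return p.normalize_internal_standard(m)

    def test_single_batch_is_identity(self):
        vals = np.c_[np.arange(1.0, 6.0), np.arange(2.0, 7.0), np.ones(5)]
        out = p.batch_median_center(self._normed(vals))
        assert np.allclose(out.values.to_numpy(), vals[:, :2])

    def test_exactly_removes_multiplicative_batch_effect(self):
        base = np.abs(np.random.default_rng(0).normal(5, 1, size=(4, 2)))
        vals = np.vstack([base, base * 3.0])
        vals = np.c_[vals, np.ones(8)]
        batches = ["b0"] * 4 + ["b1"] * 4
        out = p.batch_median_center(self._normed(vals, batches=batches))
        v = out.values
        med0 = v.iloc[:4].median(axis=0)
        med1 = v.iloc[4:].median(axis=0)
        assert np.allclose(med0, med1)

    def test_generator_batch_variance_of_medians_vanishes(self, cork_cohort, normalized):
        """After centering, the per-compound spread of batch medians is
        zero up to float tolerance even at batch_sd = 0.3."""
        n15, _ = normalized
        study = n15.role_mask("sample")
        vals = n15.values.loc[study]
        batches = n15.sample_meta.loc[study, "batch_id"]
        meds = vals.groupby(batches).median()
        assert float(meds.var(axis=0).max()) < 1e-18 * float(vals.to_numpy().var())

    def test_requires_is_normalization_first(self):
        m = toy_matrix([[1.0, 2.0, 1.0]] * 3)
        with pytest.raises(ProvenanceError):
            p.batch_median_center(m)

    def test_qc_rows_excluded_from_medians_but_transformed(self):
        # QC values wildly different; medians must come from samples only
        vals = np.array(
            [[2.0, 1.0], [4.0, 1.0], [6.0, 1.0], [1000.0, 1.0],
             [20.0, 1.0], [40.0, 1.0], [60.0, 1.0], [1000.0, 1.0]]
        )
        roles = ["sample"] * 3 + ["QC"] + ["sample"] * 3 + ["QC"]
        batches = ["b0"] * 4 + ["b1"] * 4
        out = p.batch_median_center(
            self._normed(vals, roles=roles, batches=batches))
        v = out.values["c0"]
        # global sample median 13, batch medians 4 and 40
        assert np.allclose(v.iloc[:3], np.array([2.0, 4.0, 6.0]) * 13 / 4)
        assert np.allclose(v.iloc[4:7], np.array([20.0, 40.0, 60.0]) * 13 / 40)
        # QC transformed with its batch's factor, not left alone
        assert v.iloc[3] == pytest.approx(1000.0 * 13 / 4)
        assert v.iloc[7] == pytest.approx(1000.0 * 13 / 40)


class TestContaminantFilter:
    def _cohort_norm(self, cork_cohort):
        _, _, m15, _ = cork_cohort
        return p.batch_median_center(p.normalize_internal_standard(m15))

    def test_absent_in_blanks_is_retained_and_equal_removed(self):
        vals = np.array([[10.0, 8.0, 1.0], [12.0, 9.0, 1.0], [11.0, 10.0, 1.0],
                         [0.0, 9.0, 1.0]])
        roles = ["sample"] * 3 + ["negative_control"]
        m = p.batch_median_center(
            p.normalize_internal_standard(toy_matrix(vals, roles=roles)))
        out = p.filter_contaminants(m, ratio_threshold=0.5)
        assert "c0" in out.values.columns      # absent in blank -> kept
        assert "c1" not in out.values.columns  # blank ~ samples -> removed

    def test_planted_contaminants_recovered_exactly(self, cork_cohort):
        cfg, _, m15, _ = cork_cohort
        m = self._cohort_norm(cork_cohort)
        out = p.filter_contaminants(m, ratio_threshold=0.5)
        removed = out.provenance[-1]["removed"]
        expected = sorted(m15.compound_names[j] for j in cfg.contaminant_compounds)
        assert sorted(removed) == expected

    def test_removing_everything_is_an_error(self):
        vals = np.array([[10.0, 1.0], [12.0, 1.0], [11.0, 1.0], [50.0, 1.0]])
        roles = ["sample"] * 3 + ["negative_control"]
        m = p.batch_median_center(
            p.normalize_internal_standard(toy_matrix(vals, roles=roles)))
        with pytest.raises(ValueError, match="every compound"):
            p.filter_contaminants(m, ratio_threshold=0.01)


class TestLogAndRatio:
    def test_log_basics(self):
        m = toy_matrix([[1.0, 8.0, 1.0]])
        norm = p.normalize_internal_standard(m)
        le = p.log_transform(norm, base="e")
        l2 = p.log_transform(norm, base="2")
        assert le.values.iloc[0, 0] == 0.0
        assert np.allclose(l2.values.to_numpy() * np.log(2), le.values.to_numpy())
        assert np.allclose(np.exp(le.values.to_numpy()), norm.values.to_numpy())

    def test_double_log_raises(self):
        m = p.normalize_internal_standard(toy_matrix([[1.0, 8.0, 1.0]]))
        out = p.log_transform(m)
        with pytest.raises(ProvenanceError):
            p.log_transform(out)

    def test_identical_timepoints_give_unit_ratio(self):
        m = p.normalize_internal_standard(toy_matrix([[2.0, 8.0, 1.0], [3.0, 5.0, 1.0]]))
        r = p.timepoint_ratio(m, m)
        assert np.allclose(r.values.to_numpy(), 1.0)

    def test_subject_missing_one_timepoint_dropped_and_counted(self):
        m15 = p.normalize_internal_standard(
            toy_matrix([[2.0, 8.0, 1.0], [3.0, 5.0, 1.0]]))
        m20 = p.normalize_internal_standard(toy_matrix([[4.0, 4.0, 1.0]]))
        r = p.timepoint_ratio(m15, m20)
        assert list(r.sample_meta["subject_id"]) == ["s0"]
        assert r.provenance[-1]["dropped_subjects"] == 1

    def test_log_ratio_identity(self, normalized):
        n15, n20 = normalized
        r = p.timepoint_ratio(n15, n20)
        lr = p.log_transform(r).values
        l15 = p.log_transform(n15)
        l20 = p.log_transform(n20)

        def per_subject(m):
            study = m.role_mask("sample")
            v = m.values.loc[study, lr.columns].copy()
            v.index = m.sample_meta.loc[study, "subject_id"].to_numpy()
            return v

        diff = per_subject(l20) - per_subject(l15)
        diff = diff.loc[[s.removeprefix("ratio_") for s in lr.index]]
        assert np.allclose(diff.to_numpy(), lr.to_numpy(), equal_nan=True)


def test_full_pipeline_provenance_order(normalized):
    n15, _ = normalized
    steps = [s["step"] for s in n15.provenance]
    assert steps == [
        "internal_standard_normalization",
        "batch_median_centering",
        "contaminant_filter",
        "presence_filter",
    ]


def test_composition_removes_injection_and_batch_scaling_exactly():
    """A noiseless matrix distorted by per-injection and per-batch factors
    is restored (up to one global per-compound scale) by IS + medians."""
    rng = np.random.default_rng(42)
    base = np.abs(rng.normal(10, 2, size=(1, 3)))        # true compound levels
    truth = np.repeat(base, 12, axis=0)
    inj = np.exp(rng.normal(0, 0.5, size=(12, 1)))       # recovery
    batch = np.repeat(np.exp(rng.normal(0, 0.7, size=(3, 3))), 4, axis=0)
    vals = np.c_[truth * inj * batch, 5.0 * inj.ravel()]
    batches = np.repeat(["b0", "b1", "b2"], 4)
    m = toy_matrix(vals, batches=list(batches))
    out = p.batch_median_center(p.normalize_internal_standard(m))
    v = out.values.to_numpy()
    # constant within compound across every injection and batch
    assert np.allclose(v, v[0], rtol=1e-9)
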