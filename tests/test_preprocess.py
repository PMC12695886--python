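"""QC, outlier-fence and signal-to-noise tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csf_nathist.preprocess import (ProteomicMatrix, _anova_sigma_tech,
                                    _reml_sigma_tech, compute_snr,
                                    filter_by_snr, floor_ms_outliers,
                                    log_transform, qc_hc_samples)


def _matrix(arr, prefix="S"):
    arr = np.asarray(arr, dtype=float)
    return ProteomicMatrix(values=pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"A{j}" for j in range(arr.shape[1])]))


class TestLogTransform:
    def test_known_values(self):
        m = _matrix([[np.e, 1.0]])
        out = log_transform(m)
        assert out.values.iloc[0, 0] == pytest.approx(1.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)

    def test_nonpositive_names_offender(self):
        m = _matrix([[1.0, -2.0]])
        with pytest.raises(ValueError, match="S0.*A1"):
            log_transform(m)

    def test_lognormal_column_means(self, rng):
        raw = np.exp(rng.normal(8.0, 1.0, size=(4000, 3)))
        out = log_transform(_matrix(raw))
        assert np.allclose(out.values.mean(), 8.0, atol=0.1)


class TestHCSampleQC:
    def test_contaminated_sample_dropped(self, rng):
        vals = rng.normal(0, 1, size=(30, 50))
        vals[3, :10] += 10.0          # 20% of somamers pushed 10 SD high
        m = _matrix(vals)
        out, report = qc_hc_samples(m, list(m.sample_ids))
        assert report.dropped_samples == ["S3"]
        assert "S3" not in out.sample_ids

    def test_clean_cohort_keeps_everyone(self, rng):
        m = _matrix(rng.normal(0, 1, size=(40, 80)))
        out, report = qc_hc_samples(m, list(m.sample_ids))
        assert report.dropped_samples == []

    def test_drop_frac_one_never_drops(self, rng):
        vals = rng.normal(0, 1, size=(10, 20))
        vals[0] += 50.0
        out, report = qc_hc_samples(_matrix(vals), [f"S{i}" for i in range(10)],
                                    drop_frac=1.0)
        assert report.dropped_samples == []

    def test_ms_samples_never_removed(self, rng):
        vals = rng.normal(0, 1, size=(20, 30))
        vals[15:, :] += 100.0          # extreme values in non-HC rows
        m = _matrix(vals)
        out, _ = qc_hc_samples(m, [f"S{i}" for i in range(10)])
        assert all(f"S{i}" in out.sample_ids for i in range(10, 20))


class TestFlooring:
    def test_brute_force_oracle_on_random_matrix(self, rng):
        """Floored-cell count equals an independent quantile/clip scan."""
        vals = rng.standard_t(df=3, size=(60, 25)) * 2.0
        m = _matrix(vals)
        out, report = floor_ms_outliers(m, list(m.sample_ids), k=3.0)
        q1 = np.quantile(vals, 0.25, axis=0)
        q3 = np.quantile(vals, 0.75, axis=0)
        lo, hi = q1 - 3 * (q3 - q1), q3 + 3 * (q3 - q1)
        expected = ((vals < lo) | (vals > hi)).sum()
        assert report.floored_counts.sum() == expected
        assert np.allclose(out.values.to_numpy(),
                           np.clip(vals, lo, hi))

    def test_values_inside_fences_untouched(self, rng):
        vals = rng.uniform(0, 1, size=(20, 5))
        m = _matrix(vals)
        out, report = floor_ms_outliers(m, list(m.sample_ids))
        assert report.floored_counts.sum() == 0
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_only_ms_rows_modified(self, rng):
        vals = rng.normal(0, 1, size=(30, 10))
        vals[0, 0] = 100.0             # HC row outlier must survive
        vals[10, 1] = 100.0            # MS row outlier must be floored
        m = _matrix(vals)
        ms = [f"S{i}" for i in range(10, 30)]
        out, _ = floor_ms_outliers(m, ms)
        assert out.values.iloc[0, 0] == 100.0
        assert out.values.iloc[10, 1] < 100.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_flooring_idempotent(self, seed):
        """Re-flooring a floored matrix changes nothing."""
        vals = np.random.default_rng(seed).standard_t(3, size=(24, 6))
        m = _matrix(vals)
        once, _ = floor_ms_outliers(m, list(m.sample_ids))
        twice, report = floor_ms_outliers(once, list(m.sample_ids))
        assert report.floored_counts.sum() == 0
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_median_center_switch(self, rng):
        vals = np.concatenate([rng.normal(0, 1, (30, 3)),
                               [[40.0, 0, 0]]])
        m = _matrix(vals)
        tukey, _ = floor_ms_outliers(m, list(m.sample_ids),
                                     center="quartile")
        med, _ = floor_ms_outliers(m, list(m.sample_ids), center="median")
        # median-centered fences are tighter: floored value is smaller
        assert med.values.iloc[30, 0] < tukey.values.iloc[30, 0] < 40.0


def _longitudinal_hc(rng, n_patients=20, visits=3, tech=0.5, between=1.0):
    g = np.repeat(np.arange(n_patients), visits)
    y = rng.normal(0, between, n_patients)[g] + rng.normal(0, tech, len(g))
    return y, g


class TestSNR:
    def _build(self, ms_vals, hc_vals, hc_groups):
        n_ms, n_hc = len(ms_vals), len(hc_vals)
        vals = np.concatenate([ms_vals, hc_vals])[:, None]
        ids = [f"MS{i}" for i in range(n_ms)] + [f"HC{i}" for i in range(n_hc)]
        m = ProteomicMatrix(values=pd.DataFrame(vals, index=ids,
                                                columns=["A0"]))
        hc_long = {}
        for pid, sid in zip(hc_groups, ids[n_ms:]):
            hc_long.setdefault(f"P{pid}", []).append(sid)
        return m, [f"MS{i}" for i in range(n_ms)], hc_long

    def test_identical_repeat_visits_give_snr_one(self, rng):
        ms = rng.normal(0, 2, 40)
        hc = np.repeat(rng.normal(0, 1, 5), 2)   # exact repeats
        m, ms_ids, hc_long = self._build(ms, hc, np.repeat(np.arange(5), 2))
        rec = compute_snr(m, ms_ids, hc_long)[0]
        assert rec.sigma_tech == pytest.approx(0.0, abs=1e-9)
        assert rec.snr == pytest.approx(1.0)

    def test_degenerate_constant_somamer_flagged(self):
        ms = np.zeros(10)
        hc = np.zeros(8)
        m, ms_ids, hc_long = self._build(ms, hc, np.repeat(np.arange(4), 2))
        rec = compute_snr(m, ms_ids, hc_long)[0]
        assert rec.degenerate and not rec.passed
        assert filter_by_snr([rec]) == []

    def test_formula_with_known_sigmas(self, rng):
        """sigma_clin = 2, sigma_tech -> 1 recovers SNR ~ 0.8."""
        ms = rng.normal(0, 2, 5000)
        hc, g = _longitudinal_hc(rng, n_patients=400, visits=3, tech=1.0)
        m, ms_ids, hc_long = self._build(ms, hc, g)
        rec = compute_snr(m, ms_ids, hc_long)[0]
        assert rec.snr == pytest.approx(0.8, abs=0.02)

    def test_snr_monotone_decreasing_in_sigma_tech(self, rng):
        ms = rng.normal(0, 1.5, 2000)
        snrs = []
        for tech in (0.2, 0.6, 1.2):
            hc, g = _longitudinal_hc(np.random.default_rng(7),
                                     n_patients=300, visits=2, tech=tech)
            m, ms_ids, hc_long = self._build(ms, hc, g)
            snrs.append(compute_snr(m, ms_ids, hc_long)[0].snr)
        assert snrs[0] > snrs[1] > snrs[2]
        assert all(0.0 <= s <= 1.0 for s in snrs)

    def test_threshold_inclusive(self):
        from csf_nathist.preprocess import SNRRecord
        recs = [SNRRecord("a", 2, 1, 0.80, True),
                SNRRecord("b", 2, 1, 0.79, False),
                SNRRecord("c", 2, 1, 0.95, True)]
        assert filter_by_snr(recs, 0.8) == ["a", "c"]
        assert filter_by_snr(recs, 0.0) == ["a", "b", "c"]


class TestVarianceDecomposition:
    def test_reml_equals_anova_on_balanced_designs(self):
        """On balanced designs REML and the two-level ANOVA estimator agree."""
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y, g = _longitudinal_hc(rng, n_patients=15, visits=3)
            assert _reml_sigma_tech(y, g) == pytest.approx(
                _anova_sigma_tech(y, g), abs=1e-6)

    def test_reml_matches_statsmodels_mixedlm_unbalanced(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        sizes = [2, 3, 2, 4, 2, 3, 5, 2, 2, 3]
        g = np.concatenate([[i] * s for i, s in enumerate(sizes)])
        y = rng.normal(0, 1.2, len(sizes))[g] + rng.normal(0, 0.6, len(g))
        df = pd.DataFrame({"y": y, "g": g})
        ml = smf.mixedlm("y ~ 1", df, groups=df["g"]).fit(reml=True)
        assert _reml_sigma_tech(y, g) == pytest.approx(
            float(np.sqrt(ml.scale)), abs=1e-4)

    def test_zero_between_patient_variance_boundary(self, rng):
        """Without a true patient effect the REML estimate is bracketed by
        the within-group and pooled SDs and stays near the truth (1.0)."""
        y = rng.normal(0, 1, 60)                 # no patient effect at all
        g = np.repeat(np.arange(20), 3)
        est = _reml_sigma_tech(y, g)
        assert _anova_sigma_tech(y, g) - 1e-9 <= est \
            <= np.std(y, ddof=1) + 1e-9
        assert est == pytest.approx(1.0, abs=0.2)
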