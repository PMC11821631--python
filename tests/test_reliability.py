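"""Test-retest chain: paired bias, Hedges' g, ICC(A,1), SEM/MDC."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmgkit.metrics import ALL_PARAMETERS
from tmgkit.reliability import (
    effect_size_band,
    hedges_g,
    hedges_g_from_summary,
    icc_a1,
    icc_band,
    paired_bias,
    reliability_table,
    sem_mdc,
)


class TestPairedBias:
    def test_identical_arrays(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_bias(x, x)
        assert res.bias == 0.0 and res.t == 0.0 and res.p == 1.0

    def test_constant_shift_is_degenerate(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_bias(x + 1.0, x)
        assert res.degenerate
        assert math.isinf(res.t) and res.t > 0
        assert res.p == 0.0

    def test_matches_textbook_computation(self, rng):
        x = rng.normal(10, 2, 16)
        y = rng.normal(10, 2, 16)
        res = paired_bias(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(16))
        from scipy import stats
        p_ref = 2 * stats.t.sf(abs(t_ref), 15)
        assert res.t == pytest.approx(t_ref, abs=1e-10)
        assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_bias([1.0, 2.0], [1.0, 2.0, 3.0])


class TestHedgesG:
    def test_identical_arrays_give_trivial_zero(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        res = hedges_g(x, x)
        assert res.g == 0.0 and res.band == "trivial"

    def test_baseline_summary_reproduces_printed_effect(self):
        # Pt test-retest summary: 19.47 +/- 8.49 vs 19.38 +/- 8.50, n=16
        g = hedges_g_from_summary(19.47, 8.49, 19.38, 8.50, 16)
        assert g == pytest.approx(0.01, abs=0.005)

    @pytest.mark.parametrize("g,band", [
        (0.1, "trivial"), (0.3, "small"), (1.3, "large"),
        (-1.3, "large"), (2.5, "very large"), (5.0, "extremely large"),
    ])
    def test_magnitude_bands(self, g, band):
        assert effect_size_band(g) == band

    def test_zero_spread_is_undefined(self):
        x = np.full(6, 2.0)
        res = hedges_g(x, x)
        assert np.isnan(res.g) and res.band == "undefined"


class TestIcc:
    def test_exact_duplicate_gives_one(self):
        x = np.array([1.0, 5.0, 9.0, 13.0])
        res = icc_a1(x, x)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_toy_data_matches_mean_squares_oracle(self):
        """From-scratch variance-components computation on the 4-subject
        toy set {(1,2),(3,4),(5,6),(7,8)}."""
        data = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(0) - grand) ** 2).sum() / (k - 1)
        sse = ((data - data.mean(1, keepdims=True)
                - data.mean(0, keepdims=True) + grand) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse
                                  + k * (msc - mse) / n)
        res = icc_a1(data[:, 0], data[:, 1])
        assert res.icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_absolute_agreement_single(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(10, 3, 14)
        y = x + rng.normal(0.3, 1.0, 14)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(14), 2),
            "rater": np.tile([0, 1], 14),
            "score": np.column_stack([x, y]).ravel()})
        ref = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="score")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0]
        res = icc_a1(x, y)
        assert res.icc == pytest.approx(row.ICC, abs=1e-10)
        assert res.ci[0] == pytest.approx(row.CI95[0], abs=0.01)
        assert res.ci[1] == pytest.approx(row.CI95[1], abs=0.01)

    def test_independent_ratings_give_near_zero(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        res = icc_a1(x, y)
        assert abs(res.icc) < 0.15
        assert res.ci[0] < 0.0 < res.ci[1] + 0.2

    def test_constant_data_is_undefined(self):
        x = np.full(5, 3.0)
        assert np.isnan(icc_a1(x, x).icc)

    @pytest.mark.parametrize("icc,band", [
        (0.3, "poor"), (0.6, "moderate"), (0.8, "good"), (0.95, "excellent"),
    ])
    def test_bands(self, icc, band):
        assert icc_band(icc) == band


class TestSemMdc:
    def test_perfect_reliability_gives_zero(self):
        sem, sem_pct, mdc, mdc_pct = sem_mdc(5.0, 1.0, 10.0)
        assert sem == 0.0 and mdc == 0.0

    def test_contraction_time_chain(self):
        """SEM 0.80 ms at grand mean 21.685 ms gives SEM% ~3.69 and
        MDC ~2.22 ms."""
        sem = 0.80
        mdc = sem * 1.96 * math.sqrt(2)
        assert mdc == pytest.approx(2.22, abs=0.005)
        assert 100 * sem / 21.685 == pytest.approx(3.69, abs=0.005)
        # same numbers through the function, given the implied icc
        sd_all = sem / math.sqrt(1 - 0.88)
        out = sem_mdc(sd_all, 0.88, 21.685)
        assert out[0] == pytest.approx(0.80, abs=1e-12)
        assert out[2] == pytest.approx(mdc, abs=1e-12)

    @given(sd=st.floats(0.0, 100.0), icc=st.floats(0.0, 1.0))
    def test_formula_oracle(self, sd, icc):
        sem, _, mdc, _ = sem_mdc(sd, icc, 1.0)
        assert sem == pytest.approx(sd * math.sqrt(1 - icc), rel=1e-12,
                                    abs=1e-12)
        assert mdc == pytest.approx(sem * 1.96 * math.sqrt(2), rel=1e-12,
                                    abs=1e-12)

    def test_sem_strictly_decreases_in_icc(self):
        values = [sem_mdc(5.0, icc, 10.0)[0]
                  for icc in (0.0, 0.25, 0.5, 0.75, 0.99)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sem_mdc(1.0, 1.5, 10.0)
        with pytest.raises(ValueError):
            sem_mdc(-1.0, 0.5, 10.0)


class TestPipelineReliability:
    def test_noiseless_cohort_has_perfect_reliability(self, noiseless_params):
        tbl = reliability_table(noiseless_params)
        assert len(tbl) == len(ALL_PARAMETERS)
        assert (tbl["icc"].round(9) == 1.0).all()
        np.testing.assert_allclose(tbl["mdc"], 0.0, atol=1e-6)

    def test_sem_increases_with_within_subject_noise(self):
        from tmgkit.signals import extract_cohort
        from tmgkit.synthetic import SimulationConfig, simulate_cohort

        schedule = ("Pre1", "Pre2", "Set1", "Post1", "Post15")
        sems = []
        for cv in (0.01, 0.05, 0.15):
            cfg = SimulationConfig(n_subjects=8, schedule=schedule,
                                   within_subject_sd=cv, seed=21)
            params = extract_cohort(simulate_cohort(cfg))
            tbl = reliability_table(params, parameters=["Pt"])
            sems.append(float(tbl["sem"].iloc[0]))
        assert sems[0] < sems[1] < sems[2]
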