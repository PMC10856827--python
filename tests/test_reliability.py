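"""Comparison designs, ICC(A,1) against oracles, SEM/MDC, Koo-Li categories."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitrel import reliability, synth
from gaitrel.reliability import (
    MDC_FACTOR,
    DesignError,
    build_design,
    categorize,
    day_pairs,
    icc_a1,
    run_reliability,
    sem_mdc,
)

from _oracles import icc_a1_bruteforce


class TestDesigns:
    def test_between_day_pairs_canonical(self):
        assert day_pairs(5) == [(1, 2), (2, 3), (3, 4), (4, 5), (5, 2)]
        d = build_design("between_day", n_days=5)
        assert len(d.pairs) == 5
        for (a, b), (da, db) in zip(d.pairs, day_pairs(5)):
            assert (a["day"], b["day"]) == (da, db)
            assert a["run"] == b["run"] == 1
            assert a["calibration"] == b["calibration"] == 1

    def test_within_day_five_pairs_runs_1_and_3(self):
        d = build_design("within_day", n_days=5)
        assert len(d.pairs) == 5
        for day, (a, b) in enumerate(d.pairs, start=1):
            assert a["day"] == b["day"] == day
            assert (a["run"], b["run"]) == (1, 3)
            assert a["calibration"] == b["calibration"] == 1

    def test_calibration_same_run_different_calibrations(self):
        d = build_design("calibration", n_days=5)
        for a, b in d.pairs:
            assert a["day"] == b["day"] and a["run"] == b["run"] == 1
            assert (a["calibration"], b["calibration"]) == (1, 2)

    def test_two_days_gives_single_pair(self):
        d = build_design("between_day", n_days=2)
        assert [(a["day"], b["day"]) for a, b in d.pairs] == [(1, 2)]

    def test_invalid_designs_rejected(self):
        with pytest.raises(DesignError):
            build_design("between_day", n_days=1)
        with pytest.raises(DesignError):
            build_design("sideways")


class TestIccA1:
    def test_identical_columns_perfect_agreement(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_a1(m)
        assert res.icc == pytest.approx(1.0)
        assert res.mse == pytest.approx(0.0)

    def test_frozen_integer_matrix(self):
        # brute-force two-way ANOVA on [[1,2],[3,4],[5,6],[7,8]]:
        # MSR = 40/3, MSC = 2, MSE = 0 -> ICC = 40/43
        res = icc_a1([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert res.icc == pytest.approx(40.0 / 43.0, abs=1e-12)
        assert res.ms_rows == pytest.approx(40.0 / 3.0)
        assert res.ms_cols == pytest.approx(2.0)
        assert res.mse == pytest.approx(0.0)

    @given(
        st.lists(
            st.lists(st.integers(-50, 50), min_size=2, max_size=2),
            min_size=3,
            max_size=8,
        )
    )
    def test_matches_bruteforce_oracle(self, rows):
        m = np.array(rows, dtype=float)
        ours = icc_a1(m)
        oracle = icc_a1_bruteforce(rows)
        if np.isnan(oracle["icc"]):
            assert ours.degenerate
        else:
            assert ours.icc == pytest.approx(oracle["icc"], abs=1e-10)
            assert ours.mse == pytest.approx(oracle["mse"], abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        m = rng.normal(10, 3, (12, 2)) + rng.normal(0, 1, (12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0]
        assert icc_a1(m).icc == pytest.approx(icc2, abs=1e-8)

    @given(
        st.floats(-100, 100, allow_nan=False),
        st.floats(0.1, 50, allow_nan=False),
    )
    def test_shift_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 2, (6, 2)) + rng.normal(0, 3, (6, 1))
        base = icc_a1(m).icc
        assert icc_a1(m * scale + shift).icc == pytest.approx(base, abs=1e-9)

    def test_column_shift_decreases_absolute_agreement(self):
        rng = np.random.default_rng(5)
        m = np.tile(rng.normal(0, 3, (8, 1)), (1, 2))  # perfectly consistent
        shifted = m.copy()
        shifted[:, 1] += 2.0
        assert icc_a1(shifted).icc < icc_a1(m).icc

    def test_monte_carlo_converges_to_analytic(self):
        rng = np.random.default_rng(6)
        n = 5000
        subject = rng.normal(0, 2.0, (n, 1))
        m = subject + rng.normal(0, 1.0, (n, 2))
        assert icc_a1(m).icc == pytest.approx(0.8, abs=0.02)

    def test_degenerate_matrix_flagged(self):
        res = icc_a1(np.zeros((4, 2)))
        assert res.degenerate
        assert np.isnan(res.icc)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_a1(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            icc_a1(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestSemMdc:
    @pytest.mark.parametrize(
        "mse,sem,mdc",
        [(0.0, 0.0, 0.0), (1.0, 1.0, 2.771859), (4.0, 2.0, 5.543717)],
    )
    def test_closed_form(self, mse, sem, mdc):
        s, m = sem_mdc(mse)
        assert s == pytest.approx(sem, abs=1e-6)
        assert m == pytest.approx(mdc, abs=1e-6)

    def test_ratio_is_196_sqrt2_exactly(self):
        for mse in (0.3, 1.7, 12.0):
            s, m = sem_mdc(mse)
            assert m / s == pytest.approx(MDC_FACTOR, abs=1e-12)

    def test_negative_mse_rejected(self):
        with pytest.raises(ValueError):
            sem_mdc(-0.1)


class TestCategorize:
    @pytest.mark.parametrize(
        "median,minimum,expected",
        [
            (0.95, 0.76, "good"),  # conservative downgrade by the minimum
            (0.90, 0.90, "excellent"),
            (0.45, 0.10, "poor"),
            (0.80, 0.78, "good"),
            (0.60, 0.20, "poor"),
        ],
    )
    def test_categories(self, median, minimum, expected):
        assert categorize(median, minimum) == expected

    def test_median_only(self):
        assert categorize(0.6) == "moderate"


class TestRunReliability:
    def _features(self, variance_components, seed=21, **kw):
        cfg = synth.SimulationConfig(
            n_participants=8,
            surfaces=("asphalt",),
            variance_components=variance_components,
            gate_noise_sd=0.0,
            stride_freq_within_sd=0.0,
            seed=seed,
            **kw,
        )
        table, truth = synth.simulate_feature_table(cfg)
        return table, truth

    def test_zero_error_variances_give_icc_one_mdc_zero(self):
        table, _ = self._features(
            {sig: synth.LevelVariances(runner=4.0) for sig in synth.DEFAULT_VARIANCES}
        )
        for e in run_reliability(table, variables=["IKF", "PKF", "IHF"]):
            assert np.allclose(e.icc, 1.0)
            assert np.allclose(e.mdc, 0.0)
            assert e.category == "excellent"

    def test_calibration_only_variance_structure(self):
        table, truth = self._features(
            {
                sig: synth.LevelVariances(runner=4.0, calibration=1.0)
                for sig in synth.DEFAULT_VARIANCES
            }
        )
        ests = {
            e.comparison_type: e
            for e in run_reliability(table, variables=["IKF"])
        }
        # same calibration on both within-day measurements: perfect agreement
        assert np.allclose(ests["within_day"].icc, 1.0)
        assert ests["calibration"].icc_median < 1.0
        true = synth.truth_icc(truth, "IKF", "calibration")
        assert ests["calibration"].icc_median == pytest.approx(true, abs=0.25)

    def test_missing_participant_excluded_listwise(self):
        table, _ = self._features(
            {"knee_flexion": synth.LevelVariances(runner=4.0, day=0.5)}
        )
        table.loc[
            (table["participant"] == "P01") & (table["day"] == 2), "IKF"
        ] = np.nan
        (est,) = run_reliability(
            table, variables=["IKF"], comparison_types=["between_day"]
        )
        assert any(p == "P01" for _, p in est.excluded)
        assert est.n_subjects[0] == 7  # day pair (1,2) lost one subject

    def test_mdc_sem_ratio_invariant(self):
        table, _ = self._features(
            {sig: synth.LevelVariances(runner=4.0, day=1.0) for sig in synth.DEFAULT_VARIANCES}
        )
        for e in run_reliability(table):
            nz = e.sem > 0
            assert np.allclose(e.mdc[nz] / e.sem[nz], MDC_FACTOR, atol=1e-12)
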