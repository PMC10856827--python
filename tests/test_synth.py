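"""Synthetic-cohort generator: determinism, counting, analytic truth, noise sharing."""

import numpy as np
import pytest

from gaitrel import synth
from gaitrel.synth import LevelVariances, SimulationConfig

from conftest import noise_free_variances


def _zero_noise(**kw):
    defaults = dict(
        gate_noise_sd=0.0, stride_freq_within_sd=0.0, period_jitter_frac=0.0
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenerateCohort:
    def test_same_seed_is_bit_identical(self, small_config):
        recs_a, truth_a = synth.generate_cohort(small_config)
        recs_b, truth_b = synth.generate_cohort(small_config)
        assert len(recs_a) == len(recs_b)
        for ra, rb in zip(recs_a, recs_b):
            assert ra.key == rb.key
            assert ra.avg_speed == rb.avg_speed
            for sig in ra.signals:
                assert np.array_equal(ra.signals[sig], rb.signals[sig])
        for key in truth_a.level_offsets:
            assert truth_a.level_offsets[key] == truth_b.level_offsets[key]

    def test_cohort_size_matches_design(self):
        cfg = _zero_noise(
            n_participants=17,
            n_days=5,
            surfaces=("asphalt", "woodchip"),
            strides_per_run=3,
            sample_rate=60.0,
        )
        recs, _ = synth.generate_cohort(cfg)
        assert len(recs) == 17 * 5 * 2 * 2 * 2 == 680
        assert len({r.key for r in recs}) == 680

    def test_zero_variance_runs_identical_across_days_runs_calibrations(self):
        cfg = _zero_noise(
            n_participants=2,
            n_days=3,
            surfaces=("asphalt",),
            strides_per_run=6,
            sample_rate=120.0,
            variance_components={
                sig: LevelVariances() for sig in synth.DEFAULT_VARIANCES
            },
        )
        recs, _ = synth.generate_cohort(cfg)
        by_pid = {}
        for r in recs:
            by_pid.setdefault(r.participant_id, []).append(r)
        for group in by_pid.values():
            ref = group[0]
            for other in group[1:]:
                for sig in ref.signals:
                    assert np.array_equal(ref.signals[sig], other.signals[sig])

    def test_rejects_too_few_strides(self):
        with pytest.raises(ValueError, match="strides_per_run"):
            synth.generate_cohort(_zero_noise(strides_per_run=2))

    def test_calibration_copies_share_stride_noise(self):
        cfg = _zero_noise(
            n_participants=2,
            n_days=1,
            surfaces=("asphalt",),
            strides_per_run=8,
            sample_rate=120.0,
            variance_components={
                sig: LevelVariances(stride=4.0) for sig in synth.DEFAULT_VARIANCES
            },
            seed=3,
        )
        recs, _ = synth.generate_cohort(cfg)
        by_run = {}
        for r in recs:
            by_run.setdefault((r.participant_id, r.day, r.surface, r.run), {})[
                r.calibration
            ] = r
        for copies in by_run.values():
            c1, c2 = copies[1], copies[2]
            for sig in c1.signals:
                # zero calibration variance: the two copies are the same data
                assert np.array_equal(c1.signals[sig], c2.signals[sig])
        # but two different runs of one day do differ (independent stride noise)
        (p, d, s, _), _ = next(iter(by_run.items()))
        r1 = by_run[(p, d, s, cfg.runs[0])][1]
        r3 = by_run[(p, d, s, cfg.runs[1])][1]
        assert not np.allclose(r1.signals["knee_flexion"], r3.signals["knee_flexion"])

    def test_ap_maxima_fall_on_true_boundaries(self, noise_free_config):
        recs, truth = synth.generate_cohort(noise_free_config)
        rec = recs[0]
        bounds = truth.boundaries[
            (rec.participant_id, rec.day, rec.surface, rec.run)
        ]
        idx = np.rint(bounds * rec.sample_rate).astype(int)
        ap = rec.signals["foot_ap_position"]
        assert np.allclose(ap[idx], noise_free_config.foot_ap_amplitude)
        interior = idx[1:-1]
        assert np.all(ap[interior] > ap[interior - 1])
        assert np.all(ap[interior] > ap[interior + 1])


class TestTruthIcc:
    def test_day_variance_example(self):
        cfg = _zero_noise(
            variance_components={
                "knee_flexion": LevelVariances(runner=4.0, day=1.0)
            }
        )
        assert synth.analytic_icc(cfg, "IKF", "between_day") == pytest.approx(0.8)
        assert synth.analytic_icc(cfg, "IKF", "within_day") == 1.0

    def test_equal_runner_and_day_variance_gives_half(self):
        cfg = _zero_noise(
            variance_components={"knee_flexion": LevelVariances(runner=2.0, day=2.0)}
        )
        assert synth.analytic_icc(cfg, "IKF", "between_day") == pytest.approx(0.5)

    def test_calibration_variance_example(self):
        cfg = _zero_noise(
            variance_components={
                "knee_flexion": LevelVariances(runner=9.0, calibration=1.0)
            }
        )
        assert synth.analytic_icc(cfg, "IKF", "calibration") == pytest.approx(0.9)
        # calibration pairs share stride data, so stride variance cancels too
        cfg2 = _zero_noise(
            variance_components={
                "knee_flexion": LevelVariances(runner=9.0, calibration=1.0, stride=50.0)
            }
        )
        assert synth.analytic_icc(cfg2, "IKF", "calibration") == pytest.approx(0.9)

    def test_all_error_variances_zero_gives_one(self):
        cfg = _zero_noise(variance_components=noise_free_variances())
        for kind in ("between_day", "within_day", "calibration"):
            assert synth.analytic_icc(cfg, "IKF", kind) == 1.0

    def test_unknown_variable_or_type_rejected(self, small_config):
        _, truth = synth.generate_cohort(small_config)
        with pytest.raises(KeyError):
            synth.truth_icc(truth, "NOPE", "between_day")
        with pytest.raises(KeyError):
            synth.truth_icc(truth, "IKF", "sideways")

    def test_truth_icc_in_unit_interval_for_defaults(self, small_config):
        _, truth = synth.generate_cohort(small_config)
        for var in list(synth._features.ANGLE_VARIABLES) + ["RS", "SF"]:
            for kind in ("between_day", "within_day", "calibration"):
                icc = synth.truth_icc(truth, var, kind)
                assert 0.0 <= icc <= 1.0


class TestVarianceRecovery:
    def test_runner_variance_recovered_over_many_runners(self):
        """Empirical variance of runner means converges to sigma2_runner (LLN)."""
        cfg = _zero_noise(
            n_participants=6000,
            n_days=1,
            surfaces=("asphalt",),
            runs=(1,),
            calibrations=(1,),
            variance_components={"knee_flexion": LevelVariances(runner=4.0)},
            seed=11,
        )
        table, _ = synth.simulate_feature_table(cfg)
        assert len(table) == 6000
        var = table["IKF"].var(ddof=1)
        assert abs(var - 4.0) / 4.0 < 0.05


class TestTemplates:
    def test_template_features_match_design_scale(self):
        tf = synth.template_features()
        assert tf["IKF"] == pytest.approx(7.53)
        assert tf["PKF"] == pytest.approx(42.53)
        assert tf["IHF"] == pytest.approx(34.77)
        assert tf["PHA"] == pytest.approx(-9.42, abs=0.01)
        assert tf["IAI"] == pytest.approx(-7.47)
        assert tf["PAE"] == pytest.approx(11.83)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_participants=0)
        with pytest.raises(ValueError):
            SimulationConfig(sample_rate=0.0)
        with pytest.raises(ValueError):
            LevelVariances(runner=-1.0)

    def test_fast_path_matches_analytic_offsets(self):
        """Feature-level simulation = template feature + summed level offsets."""
        cfg = _zero_noise(
            n_participants=3,
            n_days=2,
            surfaces=("asphalt",),
            variance_components={
                "knee_flexion": LevelVariances(runner=4.0, day=1.0, run=0.5, calibration=0.25)
            },
            seed=5,
        )
        table, truth = synth.simulate_feature_table(cfg)
        for _, row in table.iterrows():
            key = (row["participant"], row["day"], row["surface"], row["run"], row["calibration"])
            expected = truth.template_features["IKF"] + truth.level_offsets[key]["knee_flexion"]
            assert row["IKF"] == pytest.approx(expected, abs=1e-12)
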