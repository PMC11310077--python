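import numpy as np
import pytest

from paleodiv.chronology import (
    AgeDraw,
    CalibrationCurve,
    calibrate,
    filter_records,
    posterior_median,
    sample_age_models,
)
from paleodiv.errors import CalibrationRangeError
from paleodiv.pollen_io import ChronControl, PollenRecord, PollenSample
from paleodiv.synthetic_data import generate_defective_suite
from paleodiv import pollen_io


def _identity_curve(sigma=1e-3, hi=12000.0):
    cal = np.arange(0.0, hi, 2.0)
    return CalibrationCurve(cal, cal.copy(), np.full_like(cal, sigma))


def _record(sample_depths, controls, grains=400):
    samples = [
        PollenSample(depth=float(d), counts={"a": grains}, total_terrestrial=grains)
        for d in sample_depths
    ]
    return PollenRecord("r", 10.0, 10.0, samples, list(controls))


class TestCalibrate:
    def test_identity_curve_transports_normal(self):
        curve = _identity_curve()
        c = ChronControl(depth=10, age=5000, error=50, kind="radiocarbon")
        grid, dens = calibrate(c, curve)
        mu = float((grid * dens).sum())
        sd = float(np.sqrt(((grid - mu) ** 2 * dens).sum()))
        assert abs(mu - 5000) < 1.0
        assert abs(sd - 50) < 1.0

    def test_calendar_control_ignores_curve(self):
        curve = _identity_curve()
        c = ChronControl(depth=10, age=5000, error=20, kind="calendar")
        grid, dens = calibrate(c, curve)
        mu = float((grid * dens).sum())
        sd = float(np.sqrt(((grid - mu) ** 2 * dens).sum()))
        assert abs(mu - 5000) < 0.5
        assert abs(sd - 20) < 0.5

    def test_slope_two_halves_posterior_sd(self):
        # delta method: cal sd = lab error / |curve slope|
        cal = np.arange(0.0, 10000.0, 1.0)
        curve = CalibrationCurve(cal, 2 * cal, np.full_like(cal, 1e-3))
        c = ChronControl(depth=10, age=8000, error=40, kind="radiocarbon")
        grid, dens = calibrate(c, curve)
        mu = float((grid * dens).sum())
        sd = float(np.sqrt(((grid - mu) ** 2 * dens).sum()))
        assert abs(sd - 20.0) < 1.0

    def test_density_sums_to_one(self):
        curve = _identity_curve(sigma=15.0)
        c = ChronControl(depth=5, age=3000, error=60, kind="radiocarbon")
        _, dens = calibrate(c, curve)
        assert abs(dens.sum() - 1.0) < 1e-9

    def test_age_outside_curve_support(self):
        curve = _identity_curve(hi=2000.0)
        c = ChronControl(depth=5, age=50_000, error=60, kind="radiocarbon")
        with pytest.raises(CalibrationRangeError):
            calibrate(c, curve)


class TestSampleAgeModels:
    def test_exact_controls_give_linear_interpolation(self):
        rec = _record(
            [10, 55, 100],
            [
                ChronControl(10, 1000, 0, "calendar"),
                ChronControl(100, 9000, 0, "calendar"),
            ],
        )
        draws = sample_age_models(rec, None, 10, seed=0)
        for d in draws:
            assert np.allclose(d.ages, [1000.0, 5000.0, 9000.0])

    def test_far_extrapolation_is_age_undefined(self):
        # bottom sample extrapolates ~4,000 yr beyond the oldest control
        rec = _record(
            [10, 50, 100],
            [
                ChronControl(10, 1000, 0, "calendar"),
                ChronControl(50, 5000, 0, "calendar"),
            ],
        )
        draws = sample_age_models(rec, None, 3, seed=0)
        for d in draws:
            assert np.isnan(d.ages[2])
            assert np.allclose(d.ages[:2], [1000.0, 5000.0])

    def test_all_draws_monotone(self, small_world, filtered_records):
        for rec in filtered_records[:4]:
            curve = small_world.curves["north" if rec.lat >= 0 else "south"]
            for d in sample_age_models(rec, curve, 25, seed=3):
                finite = d.ages[np.isfinite(d.ages)]
                assert np.all(np.diff(finite) >= -1e-9)

    def test_wide_error_sd_matches_rejection_oracle(self):
        controls = [
            ChronControl(10, 3000, 250, "calendar"),
            ChronControl(100, 3500, 250, "calendar"),
        ]
        rec = _record([10, 100], controls)
        draws = sample_age_models(rec, None, 4000, seed=5)
        ages = np.array([d.ages for d in draws])

        rng = np.random.default_rng(17)
        acc = []
        while len(acc) < 4000:
            a = rng.normal(3000, 250, 2000)
            b = rng.normal(3500, 250, 2000)
            ok = b >= a
            acc.extend(np.column_stack([a[ok], b[ok]]))
        oracle = np.array(acc[:4000])
        for j in range(2):
            assert abs(ages[:, j].std() / oracle[:, j].std() - 1) < 0.08


class TestFilterRecords:
    def _calendar_controls(self, pairs):
        return [ChronControl(d, a, 1.0, "calendar") for d, a in pairs]

    def test_two_controls_rejected(self):
        rec = _record(
            range(10, 70, 10),
            self._calendar_controls([(10, 1000), (60, 8000)]),
        )
        kept, reports = filter_records([rec])
        assert not kept
        assert reports[0].reason == "too-few-controls"

    def test_control_gap_rejected(self):
        rec = _record(
            range(10, 70, 10),
            self._calendar_controls([(10, 1000), (30, 5500), (60, 9000)]),
        )
        kept, reports = filter_records([rec])
        assert not kept
        assert reports[0].reason == "control-gap"

    def test_compliant_record_kept(self):
        rec = _record(
            range(10, 70, 10),
            self._calendar_controls([(10, 4000), (30, 6000), (60, 8000)]),
        )
        kept, reports = filter_records([rec])
        assert len(kept) == 1
        assert reports[0].kept

    def test_too_few_samples(self):
        rec = _record(
            [10, 30, 50, 60],
            self._calendar_controls([(10, 4000), (30, 6000), (60, 8000)]),
        )
        kept, reports = filter_records([rec])
        assert not kept
        assert reports[0].reason == "too-few-samples"

    def test_low_count_samples(self):
        samples = [
            PollenSample(
                depth=float(d),
                counts={"a": 400 if d != 30 else 250},
                total_terrestrial=400 if d != 30 else 250,
            )
            for d in range(10, 70, 10)
        ]
        # 6 samples, one below 300 grains, but only 4 others in... all 6 in
        samples = samples[:5]
        rec = PollenRecord(
            "r", 10.0, 10.0, samples,
            self._calendar_controls([(10, 4000), (30, 6000), (50, 8000)]),
        )
        kept, reports = filter_records([rec])
        assert not kept
        assert reports[0].reason == "low-count-samples"

    def test_best_section_has_most_controls(self):
        # two qualifying runs split by a 4,000-yr gap; second has more controls
        ctrl = self._calendar_controls(
            [(10, 500), (20, 1500), (30, 2500),
             (50, 6500), (60, 7500), (70, 8500), (80, 9500)]
        )
        rec = _record(range(10, 90, 5), ctrl)
        kept, reports = filter_records([rec])
        assert len(kept) == 1
        assert len(kept[0].controls) == 4
        assert min(c.age for c in kept[0].controls) == 6500

    def test_idempotent_on_own_output(self, small_world):
        recs = pollen_io.apply_harmonization(
            small_world.records, small_world.harmonization
        )
        kept, _ = filter_records(recs, small_world.curves)
        kept2, reports2 = filter_records(kept, small_world.curves)
        assert len(kept2) == len(kept)
        assert all(r.kept for r in reports2)
        for a, b in zip(kept, kept2):
            assert len(a.samples) == len(b.samples)
            assert len(a.controls) == len(b.controls)

    def test_every_record_reported_once(self, small_world):
        recs = pollen_io.apply_harmonization(
            small_world.records, small_world.harmonization
        )
        _, reports = filter_records(recs, small_world.curves)
        assert sorted(r.record_id for r in reports) == sorted(
            r.record_id for r in recs
        )


class TestDefectiveSuite:
    def test_each_defect_matches_reason(self):
        suite = generate_defective_suite(seed=4)
        for kind in ("too-few-controls", "control-gap", "too-few-samples",
                     "low-count-samples"):
            kept, reports = filter_records([suite[kind]])
            assert not kept, kind
            assert reports[0].reason == kind
        kept, reports = filter_records([suite["compliant"]])
        assert len(kept) == 1 and reports[0].kept
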