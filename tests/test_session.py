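"""Session state: unit normalization, pairing, trends, advisories."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmpkit import (
    AdvisoryThresholds,
    Analyte,
    BloodGasSample,
    DonorProfile,
    DuplicateSampleError,
    PerfusionSession,
    PerfusionSettings,
    SampleSite,
    Sex,
    TrendDirection,
    UnitHints,
    advise_electrolytes,
    compute_snapshot,
    normalize_units,
)
from pmpkit.session import HB_GDL_PER_MMOL


def _session(**kwargs) -> PerfusionSession:
    donor = DonorProfile(sex=Sex.male, body_weight=80.0)
    return PerfusionSession(donor=donor, **kwargs)


def _sample(time, site, po2=350.0, so2=0.98, hb=9.0, **kwargs) -> dict:
    return dict(time=time, site=site, po2=po2, so2=so2, hb=hb, **kwargs)


class TestUnitNormalization:
    def test_hb_mmol_to_g_dl(self):
        out = normalize_units({"hb": 5.6}, UnitHints(hb_unit="mmol_l"))
        assert out["hb"] == pytest.approx(9.023, abs=0.001)

    def test_percent_saturation_autodetected(self):
        assert normalize_units({"so2": 98})["so2"] == pytest.approx(0.98)

    def test_fraction_left_alone(self):
        assert normalize_units({"so2": 0.98})["so2"] == pytest.approx(0.98)

    @given(hb=st.floats(min_value=0.1, max_value=15), pct=st.floats(min_value=5.0, max_value=100))
    def test_unit_round_trips_are_identity(self, hb, pct):
        there = normalize_units({"hb": hb}, UnitHints(hb_unit="mmol_l"))["hb"]
        assert math.isclose(there / HB_GDL_PER_MMOL, hb, rel_tol=1e-12)
        frac = normalize_units({"so2": pct}, UnitHints(so2_unit="percent"))["so2"]
        assert math.isclose(frac * 100.0, pct, rel_tol=1e-12)

    def test_ambiguous_saturation_rejected(self):
        from pmpkit import InputError

        with pytest.raises(InputError):
            normalize_units({"so2": 1.2})


class TestPairingAndSnapshots:
    def test_pair_within_tolerance_creates_midpoint_snapshot(self):
        session = _session()
        assert session.ingest_sample(_sample(60.0, "arterial")) is None
        snap = session.ingest_sample(_sample(62.0, "venous", so2=0.5, po2=120.0))
        assert snap is not None
        assert snap.time == pytest.approx(61.0)
        assert len(session.snapshots) == 1

    def test_samples_outside_tolerance_stay_unpaired(self):
        session = _session()
        session.ingest_sample(_sample(60.0, "arterial"))
        assert session.ingest_sample(_sample(70.0, "venous", so2=0.5)) is None
        assert session.snapshots == []

    def test_duplicate_time_site_rejected(self):
        session = _session()
        session.ingest_sample(_sample(60.0, "arterial"))
        with pytest.raises(DuplicateSampleError):
            session.ingest_sample(_sample(60.0, "arterial"))

    def test_snapshot_metrics_from_known_pair(self, settings_700):
        arterial = BloodGasSample(**_sample(60.0, "arterial", hb=9.0, so2=1.0, po2=350.0))
        venous = BloodGasSample(**_sample(60.0, "venous", hb=9.0, so2=0.48, po2=120.0))
        snap = compute_snapshot(arterial, venous, settings_700, _session().params)
        assert snap.cao2 == pytest.approx(13.145, abs=1e-9)
        assert snap.cvo2 == pytest.approx(6.1608, abs=1e-9)
        assert snap.mvo2 == pytest.approx(48.8894, abs=1e-3)
        assert snap.delta_po2 == pytest.approx(230.0)
        assert snap.cvr == pytest.approx(75.0 / 700.0, abs=1e-4)
        assert snap.meo2 == pytest.approx(snap.mvo2 / snap.mdo2, rel=1e-12)

    def test_identical_samples_give_zero_extraction(self, settings_700):
        arterial = BloodGasSample(**_sample(60.0, "arterial"))
        venous = BloodGasSample(**_sample(60.0, "venous"))
        snap = compute_snapshot(arterial, venous, settings_700, _session().params)
        assert snap.mvo2 == 0.0
        assert snap.meo2 == 0.0
        assert snap.delta_po2 == 0.0

    def test_negative_extraction_flagged_not_clipped(self, settings_700):
        arterial = BloodGasSample(**_sample(60.0, "arterial", so2=0.48, po2=120.0))
        venous = BloodGasSample(**_sample(60.0, "venous", so2=0.98, po2=350.0))
        snap = compute_snapshot(arterial, venous, settings_700, _session().params)
        assert "negative_extraction" in snap.flags
        assert snap.mvo2 < 0

    def test_snapshot_uses_active_pump_setting(self):
        session = _session()
        session.record_settings(0.0, PerfusionSettings(cbf_setting=700.0))
        session.record_settings(100.0, PerfusionSettings(cbf_setting=600.0))
        session.ingest_sample(_sample(60.0, "arterial"))
        snap = session.ingest_sample(_sample(60.0, "venous", so2=0.5))
        assert snap.cbf_setting == 700.0
        session.ingest_sample(_sample(120.0, "arterial"))
        snap2 = session.ingest_sample(_sample(120.0, "venous", so2=0.5))
        assert snap2.cbf_setting == 600.0

    def test_pairing_totality_alternating_cadence(self):
        session = _session()
        for t in range(0, 120, 12):
            session.ingest_sample(_sample(float(t), "arterial"))
            session.ingest_sample(_sample(float(t) + 2.0, "venous", so2=0.5))
        assert len(session.snapshots) == 10
        assert len(session.pairs) == 10

    def test_snapshot_conservation_identity(self):
        session = _session()
        for t in range(0, 120, 12):
            session.ingest_sample(_sample(float(t), "arterial"))
            session.ingest_sample(_sample(float(t), "venous", so2=0.5, po2=100.0))
        for snap in session.snapshots:
            residual = snap.mdo2 - snap.mvo2 - snap.cbf_setting * snap.cvo2 / 100.0
            assert abs(residual) <= 1e-9 * max(1.0, snap.mdo2)


class TestLactateTrend:
    def _with_lactate(self, values, spacing_min=60.0):
        session = _session()
        for i, lac in enumerate(values):
            session.ingest_sample(_sample(i * spacing_min, "arterial", lactate=lac))
        return session

    def test_falling(self):
        trend = self._with_lactate([3.0, 2.5, 2.0]).lactate_trend()
        assert trend.direction is TrendDirection.falling
        assert trend.slope_per_hour == pytest.approx(-0.5)

    def test_stable(self):
        trend = self._with_lactate([2.0, 2.0, 2.0]).lactate_trend()
        assert trend.direction is TrendDirection.stable

    def test_rising_least_squares(self):
        trend = self._with_lactate([2.0, 4.0, 6.0, 8.0]).lactate_trend()
        assert trend.direction is TrendDirection.rising
        assert trend.slope_per_hour == pytest.approx(2.0)

    def test_direction_absent_below_three_points(self):
        trend = self._with_lactate([2.0, 3.0]).lactate_trend()
        assert trend.direction is None


class TestAdvisories:
    def test_all_in_range_is_quiet(self):
        sample = BloodGasSample(**_sample(0.0, "arterial", ionized_ca=1.25, hco3=24.0, k=4.2))
        assert advise_electrolytes(sample) == []

    def test_low_calcium(self):
        sample = BloodGasSample(**_sample(0.0, "arterial", ionized_ca=0.9))
        items = advise_electrolytes(sample)
        assert [i.analyte for i in items] == [Analyte.ionized_calcium]
        assert items[0].threshold_low == 1.1

    def test_low_bicarbonate(self):
        sample = BloodGasSample(**_sample(0.0, "arterial", hco3=18.0))
        items = advise_electrolytes(sample)
        assert [i.analyte for i in items] == [Analyte.bicarbonate]

    def test_acidotic_ph_triggers_bicarbonate_advice(self):
        sample = BloodGasSample(**_sample(0.0, "arterial", hco3=22.0, ph=7.25))
        assert [i.analyte for i in advise_electrolytes(sample)] == [Analyte.bicarbonate]

    def test_potassium_band(self):
        low = BloodGasSample(**_sample(0.0, "arterial", k=3.0))
        high = BloodGasSample(**_sample(0.0, "arterial", k=6.0))
        assert [i.analyte for i in advise_electrolytes(low)] == [Analyte.potassium]
        assert advise_electrolytes(high)[0].threshold_high == 5.5

    def test_custom_thresholds(self):
        sample = BloodGasSample(**_sample(0.0, "arterial", ionized_ca=1.15))
        strict = AdvisoryThresholds(ionized_ca_low=1.2)
        assert len(advise_electrolytes(sample, strict)) == 1
        assert advise_electrolytes(sample) == []


class TestSerialization:
    def _populated(self):
        session = _session()
        session.record_settings(0.0, PerfusionSettings(cbf_setting=700.0))
        for t in (0.0, 30.0, 60.0):
            session.ingest_sample(_sample(t, "arterial", lactate=2.0, ionized_ca=0.9))
            session.ingest_sample(_sample(t, "venous", so2=0.5, po2=110.0))
        return session

    def test_json_round_trip_is_bit_stable(self):
        session = self._populated()
        text = session.to_json()
        restored = PerfusionSession.from_json(text)
        assert restored.to_json() == text
        assert len(restored.snapshots) == 3
        assert len(restored.recommendations) == 3

    def test_reingestion_is_idempotent(self):
        session = self._populated()
        text = session.to_json()
        for t in (0.0, 30.0, 60.0):
            with pytest.raises(DuplicateSampleError):
                session.ingest_sample(_sample(t, "arterial", lactate=2.0, ionized_ca=0.9))
        assert session.to_json() == text

    def test_same_log_fresh_session_identical_state(self):
        assert self._populated().to_json() == self._populated().to_json()
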