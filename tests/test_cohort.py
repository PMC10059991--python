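"""Cohort generation, splitting, CSV round-trips and the XML reader."""

import numpy as np
import pytest

import glucofed as gf
from glucofed.cohort import GLUCOSE_MAX, GLUCOSE_MIN
from glucofed.series import EventRecord, PatientSeries
from glucofed.windows import preprocess_series


class TestSeriesTypes:
    def test_event_validation(self):
        with pytest.raises(ValueError):
            EventRecord(0, "snack", 1.0)
        with pytest.raises(ValueError):
            EventRecord(-5, "meal", 1.0)
        with pytest.raises(ValueError):
            EventRecord(0, "glucose", -1.0)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            PatientSeries("p", 5, [0, 0, 5], [5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="multiples"):
            PatientSeries("p", 5, [0, 3], [5.0, 5.0])
        with pytest.raises(ValueError, match="span"):
            PatientSeries("p", 5, [0, 5], [5.0, 5.0],
                          meal_events=[EventRecord(500, "meal", 10.0)])

    def test_split_ordering_enforced(self):
        with pytest.raises(ValueError, match="precede"):
            PatientSeries("p", 5, [0, 5, 10], [5.0] * 3,
                          split=np.array(["test", "train", "train"], dtype=object))


class TestAssignSplit:
    def test_fraction(self):
        s = PatientSeries("p", 5, np.arange(100) * 5, np.full(100, 6.0))
        out = gf.assign_split(s, 0.2)
        assert (out.split == "test").sum() == 20
        assert (out.split[:80] == "train").all()

    def test_odd_count_floors_train(self):
        s = PatientSeries("p", 5, np.arange(101) * 5, np.full(101, 6.0))
        out = gf.assign_split(s, 0.5)
        assert (out.split == "train").sum() == 50
        assert (out.split == "test").sum() == 51

    def test_fraction_bounds(self):
        s = PatientSeries("p", 5, np.arange(10) * 5, np.full(10, 6.0))
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                gf.assign_split(s, bad)


class TestSimulation:
    def test_deterministic(self, small_cohort_config):
        a = gf.simulate_patient(small_cohort_config, 1)
        b = gf.simulate_patient(small_cohort_config, 1)
        assert a == b

    def test_constant_without_inputs(self):
        """With no meals, no insulin and no noise, basal glucose is a fixed
        point of the update."""
        cfg = gf.CohortConfig(n_patients=1, days=1.0, seed=0, meal_rate=0.0,
                              basal_rate=0.0, noise_sd=0.0, missing_rate=0.0,
                              basal_glucose=(7.0, 7.0))
        s = gf.simulate_patient(cfg, 0)
        assert np.allclose(s.glucose, 7.0)

    def test_meal_rise_matches_step_oracle(self):
        """One 50 g meal, no insulin, no mean reversion, no noise: the
        cumulative glucose rise equals alpha * sum(C), and the whole
        trajectory matches an independent step-by-step recomputation."""
        from glucofed.absorption import AbsorptionParams, carb_signal
        from glucofed.cohort import integrate_glucose

        grid = np.arange(0, 24 * 60, 5, dtype=np.int64)
        c = carb_signal([EventRecord(120, "meal", 50.0)],
                        AbsorptionParams(), grid)
        zeros = np.zeros(len(grid))
        g = integrate_glucose(6.0, c, zeros, alpha=0.4, beta=0.0, gamma=0.0,
                              g_basal=6.0, noise=zeros)
        # independent oracle: plain running sum (no clipping active here)
        expect = 6.0 + 0.4 * np.concatenate([[0.0], np.cumsum(c[:-1])])
        assert np.allclose(g, expect)
        assert g[-1] - g[0] == pytest.approx(0.4 * c[:-1].sum())

    def test_range_and_grid_invariants(self, small_cohort_config):
        for i in range(small_cohort_config.n_patients):
            s = gf.simulate_patient(small_cohort_config, i)
            vals = s.glucose[np.isfinite(s.glucose)]
            assert vals.min() >= GLUCOSE_MIN and vals.max() <= GLUCOSE_MAX
            assert np.all(s.t % s.delta_t == 0)

    def test_missingness_applied(self):
        cfg = gf.CohortConfig(n_patients=1, days=2.0, seed=1, missing_rate=0.2)
        s = gf.simulate_patient(cfg, 0)
        frac = np.isnan(s.glucose).mean()
        assert 0.1 < frac < 0.3

    def test_default_cohort_imbalance(self):
        """Hypoglycemic classes are a small minority, as in real CGM
        cohorts (fixed seed)."""
        cfg = gf.CohortConfig(n_patients=6, days=7.0, seed=0)
        counts = np.zeros(7)
        for i in range(cfg.n_patients):
            sam = preprocess_series(gf.simulate_patient(cfg, i))
            vc = sam["target_class"].value_counts()
            counts[vc.index] += vc.values
        assert counts[:2].sum() / counts.sum() < 0.10

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            gf.CohortConfig(n_patients=0)
        with pytest.raises(ValueError):
            gf.CohortConfig(missing_rate=1.2)
        with pytest.raises(ValueError):
            gf.CohortConfig(alpha=(np.inf, np.inf))


class TestCsvRoundTrip:
    def test_simulated_series(self, tmp_path, small_cohort_config):
        s = gf.assign_split(gf.simulate_patient(small_cohort_config, 0), 0.25)
        path = tmp_path / "p.csv"
        gf.write_csv(s, path)
        assert gf.read_csv(path) == s

    def test_empty_events_and_missing_markers(self, tmp_path):
        g = np.array([5.0, np.nan, 6.0, np.nan, 7.0, np.nan])
        s = PatientSeries("x", 5, np.arange(6) * 5, g)
        path = tmp_path / "x.csv"
        gf.write_csv(s, path)
        back = gf.read_csv(path)
        assert back == s
        assert np.isnan(back.glucose).sum() == 3

    def test_schema_mismatch(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(ValueError):
            gf.read_csv(path)


OHIO_XML = """
<patient id="p559">
  <training>
    <glucose_level>
      <event ts="0" value="90"/>
      <event ts="5" value="108"/>
      <event ts="10" value="126"/>
    </glucose_level>
    <bolus><event ts="5" value="2000"/></bolus>
    <basal><event ts="0" value="0.03"/></basal>
    <meal><event ts="10" value="45"/></meal>
  </training>
  <testing>
    <glucose_level>
      <event ts="15" value="180"/>
    </glucose_level>
  </testing>
</patient>
"""


class TestOhioXml:
    def test_reads_fixture(self, tmp_path):
        path = tmp_path / "p.xml"
        path.write_text(OHIO_XML)
        s = gf.read_ohio_xml(path)
        assert s.patient_id == "p559"
        assert s.n_points == 4
        # mg/dL converted on ingest: 90 -> 5.0 mmol/L
        assert s.glucose[0] == pytest.approx(5.0)
        assert s.glucose[3] == pytest.approx(10.0)
        boluses = [e for e in s.insulin_events if e.kind == "bolus"]
        assert len(boluses) == 1 and boluses[0].value == 2000
        assert len(s.meal_events) == 1
        # split taken from the file's own partition
        assert list(s.split) == ["train"] * 3 + ["test"]

    def test_unit_override(self, tmp_path):
        path = tmp_path / "p.xml"
        path.write_text(OHIO_XML)
        s = gf.read_ohio_xml(path, glucose_unit="mmol/L")
        assert s.glucose[0] == 90.0
        with pytest.raises(ValueError):
            gf.read_ohio_xml(path, glucose_unit="furlongs")

    def test_malformed_xml(self, tmp_path):
        path = tmp_path / "broken.xml"
        path.write_text("<patient><glucose_level><event ts='0'")
        with pytest.raises(ValueError, match="malformed"):
            gf.read_ohio_xml(path)

    def test_missing_attributes(self, tmp_path):
        path = tmp_path / "noval.xml"
        path.write_text("<patient><glucose_level><event ts='0'/>"
                        "</glucose_level></patient>")
        with pytest.raises(ValueError, match="glucose_level"):
            gf.read_ohio_xml(path)
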