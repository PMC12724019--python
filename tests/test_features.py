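"""Event morphology: multitaper power maps, peak extraction, spectral
entropy, and electrode-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfamark.features import (
    TfMap,
    aggregate_electrode,
    cohort_feature_table,
    electrode_feature_table,
    event_feature_table,
    max_power_and_peak_freq,
    multitaper_tf,
    normalized_entropy,
    training_table,
)
from hfamark.simulate import SimulationConfig, sample_feature_cohort

FS = 1000.0


class TestMultitaper:
    def test_sinusoid_peaks_in_its_bin(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 140 * t)
        tf = multitaper_tf(x, 900, 1100, FS)
        power, freq = max_power_and_peak_freq(tf)
        assert abs(freq - 140) <= 2.5  # within the 5-Hz bin containing 140
        assert power > 0

    def test_zero_signal_zero_map(self):
        tf = multitaper_tf(np.zeros(2000), 500, 600, FS)
        assert np.allclose(tf.power, 0.0)
        assert (tf.power >= 0).all()

    def test_quadratic_amplitude_scaling(self):
        t = np.arange(0, 2, 1 / FS)
        x = np.sin(2 * np.pi * 200 * t)
        p1 = multitaper_tf(x, 800, 900, FS).power
        p2 = multitaper_tf(2 * x, 800, 900, FS).power
        assert np.allclose(p2, 4 * p1, rtol=1e-9)

    def test_frequency_grid_is_85_five_hz_bins(self):
        tf = multitaper_tf(np.zeros(3000), 1000, 1050, FS)
        assert tf.freqs.size == 85
        assert np.allclose(np.diff(tf.freqs), 5.0)
        assert tf.freqs[0] == 80.0 and tf.freqs[-1] == 500.0

    def test_bounds_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            multitaper_tf(np.zeros(100), 50, 200, FS)


class TestPeakExtraction:
    def test_single_nonzero_cell(self):
        power = np.zeros((3, 4))
        power[1, 2] = 9.0
        tf = TfMap(power=power, freqs=np.array([100.0, 102.5, 105.0]), times=np.arange(4), window_ms=200)
        assert max_power_and_peak_freq(tf) == (9.0, 102.5)

    def test_tie_broken_toward_lower_frequency(self):
        power = np.zeros((3, 2))
        power[0, 1] = power[2, 0] = 5.0
        tf = TfMap(power=power, freqs=np.array([100.0, 175.0, 250.0]), times=np.arange(2), window_ms=200)
        assert max_power_and_peak_freq(tf)[1] == 100.0

    def test_empty_bounds_rejected(self):
        tf = TfMap(power=np.ones((2, 3)), freqs=np.array([100.0, 105.0]), times=np.arange(3), window_ms=200)
        with pytest.raises(ValueError):
            max_power_and_peak_freq(tf, bounds=(10, 12))


class TestEntropy:
    def test_uniform_spectrum_is_one(self):
        for n in (2, 10, 85):
            assert normalized_entropy(np.full(n, 1.0 / n)) == pytest.approx(1.0, abs=1e-6)

    def test_single_bin_is_zero(self):
        spec = np.zeros(85)
        spec[17] = 3.0
        assert normalized_entropy(spec) == pytest.approx(0.0, abs=1e-6)

    def test_two_bin_example(self):
        assert normalized_entropy([0.75, 0.25]) == pytest.approx(0.8113, abs=1e-4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=85)
    )
    def test_bounds_hold_for_any_spectrum(self, spectrum):
        spectrum = np.asarray(spectrum)
        if spectrum.sum() == 0:
            with pytest.warns(RuntimeWarning):
                assert np.isnan(normalized_entropy(spectrum))
        else:
            assert 0.0 <= normalized_entropy(spectrum) <= 1.0

    def test_all_zero_flagged(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(normalized_entropy(np.zeros(10)))


class TestAggregation:
    def test_rate_from_count_and_epoch(self):
        ev = pd.DataFrame(
            {"duration_ms": np.full(10, 20.0), "max_power_uv2": 1.0, "peak_freq_hz": 100.0, "entropy": 0.5}
        )
        assert aggregate_electrode(ev, 20.0)["rate"] == pytest.approx(0.5)

    def test_zero_events_missing_morphology(self):
        row = aggregate_electrode(pd.DataFrame(columns=["duration_ms", "max_power_uv2", "peak_freq_hz", "entropy"]), 5.0)
        assert row["rate"] == 0.0
        assert np.isnan(row["duration"]) and np.isnan(row["entropy"])

    def test_median_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        durations = rng.uniform(5, 100, 31)
        ev = pd.DataFrame(
            {"duration_ms": durations, "max_power_uv2": 1.0, "peak_freq_hz": 100.0, "entropy": 0.5}
        )
        assert aggregate_electrode(ev, 5.0)["duration"] == pytest.approx(np.sort(durations)[15])

    def test_invalid_epoch(self):
        with pytest.raises(ValueError):
            aggregate_electrode(pd.DataFrame(), 0.0)


def _toy_patient(n_soz=4, n_ne=20, n_spk=3):
    rows = []
    for i in range(n_soz + n_ne + n_spk):
        group = "soz" if i < n_soz else ("spiking" if i >= n_soz + n_ne else "ne")
        rows.append(
            {
                "name": f"G{i + 1:02d}",
                "kind": "subdural",
                "shaft_id": "",
                "contact_index": -1,
                "hemisphere": "L",
                "region": "L_frontal",
                "soz": group == "soz",
                "spiking": group == "spiking",
                "resected": False,
                "excluded": False,
            }
        )
    return pd.DataFrame(rows)


class TestFeatureTables:
    def test_training_row_filter_counts(self):
        elec = _toy_patient()
        events = pd.DataFrame(columns=["patient", "channel", "detector", "duration_ms", "max_power_uv2", "peak_freq_hz", "entropy"])
        table = electrode_feature_table(events, elec, elec, 5.0, age=10.0, patient="p1", detector="STE")
        assert len(table) == 27
        assert len(training_table(table)) == 24  # 4 SOZ + 20 non-epileptic

    def test_empty_event_set_emits_zero_rate_rows(self):
        elec = _toy_patient()
        events = pd.DataFrame(columns=["patient", "channel", "detector", "duration_ms", "max_power_uv2", "peak_freq_hz", "entropy"])
        table = electrode_feature_table(events, elec, elec, 5.0, age=8.0, patient="p1", detector="HIL")
        assert (table["rate"] == 0).all()
        assert table["duration"].isna().all()

    def test_unknown_channel_named_in_error(self):
        elec = _toy_patient(1, 2, 0)
        events = pd.DataFrame(
            [{"patient": "p1", "channel": "GHOST", "detector": "STE",
              "duration_ms": 20.0, "max_power_uv2": 1.0, "peak_freq_hz": 100.0, "entropy": 0.5}]
        )
        with pytest.raises(ValueError, match="GHOST"):
            electrode_feature_table(events, elec, elec, 5.0, 10.0, "p1", "STE")

    def test_per_detector_tables_kept_separate(self):
        elec = _toy_patient(1, 3, 0)
        events = pd.DataFrame(
            [
                {"patient": "p1", "channel": "G01", "detector": d,
                 "duration_ms": 20.0, "max_power_uv2": 1.0, "peak_freq_hz": 100.0, "entropy": 0.5}
                for d in ("STE", "MNI")
            ]
        )
        meta = {"p1": {"montaged": elec, "electrodes": elec, "age": 12.0}}
        tables = cohort_feature_table(events, meta, 5.0)
        assert set(tables) == {"STE", "MNI"}
        assert all((t["detector"] == d).all() for d, t in tables.items())

    def test_table1_style_rate_ordering_reproduced(self):
        features, _ = sample_feature_cohort(SimulationConfig(n_patients=15, seed=51))
        med = features.groupby(["patient", "site_group"])["rate"].median().unstack()
        med = med.dropna(subset=["soz", "non_epileptic"])
        assert (med["soz"] > med["non_epileptic"]).mean() > 0.9


def test_event_feature_table_power_and_rate_invariances():
    """Power scales with amplitude but not event count; rate counts events
    but ignores amplitude."""
    t = np.arange(0, 10, 1 / FS)
    base = np.sin(2 * np.pi * 150 * t)
    one = event_feature_table(base, [(2000, 2060)], FS)
    two = event_feature_table(base, [(2000, 2060), (5000, 5060)], FS)
    loud = event_feature_table(3 * base, [(2000, 2060)], FS)
    assert one["max_power_uv2"].iloc[0] == pytest.approx(two["max_power_uv2"].iloc[0])
    assert loud["max_power_uv2"].iloc[0] == pytest.approx(9 * one["max_power_uv2"].iloc[0], rel=1e-6)
    assert len(two) == 2
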