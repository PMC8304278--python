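"""Determinism, calibration and ground-truth closure of the generator."""

import numpy as np
import pytest

from polyphos.peakdetect import detect_peaks
from polyphos.species_db import get_species, species_mass_from_p2o5
from polyphos.synthgen import (
    SHMP_ENVELOPE_RTS,
    SyntheticSpec,
    generate_calibration_series,
    generate_hrms_scanset,
    generate_scd_trace,
    generate_validation_batch,
    window_signal,
)


class TestSpec:
    def test_rejects_negative_spikes(self):
        with pytest.raises(ValueError):
            SyntheticSpec(spikes={"pyrophosphate": -1.0})
        with pytest.raises(ValueError):
            SyntheticSpec(shmp_spike=-5.0)

    def test_rejects_unknown_matrix(self):
        with pytest.raises(ValueError):
            SyntheticSpec(matrix="cereal")


class TestScdTrace:
    def test_deterministic_per_seed(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 50.0}, seed=3)
        t1, _ = generate_scd_trace(spec)
        t2, _ = generate_scd_trace(spec)
        np.testing.assert_array_equal(t1.intensities, t2.intensities)
        t3, _ = generate_scd_trace(SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 50.0}, seed=4))
        assert not np.array_equal(t1.intensities, t3.intensities)

    def test_blank_shows_only_natural_ortho(self):
        tr, truth = generate_scd_trace(SyntheticSpec(matrix="dairy", seed=1))
        assert [c["name"] for c in truth["peaks"]] == ["orthophosphate"]
        peaks = detect_peaks(tr, min_snr=3)
        assert len(peaks) == 1 and peaks[0].apex_time == pytest.approx(5.9, abs=0.05)

    def test_interferent_peak_at_6p95(self):
        tr, truth = generate_scd_trace(SyntheticSpec(matrix="dairy", interferent=True, seed=2))
        assert any(c["name"] == "interferent" and c["rt"] == 6.95 for c in truth["peaks"])
        peaks = detect_peaks(tr, min_snr=3)
        assert any(abs(p.apex_time - 6.95) < 0.05 for p in peaks)

    def test_doubling_spike_doubles_area_noise_free(self):
        base = dict(matrix="blank", natural_ortho=0.0, baseline_sd=0.0,
                    proportional_sd=0.0, drift_slope=0.0, seed=0)
        t1, _ = generate_scd_trace(SyntheticSpec(spikes={"triphosphate": 40.0}, **base))
        t2, _ = generate_scd_trace(SyntheticSpec(spikes={"triphosphate": 80.0}, **base))
        a1 = detect_peaks(t1)[0].area
        a2 = detect_peaks(t2)[0].area
        assert a2 == pytest.approx(2 * a1, rel=1e-3)

    def test_shmp_envelope_all_peaks_above_cutoff(self):
        tr, truth = generate_scd_trace(SyntheticSpec(matrix="dairy", shmp_spike=200.0, seed=5))
        env = [c for c in truth["peaks"] if c["name"].startswith("shmp_")]
        assert len(env) == 10
        assert all(c["snr_true"] >= 3 for c in env)
        peaks = detect_peaks(tr, min_snr=3)
        for rt in SHMP_ENVELOPE_RTS:
            assert any(abs(p.apex_time - rt) < 0.05 for p in peaks), rt


class TestHrmsScanset:
    def test_deterministic_per_seed(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 30.0},
                             hrms_time_range=(8.0, 10.0), seed=6)
        s1, _ = generate_hrms_scanset(spec)
        s2, _ = generate_hrms_scanset(spec)
        assert len(s1.scans) == len(s2.scans)
        for a, b in zip(s1.scans, s2.scans):
            np.testing.assert_array_equal(a.mz_values, b.mz_values)
            np.testing.assert_array_equal(a.intensity_values, b.intensity_values)

    def test_pyro_centroids_peak_at_9(self):
        spec = SyntheticSpec(matrix="blank", natural_ortho=0.0, internal_standard_amount=0.0,
                             spikes={"pyrophosphate": 30.0}, hrms_time_range=(7.0, 11.0), seed=7)
        ss, _ = generate_hrms_scanset(spec)
        target = get_species("pyrophosphate").computed_precursor_mz()
        best_t, best_i = None, 0.0
        for s in ss.of_mode("FS"):
            sel = np.abs(s.mz_values - target) / target < 5e-6
            tot = float(s.intensity_values[sel].sum())
            if tot > best_i:
                best_t, best_i = s.time, tot
        assert best_t == pytest.approx(9.0, abs=0.1)

    def test_interconversion_places_pyro_ion_at_host_rts(self):
        spec = SyntheticSpec(matrix="fish", spikes={"triphosphate": 40.0},
                             interconversion_fraction=0.1, hrms_time_range=(4.0, 13.0), seed=8)
        ss, _ = generate_hrms_scanset(spec)
        target = get_species("pyrophosphate").computed_precursor_mz()
        def xic_at(rt):
            tot = 0.0
            for s in ss.of_mode("FS"):
                if abs(s.time - rt) < 0.2:
                    sel = np.abs(s.mz_values - target) / target < 5e-6
                    tot += float(s.intensity_values[sel].sum())
            return tot
        assert xic_at(5.9) > 0 and xic_at(11.8) > 0  # ortho and tri RTs
        assert xic_at(7.5) == 0.0

    def test_truth_lists_longchain_set(self):
        ss, truth = generate_hrms_scanset(
            SyntheticSpec(matrix="dairy", shmp_spike=100.0, hrms_time_range=(15.0, 16.0), seed=9)
        )
        assert len(truth["longchain"]) == 6


class TestValidationBatch:
    def test_counts_and_labels(self):
        spec = SyntheticSpec(matrix="meat", seed=0)
        batch = generate_validation_batch(spec, 10, 10, 200.0)
        assert len(batch) == 20
        assert sum(1 for l, _, _ in batch if l == "blank") == 10

    def test_zero_blanks_rejected(self):
        with pytest.raises(ValueError):
            generate_validation_batch(SyntheticSpec(), 0, 5, 200.0)

    def test_fortified_clearly_separated_from_blanks(self):
        spec = SyntheticSpec(matrix="meat", seed=1)
        batch = generate_validation_batch(spec, 10, 10, 200.0)
        rt = get_species("pyrophosphate").expected_rt
        blanks = [window_signal(tr, rt) for l, tr, _ in batch if l == "blank"]
        fortified = [window_signal(tr, rt) for l, tr, _ in batch if l == "fortified"]
        cutoff = np.mean(blanks) + 3 * np.std(blanks, ddof=1)
        assert min(fortified) > cutoff


class TestCalibrationSeries:
    def test_deterministic_and_linear(self):
        x1, y1 = generate_calibration_series([10, 25, 50], slope=7.0, proportional_noise=0.0, seed=0)
        np.testing.assert_allclose(y1, 7.0 * x1)
        _, y2 = generate_calibration_series([10, 25, 50], seed=5)
        _, y3 = generate_calibration_series([10, 25, 50], seed=5)
        np.testing.assert_array_equal(y2, y3)
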