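"""XIC extraction, three-way confirmation, interconversion and the fingerprint."""

import numpy as np
import pytest

from polyphos.hrms_screen import (
    confirm_species,
    extract_xic,
    fingerprint_longchain,
    resolve_interconversion,
)
from polyphos.signal_io import Scan, ScanSet
from polyphos.species_db import get_species
from polyphos.synthgen import SyntheticSpec, generate_hrms_scanset

FAST = dict(hrms_time_range=(4.0, 14.0))
LONG = dict(hrms_time_range=(13.0, 23.0))


def _fs_scanset(target, intensities, times=None, offset_ppm=0.0):
    times = times if times is not None else np.arange(len(intensities)) * 0.1 + 1.0
    mz = target * (1 + offset_ppm * 1e-6)
    scans = [
        Scan(time=t, mode="FS", mz_values=np.array([mz]), intensity_values=np.array([v]))
        for t, v in zip(times, intensities)
    ]
    return ScanSet(scans=scans)


class TestExtractXic:
    def test_exact_centroids_copied(self):
        ss = _fs_scanset(176.9359, [10.0, 20.0, 30.0])
        tr = extract_xic(ss, 176.9359, tol_ppm=5)
        np.testing.assert_allclose(tr.intensities, [10, 20, 30])

    def test_out_of_tolerance_excluded(self):
        ss = _fs_scanset(176.9359, [10.0, 20.0, 30.0], offset_ppm=10.0)
        tr = extract_xic(ss, 176.9359, tol_ppm=5)
        np.testing.assert_allclose(tr.intensities, 0.0)

    def test_jittered_intensity_mostly_captured(self):
        rng = np.random.default_rng(0)
        total = 0.0
        scans = []
        for i in range(100):
            mz = 256.9023 * (1 + rng.normal(0, 2e-6))
            scans.append(Scan(time=1.0 + i * 0.05, mode="FS",
                              mz_values=np.array([mz]), intensity_values=np.array([100.0])))
            total += 100.0
        tr = extract_xic(ScanSet(scans=scans), 256.9023, tol_ppm=5)
        assert tr.intensities.sum() / total > 0.95

    def test_requires_positive_tolerance_and_scans(self):
        ss = _fs_scanset(100.0, [1.0, 2.0])
        with pytest.raises(ValueError):
            extract_xic(ss, 100.0, tol_ppm=0)
        with pytest.raises(ValueError):
            extract_xic(ss, 100.0, tol_ppm=5, mode="DIA")


class TestConfirmSpecies:
    def test_spiked_pyrophosphate_confirmed(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 40.0}, seed=1, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("pyrophosphate"))
        assert rec.confirmed
        assert rec.matched_rt == pytest.approx(9.0, abs=0.1)
        assert abs(rec.mass_error_ppm) < 3.0
        assert rec.fragments_confirmed  # at least one DIA ion

    def test_no_dia_fragment_blocks_confirmation(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 40.0},
                             dia_enabled=False, seed=2, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("pyrophosphate"))
        assert not rec.confirmed
        assert any("fragment" in n for n in rec.notes)

    def test_wrong_rt_not_confirmed(self):
        # pyrophosphate ion eluting at the orthophosphate RT only
        target = get_species("pyrophosphate").computed_precursor_mz()
        times = np.arange(4.0, 12.0, 0.05)
        inten = 1e5 * np.exp(-0.5 * ((times - 5.9) / 0.08) ** 2)
        ss = ScanSet(scans=[
            Scan(time=t, mode="FS", mz_values=np.array([target]), intensity_values=np.array([v]))
            for t, v in zip(times, inten)
        ])
        rec = confirm_species(ss, get_species("pyrophosphate"))
        assert not rec.confirmed
        assert any("outside RT tolerance" in n for n in rec.notes)

    def test_internal_standard_precursor_only(self):
        spec = SyntheticSpec(matrix="fish", seed=3, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("internal standard"))
        assert rec.confirmed
        assert any("precursor-only" in n for n in rec.notes)

    def test_monotone_in_tolerances(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 40.0, "triphosphate": 25.0},
                             seed=4, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        tight = {
            sp: confirm_species(ss, get_species(sp), rt_tol=0.3, tol_ppm=3.0).confirmed
            for sp in ("orthophosphate", "pyrophosphate", "triphosphate")
        }
        loose = {
            sp: confirm_species(ss, get_species(sp), rt_tol=0.6, tol_ppm=6.0).confirmed
            for sp in tight
        }
        for sp in tight:
            assert loose[sp] >= tight[sp]


class TestInterconversion:
    def test_cross_rt_signal_annotated_not_counted(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 40.0, "triphosphate": 40.0},
                             interconversion_fraction=0.1, seed=5, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("pyrophosphate"))
        assert rec.confirmed
        assert rec.matched_rt == pytest.approx(9.0, abs=0.1)
        [rec] = resolve_interconversion([rec], ss)
        assert any("in-source" in n for n in rec.notes)

    def test_clean_records_unchanged(self):
        spec = SyntheticSpec(matrix="fish", spikes={"pyrophosphate": 40.0}, seed=6, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("pyrophosphate"))
        notes_before = list(rec.notes)
        [rec] = resolve_interconversion([rec], ss)
        assert rec.notes == notes_before

    def test_fragment_of_triphosphate_only(self):
        # triphosphate present with in-source pyrophosphate ion; no real pyro
        spec = SyntheticSpec(matrix="fish", natural_ortho=0.0, internal_standard_amount=0.0,
                             spikes={"triphosphate": 40.0},
                             interconversion_fraction=0.1, seed=7, **FAST)
        ss, _ = generate_hrms_scanset(spec)
        rec = confirm_species(ss, get_species("pyrophosphate"))
        assert not rec.confirmed
        [rec] = resolve_interconversion([rec], ss)
        assert any("in-source fragment of triphosphate" in n for n in rec.notes)


class TestFingerprint:
    def test_blank_has_empty_fingerprint(self):
        ss, _ = generate_hrms_scanset(SyntheticSpec(matrix="dairy", seed=8, **LONG))
        assert fingerprint_longchain(ss) == []

    def test_shmp_treated_sample_matches_truth(self):
        ss, truth = generate_hrms_scanset(
            SyntheticSpec(matrix="dairy", shmp_spike=150.0, seed=9, **LONG)
        )
        fp = fingerprint_longchain(ss)
        assert sorted(fp) == sorted(truth["longchain"])
        assert fp  # non-empty: E452 evidence

    def test_single_species_fingerprint(self):
        ss, _ = generate_hrms_scanset(
            SyntheticSpec(matrix="fish", spikes={"pentaphosphate": 20.0}, seed=10, **LONG)
        )
        assert fingerprint_longchain(ss) == ["pentaphosphate"]

    def test_ordered_by_retention_time(self):
        ss, _ = generate_hrms_scanset(
            SyntheticSpec(matrix="fish", shmp_spike=150.0, seed=11, **LONG)
        )
        fp = fingerprint_longchain(ss)
        rts = [get_species(n).expected_rt for n in fp]
        assert rts == sorted(rts)
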