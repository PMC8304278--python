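"""Trace/scan containers, delimited I/O, mzML round-trips and reports."""

import subprocess
import textwrap

import numpy as np
import pytest

from polyphos.classify import classify_sample, undeclared_survey
from polyphos.signal_io import (
    Scan,
    ScanSet,
    Trace,
    read_mzml,
    read_report,
    read_trace,
    write_mzml,
    write_report,
    write_trace,
)


class TestTrace:
    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            Trace(channel="SCD", times=[0.0, 1.0, 1.0], intensities=[1, 2, 3])

    def test_requires_finite_intensities(self):
        with pytest.raises(ValueError):
            Trace(channel="SCD", times=[0.0, 1.0], intensities=[1.0, np.nan])

    def test_csv_round_trip(self, tmp_path):
        tr = Trace(channel="SCD", times=np.linspace(0, 5, 50), intensities=np.sin(np.linspace(0, 5, 50)))
        p = tmp_path / "t.csv"
        write_trace(tr, p)
        back = read_trace(p)
        np.testing.assert_allclose(back.times, tr.times)
        np.testing.assert_allclose(back.intensities, tr.intensities)

    def test_seconds_converted_to_minutes(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("0,1\n60,2\n120,3\n")
        tr = read_trace(p, time_unit="s")
        np.testing.assert_allclose(tr.times, [0, 1, 2])

    def test_comma_decimal_dialect(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("0,0;1,5\n1,0;2,5\n2,0;3,0\n")
        tr = read_trace(p, sep=";", decimal=",")
        np.testing.assert_allclose(tr.intensities, [1.5, 2.5, 3.0])

    def test_non_monotone_time_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("0,1\n2,2\n1,3\n")
        with pytest.raises(ValueError, match="increasing"):
            read_trace(p)


class TestScanSet:
    def test_dia_needs_isolation_center(self):
        with pytest.raises(ValueError):
            Scan(time=1.0, mode="DIA", mz_values=[100.0], intensity_values=[1.0])

    def test_isolation_window_coverage(self):
        s = Scan(time=1.0, mode="DIA", mz_values=[], intensity_values=[],
                 isolation_center=176.94, isolation_width=1.0)
        assert s.covers(176.5) and s.covers(177.4)
        assert not s.covers(178.0)

    def test_scans_sorted_by_time(self):
        ss = ScanSet(scans=[
            Scan(time=2.0, mode="FS", mz_values=[], intensity_values=[]),
            Scan(time=1.0, mode="FS", mz_values=[], intensity_values=[]),
        ])
        assert [s.time for s in ss.scans] == [1.0, 2.0]


@pytest.fixture
def small_scanset():
    return ScanSet(scans=[
        Scan(time=1.0, mode="FS", mz_values=np.array([96.9696, 200.123]),
             intensity_values=np.array([1000.0, 5.5])),
        Scan(time=1.01, mode="DIA", mz_values=np.array([78.959]),
             intensity_values=np.array([300.0]), isolation_center=176.9359),
        Scan(time=2.0, mode="FS", mz_values=np.array([62.9854]),
             intensity_values=np.array([42.0])),
    ])


class TestMzml:
    def test_round_trip(self, tmp_path, small_scanset):
        p = tmp_path / "x.mzML"
        write_mzml(small_scanset, p)
        back = read_mzml(p)
        assert len(back.scans) == 3
        for a, b in zip(small_scanset.scans, back.scans):
            assert a.mode == b.mode
            assert b.time == pytest.approx(a.time, abs=1e-6)
            np.testing.assert_allclose(b.mz_values, a.mz_values)
            np.testing.assert_allclose(b.intensity_values, a.intensity_values)
        dia = back.scans[1]
        assert dia.isolation_center == pytest.approx(176.9359, abs=1e-4)
        assert dia.isolation_width == pytest.approx(1.0)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.mzML"
        p.write_text("")
        with pytest.raises(ValueError):
            read_mzml(p)

    def test_profile_spectrum_rejected(self, tmp_path):
        doc = textwrap.dedent("""\
            <?xml version="1.0" encoding="utf-8"?>
            <mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
             <run id="r"><spectrumList count="1">
              <spectrum index="0" id="scan=1" defaultArrayLength="0">
               <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
               <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
              </spectrum>
             </spectrumList></run>
            </mzML>
        """)
        p = tmp_path / "profile.mzML"
        p.write_text(doc)
        with pytest.raises(ValueError, match="centroid"):
            read_mzml(p)

    def test_missing_polarity_warns(self, tmp_path, small_scanset):
        p = tmp_path / "x.mzML"
        write_mzml(small_scanset, p)
        txt = p.read_text().replace('accession="MS:1000129" name="negative scan"',
                                    'accession="MS:1000999" name="nothing"')
        p.write_text(txt)
        with pytest.warns(UserWarning, match="polarity"):
            read_mzml(p)

    def test_mzr_reads_our_mzml(self, tmp_path, small_scanset):
        """Independent oracle: Bioconductor mzR parses the writer's output."""
        p = tmp_path / "x.mzML"
        write_mzml(small_scanset, p)
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(mzR))\n'
            f'f <- openMSfile("{p}")\n'
            'h <- header(f)\n'
            'cat(nrow(h), h$msLevel, sprintf("%.6f", h$retentionTime), "\\n")\n'
            'pk <- peaks(f, 1)\n'
            'cat(sprintf("%.4f", pk[,1]), sprintf("%.2f", pk[,2]), "\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        fields = out.stdout.split()
        assert fields[0] == "3"
        assert fields[1:4] == ["1", "2", "1"]
        # retention times in seconds
        assert [float(x) for x in fields[4:7]] == pytest.approx([60.0, 60.6, 120.0])
        assert [float(x) for x in fields[7:9]] == pytest.approx([96.9696, 200.123])
        assert [float(x) for x in fields[9:11]] == pytest.approx([1000.0, 5.5])


class TestReports:
    def test_round_trip_and_censoring(self, tmp_path):
        records = [
            {"species": "pyrophosphate", "confirmed": False, "amount": "ND", "notes": []},
            {"species": "triphosphate", "confirmed": True, "amount": 3.2, "notes": ["ok"]},
        ]
        profiles = {p.name: p for p in undeclared_survey()}
        verdicts = [classify_sample(profiles["minced beef"])]
        p = tmp_path / "rep.json"
        write_report(records, verdicts, p)
        back = read_report(p)
        assert back["records"] == records
        assert back["verdicts"][0]["label"] == "no_evidence"

    def test_longchain_evidence_listed(self, tmp_path):
        profiles = {p.name: p for p in undeclared_survey()}
        v = classify_sample(profiles["caramote prawn I"])
        p = tmp_path / "rep.json"
        write_report([], [v], p)
        ev = " ".join(read_report(p)["verdicts"][0]["evidence"])
        for name in ("tetraphosphate", "pentametaphosphate", "pentaphosphate", "hexaphosphate"):
            assert name in ev

    def test_bit_stable(self, tmp_path):
        records = [{"species": "orthophosphate", "confirmed": True, "amount": 781.0, "notes": []}]
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        write_report(records, [], a)
        write_report(records, [], b)
        assert a.read_bytes() == b.read_bytes()
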