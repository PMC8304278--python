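"""Chromatographic and HRMS data containers plus file readers/writers.

Carries the two signal types of the platform: the suppressed-conductivity
trace (SCD channel) and centroided HRMS scan sets (full-scan MS1 + DIA MS2),
together with delimited-text trace I/O, a minimal centroided-mzML
reader/writer, calibration-table input and JSON result reports.

All retention times are minutes internally; seconds are converted on input.
Only centroided spectra are processed — profile data must be centroided
upstream.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "Scan",
    "ScanSet",
    "read_trace",
    "write_trace",
    "read_mzml",
    "write_mzml",
    "read_calibration",
    "write_report",
    "read_report",
]

_NS = "http://psi.hupo.org/ms/mzml"

# Censoring states, ordered: absent < detected-below-LOD < below-LOQ.
CENSOR_STATES = ("ND", "<LOD", "<LOQ")


@dataclass
class Trace:
    """A time/intensity chromatogram (conductivity channel or XIC)."""

    channel: str  # "SCD" or "XIC"
    times: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.channel not in ("SCD", "XIC"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.times.size < 2:
            raise ValueError("trace needs at least 2 points")
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def median_dt(self) -> float:
        return float(np.median(np.diff(self.times)))


@dataclass
class Scan:
    """One centroided mass spectrum."""

    time: float  # minutes
    mode: str  # "FS" (MS1 full scan) or "DIA" (MS2)
    mz_values: np.ndarray
    intensity_values: np.ndarray
    isolation_center: float | None = None  # Th, DIA only
    isolation_width: float = 1.0  # Th

    def __post_init__(self):
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensity_values = np.asarray(self.intensity_values, dtype=float)
        if self.mode not in ("FS", "DIA"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mz_values.size != self.intensity_values.size:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz_values.size > 1 and np.any(np.diff(self.mz_values) < 0):
            order = np.argsort(self.mz_values)
            self.mz_values = self.mz_values[order]
            self.intensity_values = self.intensity_values[order]
        if self.mode == "DIA" and self.isolation_center is None:
            raise ValueError("DIA scan requires an isolation window center")

    def covers(self, mz: float) -> bool:
        """Whether a DIA isolation window covers the given precursor m/z."""
        if self.mode != "DIA":
            return False
        half = self.isolation_width / 2.0
        return abs(mz - self.isolation_center) <= half


@dataclass
class ScanSet:
    """An acquisition: scans ordered by time, fixed negative polarity."""

    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [s.time for s in self.scans]
        if any(b < a for a, b in zip(times, times[1:])):
            self.scans = sorted(self.scans, key=lambda s: s.time)
        self.metadata.setdefault("polarity", "negative")

    def of_mode(self, mode: str) -> list[Scan]:
        return [s for s in self.scans if s.mode == mode]

    def dia_covering(self, precursor_mz: float) -> list[Scan]:
        return [s for s in self.scans if s.mode == "DIA" and s.covers(precursor_mz)]


# ---------------------------------------------------------------------------
# Delimited trace I/O


def read_trace(
    path,
    channel: str = "SCD",
    sep: str = ",",
    decimal: str = ".",
    time_unit: str = "min",
) -> Trace:
    """Read a two-column time/intensity file (header optional).

    ``time_unit='s'`` converts seconds to minutes. ``decimal=','`` accepts
    the comma-decimal dialect used in some exported tables.
    """
    df = pd.read_csv(path, sep=sep, decimal=decimal, comment="#", header=None, skip_blank_lines=True)
    # tolerate a header row of labels
    if df.shape[0] and not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        try:
            df.iloc[0].astype(float)
        except (ValueError, TypeError):
            df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two delimited columns")
    times = df.iloc[:, 0].astype(float).to_numpy()
    inten = df.iloc[:, 1].astype(float).to_numpy()
    if time_unit == "s":
        times = times / 60.0
    elif time_unit != "min":
        raise ValueError(f"unknown time unit {time_unit!r}")
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    return Trace(channel=channel, times=times, intensities=inten)


def write_trace(trace: Trace, path, sep: str = ",") -> None:
    df = pd.DataFrame({"time_min": trace.times, "intensity": trace.intensities})
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_calibration(path, sep: str = ",", decimal: str = ".") -> pd.DataFrame:
    """Read a calibration series: columns ``level`` (conc) and ``response``."""
    df = pd.read_csv(path, sep=sep, decimal=decimal)
    cols = {c.lower().strip(): c for c in df.columns}
    if "level" not in cols or "response" not in cols:
        raise ValueError(f"{path}: calibration table needs 'level' and 'response' columns")
    out = df.rename(columns={cols["level"]: "level", cols["response"]: "response"})
    return out[["level", "response"] + [c for c in out.columns if c not in ("level", "response")]]


# ---------------------------------------------------------------------------
# mzML

_CV = {
    "ms_level": "MS:1000511",
    "ms1": "MS:1000579",
    "msn": "MS:1000580",
    "negative": "MS:1000129",
    "positive": "MS:1000130",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "scan_start": "MS:1000016",
    "iso_target": "MS:1000827",
    "iso_lower": "MS:1000828",
    "iso_upper": "MS:1000829",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "no_compression": "MS:1000576",
    "zlib": "MS:1000574",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
}


def _q(tag: str) -> str:
    return f"{{{_NS}}}{tag}"


def _cv_params(elem) -> dict[str, dict]:
    return {
        cv.get("accession"): dict(cv.attrib)
        for cv in elem.findall(_q("cvParam"))
    }


def _decode_binary(bda) -> np.ndarray:
    params = _cv_params(bda)
    raw = base64.b64decode((bda.findtext(_q("binary")) or "").strip())
    if _CV["zlib"] in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _CV["f32"] in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> ScanSet:
    """Read a centroided mzML file into a :class:`ScanSet`.

    Scan times are converted to minutes.  Profile-only spectra raise with a
    pointer to centroid first; a missing polarity yields a warning and is
    assumed negative.
    """
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise ValueError(f"{path}: not a readable mzML file ({e})") from e
    root = tree.getroot()
    spectra = root.iter(_q("spectrum"))
    scans: list[Scan] = []
    polarity_seen = False
    for sp in spectra:
        params = _cv_params(sp)
        if _CV["profile"] in params and _CV["centroid"] not in params:
            raise ValueError(
                f"{path}: profile-mode spectrum found; centroid the data before reading"
            )
        if _CV["negative"] in params or _CV["positive"] in params:
            polarity_seen = True
            if _CV["positive"] in params:
                raise ValueError(f"{path}: positive-polarity scan; this assay is negative-mode")
        level = int(params.get(_CV["ms_level"], {}).get("value", 1))
        # scan start time lives on scanList/scan
        t = None
        for scan_el in sp.iter(_q("scan")):
            sparams = _cv_params(scan_el)
            if _CV["scan_start"] in sparams:
                attr = sparams[_CV["scan_start"]]
                t = float(attr["value"])
                unit = (attr.get("unitName") or "").lower()
                if unit.startswith("second"):
                    t /= 60.0
                break
        if t is None:
            raise ValueError(f"{path}: spectrum without scan start time")
        iso_center, iso_width = None, 1.0
        iw = sp.find(f"{_q('precursorList')}/{_q('precursor')}/{_q('isolationWindow')}")
        if iw is not None:
            iparams = _cv_params(iw)
            iso_center = float(iparams[_CV["iso_target"]]["value"])
            lo = float(iparams.get(_CV["iso_lower"], {}).get("value", 0.5))
            hi = float(iparams.get(_CV["iso_upper"], {}).get("value", 0.5))
            iso_width = lo + hi
        mz = inten = None
        for bda in sp.iter(_q("binaryDataArray")):
            bparams = _cv_params(bda)
            if _CV["mz_array"] in bparams:
                mz = _decode_binary(bda)
            elif _CV["intensity_array"] in bparams:
                inten = _decode_binary(bda)
        if mz is None or inten is None:
            mz = np.empty(0)
            inten = np.empty(0)
        mode = "FS" if level == 1 else "DIA"
        if mode == "DIA" and iso_center is None:
            # MS2 without isolation info cannot be assigned a window; skip.
            continue
        scans.append(
            Scan(
                time=t,
                mode=mode,
                mz_values=mz,
                intensity_values=inten,
                isolation_center=iso_center,
                isolation_width=iso_width,
            )
        )
    if not scans:
        raise ValueError(f"{path}: no spectra found")
    if not polarity_seen:
        warnings.warn(f"{path}: no polarity annotation; assuming negative mode")
    return ScanSet(scans=scans)


def _b64_f64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **units):
    el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value)
    for k, v in units.items():
        el.set(k, v)
    return el


def write_mzml(scanset: ScanSet, path) -> None:
    """Write a :class:`ScanSet` as minimal centroided mzML (64-bit, uncompressed)."""
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    cvlist = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    ET.SubElement(cvlist, "cv", id="UO", fullName="Unit Ontology", URI="https://unit-ontology.googlecode.com/svn/trunk/unit.obo")
    run = ET.SubElement(root, "run", id="run1")
    slist = ET.SubElement(run, "spectrumList", count=str(len(scanset.scans)))
    for i, s in enumerate(scanset.scans):
        sp = ET.SubElement(slist, "spectrum", index=str(i), id=f"scan={i + 1}",
                           defaultArrayLength=str(s.mz_values.size))
        if s.mode == "FS":
            _cv(sp, _CV["ms1"], "MS1 spectrum")
            _cv(sp, _CV["ms_level"], "ms level", "1")
        else:
            _cv(sp, _CV["msn"], "MSn spectrum")
            _cv(sp, _CV["ms_level"], "ms level", "2")
        _cv(sp, _CV["negative"], "negative scan")
        _cv(sp, _CV["centroid"], "centroid spectrum")
        scl = ET.SubElement(sp, "scanList", count="1")
        _cv(scl, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scl, "scan")
        _cv(scan_el, _CV["scan_start"], "scan start time", f"{s.time:.6f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        if s.mode == "DIA":
            plist = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            iw = ET.SubElement(prec, "isolationWindow")
            half = s.isolation_width / 2.0
            _cv(iw, _CV["iso_target"], "isolation window target m/z", f"{s.isolation_center:.4f}", unitName="m/z")
            _cv(iw, _CV["iso_lower"], "isolation window lower offset", f"{half:.4f}", unitName="m/z")
            _cv(iw, _CV["iso_upper"], "isolation window upper offset", f"{half:.4f}", unitName="m/z")
        blist = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for acc, name, arr in (
            (_CV["mz_array"], "m/z array", s.mz_values),
            (_CV["intensity_array"], "intensity array", s.intensity_values),
        ):
            payload = _b64_f64(arr)
            bda = ET.SubElement(blist, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, _CV["f64"], "64-bit float")
            _cv(bda, _CV["no_compression"], "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# Result reports


def _record_to_dict(rec) -> dict:
    d = {
        "species": rec.species,
        "confirmed": bool(rec.confirmed),
        "matched_rt": rec.matched_rt,
        "rt_error": rec.rt_error,
        "mass_error_ppm": rec.mass_error_ppm,
        "fragments_confirmed": list(rec.fragments_confirmed),
        "amount": rec.amount,
        "notes": list(rec.notes),
    }
    return d


def write_report(records: Sequence, verdicts: Sequence, path) -> None:
    """Write per-species detection records and per-sample verdicts as JSON.

    Output is bit-stable for fixed inputs (sorted keys, fixed float repr).
    """
    doc = {
        "records": [_record_to_dict(r) if not isinstance(r, dict) else r for r in records],
        "verdicts": [v if isinstance(v, dict) else v.to_dict() for v in verdicts],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
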