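"""Targeted HRMS confirmation of (poly)phosphate anions.

An anion counts as confirmed when three criteria coincide: an extracted-ion
chromatogram (XIC) peak of the [M−H]⁻ precursor at the expected retention
time, an exact-mass match of the intensity-weighted centroid, and at least
one diagnostic fragment co-eluting in the DIA channel whose isolation
window covers the precursor.  The long-chain "fingerprint" is the subset of
tetra-/tetrameta-/penta-/pentameta-/hexa-/hexameta-phosphate passing those
criteria: because no standards exist for these polymers, their joint
presence (not a quantity) is the evidence of polyphosphate (E452) use.

In-source interconversion — an ion of one species appearing at another
species' retention time, e.g. the pyrophosphate ion under the triphosphate
peak — is handled by only ever counting the peak at a species' own RT and
annotating cross-RT signal as in-source transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import species_db
from .peakdetect import Peak, detect_peaks
from .signal_io import ScanSet, Trace
from .species_db import PhosphateSpecies

__all__ = [
    "DetectionRecord",
    "extract_xic",
    "confirm_species",
    "resolve_interconversion",
    "fingerprint_longchain",
]

DEFAULT_TOL_PPM = 5.0
DEFAULT_RT_TOL = 0.5  # min


@dataclass
class DetectionRecord:
    """Per-species HRMS outcome for one sample."""

    species: str
    confirmed: bool
    matched_rt: float | None = None  # min
    rt_error: float | None = None  # min, matched − expected
    mass_error_ppm: float | None = None
    fragments_confirmed: tuple[float, ...] = ()
    amount: float | str | None = None  # µg/g, or "ND"/"<LOD"/"<LOQ"
    precursor_area: float = 0.0
    precursor_height: float = 0.0
    notes: list[str] = field(default_factory=list)


def extract_xic(
    scanset: ScanSet,
    target_mz: float,
    tol_ppm: float = DEFAULT_TOL_PPM,
    mode: str = "FS",
    precursor_mz: float | None = None,
) -> Trace:
    """Extract an ion chromatogram: per-scan summed intensity within ±tol_ppm.

    For ``mode='DIA'`` only scans whose isolation window covers
    ``precursor_mz`` (default: ``target_mz``) are used, so fragment traces
    are linked to their precursor's window.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if mode == "FS":
        scans = scanset.of_mode("FS")
    elif mode == "DIA":
        scans = scanset.dia_covering(precursor_mz if precursor_mz is not None else target_mz)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not scans:
        raise ValueError(f"no {mode} scans available for XIC extraction")
    half = target_mz * tol_ppm * 1e-6
    times = np.array([s.time for s in scans])
    inten = np.zeros(len(scans))
    for i, s in enumerate(scans):
        lo = np.searchsorted(s.mz_values, target_mz - half, side="left")
        hi = np.searchsorted(s.mz_values, target_mz + half, side="right")
        if hi > lo:
            inten[i] = s.intensity_values[lo:hi].sum()
    return Trace(
        channel="XIC",
        times=times,
        intensities=inten,
        metadata={"target_mz": target_mz, "tol_ppm": tol_ppm, "mode": mode},
    )


def _weighted_mass_error_ppm(
    scanset: ScanSet, target_mz: float, tol_ppm: float, t_lo: float, t_hi: float
) -> float | None:
    """ppm offset of the intensity-weighted centroid within a peak's span."""
    num = den = 0.0
    half = target_mz * tol_ppm * 1e-6
    for s in scanset.of_mode("FS"):
        if not (t_lo <= s.time <= t_hi):
            continue
        lo = np.searchsorted(s.mz_values, target_mz - half, side="left")
        hi = np.searchsorted(s.mz_values, target_mz + half, side="right")
        if hi > lo:
            w = s.intensity_values[lo:hi]
            num += float(np.dot(w, s.mz_values[lo:hi]))
            den += float(w.sum())
    if den == 0:
        return None
    return (num / den - target_mz) / target_mz * 1e6


def _peak_near(peaks: list[Peak], rt: float, tol: float) -> Peak | None:
    cands = [p for p in peaks if abs(p.apex_time - rt) <= tol]
    if not cands:
        return None
    return max(cands, key=lambda p: p.height)


def confirm_species(
    scanset: ScanSet,
    species: PhosphateSpecies,
    rt_tol: float = DEFAULT_RT_TOL,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_snr: float = 3.0,
) -> DetectionRecord:
    """Apply the three-way confirmation rule to one species.

    Fragment matching uses the computed exact masses where the curated value
    disagrees with the composition-derived one (both are recorded).  A
    species listing no fragments (the internal standard) is confirmed on
    precursor RT + exact mass alone.
    """
    target = species.computed_precursor_mz()
    rec = DetectionRecord(species=species.name, confirmed=False, amount="ND")
    xic = extract_xic(scanset, target, tol_ppm, mode="FS")
    peaks = detect_peaks(xic, min_snr=min_snr)
    peak = _peak_near(peaks, species.expected_rt, rt_tol)
    if peak is None:
        if peaks:
            rec.notes.append(
                "precursor signal only at "
                + ", ".join(f"{p.apex_time:.2f}" for p in peaks)
                + " min (outside RT tolerance)"
            )
        else:
            rec.notes.append("no precursor signal")
        return rec
    rec.matched_rt = peak.apex_time
    rec.rt_error = peak.apex_time - species.expected_rt
    rec.precursor_area = peak.area
    rec.precursor_height = peak.height
    rec.mass_error_ppm = _weighted_mass_error_ppm(
        scanset, target, tol_ppm, peak.start_time, peak.end_time
    )

    confirmed_frags: list[float] = []
    if species.fragment_mzs:
        for frag_printed in species.fragment_mzs:
            frag = frag_printed
            if frag_printed in species.unverified_fragments:
                rec.notes.append(f"fragment {frag_printed:.4f} stored as printed (unverified assignment)")
            try:
                fx = extract_xic(scanset, frag, tol_ppm, mode="DIA", precursor_mz=target)
            except ValueError:
                continue
            fpeaks = detect_peaks(fx, min_snr=min_snr)
            fpeak = _peak_near(fpeaks, peak.apex_time, rt_tol / 2.0)
            if fpeak is not None:
                confirmed_frags.append(frag)
        rec.fragments_confirmed = tuple(confirmed_frags)
        if not confirmed_frags:
            rec.notes.append("no fragment confirmed in DIA")
            return rec
    else:
        rec.notes.append("no diagnostic fragments listed; precursor-only confirmation")
    rec.confirmed = True
    rec.amount = None  # quantification pending
    return rec


def resolve_interconversion(
    records: list[DetectionRecord],
    scanset: ScanSet,
    database: list[PhosphateSpecies] | None = None,
    rt_tol: float = DEFAULT_RT_TOL,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_snr: float = 3.0,
) -> list[DetectionRecord]:
    """Annotate cross-RT signal as in-source transformation.

    Electrospray heat can fragment or condense (poly)phosphate anions so
    that one species' m/z shows peaks at another species' retention time.
    Confirmation and quantification already use only the peak at each
    species' own RT; this pass adds the provenance notes: cross-RT peaks of
    a confirmed species are flagged as in-source signal, and an unconfirmed
    species whose ion elutes exactly at a longer chain's RT is annotated as
    that chain's in-source fragment.
    """
    db = database if database is not None else species_db.default_database()
    by_rt = sorted((sp for sp in db if sp.chain_class != "internal_standard"),
                   key=lambda sp: sp.expected_rt)
    for rec in records:
        sp = species_db.get_species(rec.species, db)
        xic = extract_xic(scanset, sp.computed_precursor_mz(), tol_ppm, mode="FS")
        peaks = detect_peaks(xic, min_snr=min_snr)
        for p in peaks:
            if abs(p.apex_time - sp.expected_rt) <= rt_tol:
                continue  # the species' own peak
            host = next(
                (o for o in by_rt if o.name != sp.name and abs(p.apex_time - o.expected_rt) <= rt_tol),
                None,
            )
            if host is None:
                continue
            if rec.confirmed:
                rec.notes.append(
                    f"ion {sp.computed_precursor_mz():.4f} also at {p.apex_time:.2f} min "
                    f"({host.name} RT): in-source interconversion, excluded from quantification"
                )
            elif host.n_phosphorus > sp.n_phosphorus:
                rec.notes.append(
                    f"signal at {p.apex_time:.2f} min attributed to in-source fragment of {host.name}"
                )
            else:
                rec.notes.append(
                    f"signal at {p.apex_time:.2f} min coincides with {host.name} RT; "
                    "attributed to in-source transformation"
                )
    return records


def fingerprint_longchain(
    scanset: ScanSet,
    rt_tol: float = DEFAULT_RT_TOL,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_snr: float = 3.0,
    database: list[PhosphateSpecies] | None = None,
) -> list[str]:
    """Confirmed long-chain species, ordered by retention time.

    A non-empty result is the E452 confirmation fingerprint.
    """
    db = database if database is not None else species_db.default_database()
    longs = [sp for sp in db if sp.is_long_chain]
    confirmed = []
    for sp in sorted(longs, key=lambda s: s.expected_rt):
        rec = confirm_species(scanset, sp, rt_tol=rt_tol, tol_ppm=tol_ppm, min_snr=min_snr)
        if rec.confirmed:
            confirmed.append(sp.name)
    return confirmed
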