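"""Conductivity-channel screening by relative retention time.

The screening tier is qualitative: peaks in the suppressed-conductivity
chromatogram are identified by their retention time relative to the
orthophosphate peak (RRT), compared against a reference table measured on a
sample spiked at the 200 µg/g (P₂O₅) screening cut-off, with a ±2.5%
acceptance band.  A sample is screening-positive when at least one additive
species (pyro-, tri-, trimetaphosphate) or the hexametaphosphate multi-peak
envelope matches with S/N ≥ 3.  Quantification is left to the HRMS tier.

Because RRT is a ratio, the decision is invariant to uniform stretching of
the time axis; the orthophosphate anchor is taken as the earliest detected
peak, orthophosphate being the first-eluting anion of the target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .peakdetect import Peak, detect_peaks
from .signal_io import Trace

__all__ = [
    "RRTReference",
    "ScreeningResult",
    "relative_rt",
    "match_rrt",
    "build_rrt_reference",
    "screen_scd",
    "false_positive_check",
    "linearity",
]

RRT_TOL = 0.025  # ±2.5% acceptance band on relative retention time
SHMP_MIN_CONSECUTIVE = 3  # envelope peaks required in a row to call SHMP


@dataclass
class RRTReference:
    """Reference relative retention times from a spiked run.

    ``species_rrt`` maps additive species names to RRT (ratio to the
    orthophosphate RT, which is 1 by construction); ``shmp_rrts`` holds the
    RRTs of the first (up to ten) envelope peaks of the hexametaphosphate
    mixture, in elution order.  ``column`` tags the separation column the
    table was measured on (reference tables are column-specific).
    """

    species_rrt: dict[str, float]
    shmp_rrts: tuple[float, ...] = ()
    ortho_rt: float | None = None  # min, informational
    column: str = "AS16"

    def __post_init__(self):
        for name, r in self.species_rrt.items():
            if r <= 0:
                raise ValueError(f"RRT for {name} must be positive")
        if any(r <= 0 for r in self.shmp_rrts):
            raise ValueError("SHMP envelope RRTs must be positive")


@dataclass
class ScreeningResult:
    positive: bool
    matched_species: list[str] = field(default_factory=list)
    shmp_peaks_matched: int = 0
    shmp_detected: bool = False
    anchor_rt: float | None = None
    peaks: list[Peak] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "positive": self.positive,
            "matched_species": list(self.matched_species),
            "shmp_peaks_matched": self.shmp_peaks_matched,
            "shmp_detected": self.shmp_detected,
            "anchor_rt": self.anchor_rt,
            "notes": list(self.notes),
        }


def relative_rt(peak_rt: float, ortho_rt: float) -> float:
    """Retention time relative to the orthophosphate reference peak."""
    if ortho_rt <= 0:
        raise ValueError("orthophosphate reference peak not found")
    return peak_rt / ortho_rt


def match_rrt(sample_rrt: float, reference_rrt: float, tol: float = RRT_TOL) -> bool:
    """True iff the sample RRT is within ±tol (relative) of the reference."""
    if sample_rrt <= 0 or reference_rrt <= 0:
        raise ValueError("RRTs must be positive")
    return abs(sample_rrt - reference_rrt) / reference_rrt <= tol


def _anchor_peak(peaks: list[Peak]) -> Peak:
    """The orthophosphate anchor: earliest detected peak."""
    if not peaks:
        raise ValueError("orthophosphate reference peak not found")
    return min(peaks, key=lambda p: p.apex_time)


def build_rrt_reference(
    trace: Trace,
    species_rts: dict[str, float],
    shmp_window: tuple[float, float] = (14.0, 28.0),
    min_snr: float = 3.0,
    column: str = "AS16",
) -> RRTReference:
    """Derive a reference RRT table from a run spiked at the screening level.

    ``species_rts`` gives the nominal retention times of the additive
    species on this column (used only to assign detected peaks to names);
    envelope peaks are all remaining peaks inside ``shmp_window``.
    """
    peaks = detect_peaks(trace, min_snr=min_snr)
    anchor = _anchor_peak(peaks)
    rrt: dict[str, float] = {}
    assigned: set[float] = set()
    for name, rt in species_rts.items():
        cands = [p for p in peaks if abs(p.apex_time - rt) <= 0.3 and p.apex_time not in assigned]
        if not cands:
            continue
        best = min(cands, key=lambda p: abs(p.apex_time - rt))
        rrt[name] = relative_rt(best.apex_time, anchor.apex_time)
        assigned.add(best.apex_time)
    lo, hi = shmp_window
    env = [
        p for p in sorted(peaks, key=lambda p: p.apex_time)
        if lo <= p.apex_time <= hi and p.apex_time not in assigned
    ][:10]
    return RRTReference(
        species_rrt=rrt,
        shmp_rrts=tuple(relative_rt(p.apex_time, anchor.apex_time) for p in env),
        ortho_rt=anchor.apex_time,
        column=column,
    )


def screen_scd(
    trace: Trace | list[Trace],
    reference: RRTReference,
    min_snr: float = 3.0,
    rrt_tol: float = RRT_TOL,
) -> ScreeningResult:
    """Screen a conductivity trace (or replicate traces) against a reference.

    With replicate injections, each species (and the envelope) must be
    detected in every replicate to count, mirroring duplicate-injection
    practice.  The result is qualitative (detect / non-detect).
    """
    if isinstance(trace, list):
        if not trace:
            raise ValueError("no traces supplied")
        results = [screen_scd(t, reference, min_snr=min_snr, rrt_tol=rrt_tol) for t in trace]
        matched = set(results[0].matched_species)
        for r in results[1:]:
            matched &= set(r.matched_species)
        shmp = all(r.shmp_detected for r in results)
        merged = ScreeningResult(
            positive=bool(matched) or shmp,
            matched_species=sorted(matched),
            shmp_peaks_matched=min(r.shmp_peaks_matched for r in results),
            shmp_detected=shmp,
            anchor_rt=results[0].anchor_rt,
            notes=[f"combined over {len(results)} replicate injections"],
        )
        return merged

    peaks = detect_peaks(trace, min_snr=min_snr)
    anchor = _anchor_peak(peaks)
    others = [p for p in peaks if p is not anchor]
    result = ScreeningResult(positive=False, anchor_rt=anchor.apex_time, peaks=peaks)

    for name, ref_rrt in reference.species_rrt.items():
        hit = any(
            match_rrt(relative_rt(p.apex_time, anchor.apex_time), ref_rrt, rrt_tol)
            and p.snr >= min_snr
            for p in others
        )
        if hit:
            result.matched_species.append(name)

    # SHMP envelope: walk the reference envelope RRTs and count the longest
    # run of consecutive matches.
    run = best_run = 0
    n_matched = 0
    for ref_rrt in reference.shmp_rrts:
        hit = any(
            match_rrt(relative_rt(p.apex_time, anchor.apex_time), ref_rrt, rrt_tol)
            and p.snr >= min_snr
            for p in others
        )
        if hit:
            n_matched += 1
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    result.shmp_peaks_matched = n_matched
    result.shmp_detected = best_run >= SHMP_MIN_CONSECUTIVE
    if result.shmp_detected:
        result.notes.append(
            f"hexametaphosphate envelope: {n_matched} peaks matched "
            f"(longest consecutive run {best_run})"
        )
    result.positive = bool(result.matched_species) or result.shmp_detected
    return result


def false_positive_check(
    blank_signals: list[float], fortified_signals: list[float]
) -> tuple[float, bool]:
    """Screening false-positive rule on validation batches.

    Returns the fraction of fortified samples whose signal falls below the
    blanks' mean + 3 sd, and whether that fraction is < 5%.
    """
    if len(blank_signals) < 2:
        raise ValueError("need at least 2 blank signals")
    if not fortified_signals:
        raise ValueError("no fortified signals supplied")
    blanks = np.asarray(blank_signals, dtype=float)
    cutoff = blanks.mean() + 3.0 * blanks.std(ddof=1)
    frac = float(np.mean(np.asarray(fortified_signals, dtype=float) < cutoff))
    return frac, frac < 0.05


def linearity(levels, responses) -> tuple[float, float, float]:
    """OLS calibration line; returns (slope, intercept, R²).

    R² = 1 − SS_res/SS_tot; a constant response gives R² = 0.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need ≥ 3 paired points")
    if np.unique(x).size < 3:
        raise ValueError("need ≥ 3 distinct concentration levels")
    res = stats.linregress(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        # a constant response carries no calibration information
        return float(res.slope), float(res.intercept), 0.0
    pred = res.slope * x + res.intercept
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return float(res.slope), float(res.intercept), r2
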