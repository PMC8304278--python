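"""Seeded synthetic-data generator with known ground truth.

Emulates the two instrument channels on which the method runs:

* conductivity traces — Gaussian peaks at the database retention times on a
  drifting noisy baseline, response proportional to the P₂O₅-equivalent
  amount, with an optional matrix interferent near 6.95 min and a ten-peak
  hexametaphosphate (SHMP) envelope on a documented default retention grid;
* HRMS scan sets — full-scan centroids at the [M−H]⁻ masses with ppm-scale
  jitter, plus DIA scans (1 Th isolation) carrying the diagnostic fragments,
  with optional in-source interconversion of the pyrophosphate ion.

All randomness flows from the spec's seed; identical specs give identical
output.  The SHMP envelope grid and intensity decay are synthetic defaults
(the true envelope is instrument-specific): ten peaks from 14 to 27.5 min
with geometrically decaying areas (ratio 0.85).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import species_db
from .signal_io import Scan, ScanSet, Trace
from .species_db import (
    LONG_CHAIN_NAMES,
    PhosphateSpecies,
    p2o5_equivalent,
    species_mass_from_p2o5,
)

__all__ = [
    "SyntheticSpec",
    "generate_scd_trace",
    "generate_hrms_scanset",
    "generate_validation_batch",
    "generate_calibration_series",
    "window_signal",
    "SHMP_ENVELOPE_RTS",
]

# Synthetic SHMP envelope: ten peaks, 14–27.5 min, areas decaying by 0.85.
SHMP_ENVELOPE_RTS: tuple[float, ...] = tuple(np.round(np.linspace(14.0, 27.5, 10), 3))
SHMP_AREA_RATIO = 0.85

#: Conductivity response: peak height units per µg/g expressed as P₂O₅.
#: Set so a 200 µg/g single-species spike sits near S/N 80 at default noise
#: and the weakest peak of a 200 µg/g SHMP envelope near S/N 4 — the
#: screening S/N ≥ 3 cut-off is then genuinely exercised by the envelope.
SCD_HEIGHT_PER_UG_P2O5 = 0.5

#: HRMS response: apex counts per µg/g of species in the sample.
MS_COUNTS_PER_UG = 2.0e4

#: Fraction of precursor intensity carried by each DIA fragment.
DIA_EFFICIENCY = 0.3

# Typical endogenous orthophosphate by matrix (µg/g); survey range ~30–1300.
NATURAL_ORTHO_DEFAULT = {"meat": 800.0, "fish": 950.0, "dairy": 450.0, "blank": 100.0}

_LONGCHAIN_SHMP_FRACTIONS = {
    "tetraphosphate": 0.25,
    "tetrametaphosphate": 0.20,
    "pentaphosphate": 0.20,
    "pentametaphosphate": 0.15,
    "hexaphosphate": 0.10,
    "hexametaphosphate": 0.10,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything that defines one synthetic sample."""

    matrix: str = "blank"  # meat | fish | dairy | blank
    spikes: dict = field(default_factory=dict)  # species name -> µg/g (species mass)
    shmp_spike: float = 0.0  # µg/g expressed as P₂O₅
    natural_ortho: float | None = None  # µg/g; default per matrix
    interferent: bool = False  # matrix peak at 6.95 min
    baseline_sd: float = 1.0
    proportional_sd: float = 0.01
    drift_slope: float = 0.05  # units per minute
    baseline_offset: float = 10.0
    peak_width_sd: float = 0.08  # min
    mz_jitter_ppm: float = 2.0
    interconversion_fraction: float = 0.0
    internal_standard_amount: float = 50.0  # µg/g-equivalent, HRMS only
    scd_time_range: tuple[float, float] = (0.0, 30.0)
    scd_dt: float = 0.005  # min
    hrms_time_range: tuple[float, float] = (3.0, 24.0)
    hrms_scan_interval: float = 0.05  # min
    dia_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.matrix not in NATURAL_ORTHO_DEFAULT:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if any(v < 0 for v in self.spikes.values()) or self.shmp_spike < 0:
            raise ValueError("spike amounts must be non-negative")
        if self.natural_ortho is not None and self.natural_ortho < 0:
            raise ValueError("natural orthophosphate must be non-negative")

    @property
    def ortho_level(self) -> float:
        return (
            self.natural_ortho
            if self.natural_ortho is not None
            else NATURAL_ORTHO_DEFAULT[self.matrix]
        )


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _shmp_fractions(n: int = 10) -> np.ndarray:
    w = SHMP_AREA_RATIO ** np.arange(n)
    return w / w.sum()


def _scd_components(spec: SyntheticSpec, db: list[PhosphateSpecies]) -> list[dict]:
    """Ground-truth peak list: name, rt, height, amount (µg/g P₂O₅)."""
    comps: list[dict] = []
    by_name = {sp.name: sp for sp in db}
    amounts = dict(spec.spikes)
    ortho = amounts.pop("orthophosphate", 0.0) + spec.ortho_level
    if ortho > 0:
        amounts["orthophosphate"] = ortho
    for name, ug in amounts.items():
        sp = by_name[name]
        if sp.chain_class == "internal_standard":
            continue
        c_p2o5 = p2o5_equivalent(ug, sp)
        h = SCD_HEIGHT_PER_UG_P2O5 * c_p2o5
        if h > 0:
            comps.append({"name": name, "rt": sp.expected_rt, "height": h, "p2o5": c_p2o5})
    if spec.shmp_spike > 0:
        for i, (rt, f) in enumerate(zip(SHMP_ENVELOPE_RTS, _shmp_fractions()), start=1):
            amt = spec.shmp_spike * f
            comps.append(
                {
                    "name": f"shmp_{i}",
                    "rt": rt,
                    "height": SCD_HEIGHT_PER_UG_P2O5 * amt,
                    "p2o5": amt,
                }
            )
    if spec.interferent:
        comps.append({"name": "interferent", "rt": 6.95, "height": 15.0, "p2o5": 0.0})
    return comps


def generate_scd_trace(spec: SyntheticSpec) -> tuple[Trace, dict]:
    """Simulate a conductivity chromatogram; returns (trace, ground truth).

    Ground truth lists every injected peak with its retention time, height
    and expected S/N against the spec's baseline noise.
    """
    rng = np.random.default_rng(spec.seed)
    db = species_db.default_database()
    t0, t1 = spec.scd_time_range
    t = np.arange(t0, t1 + spec.scd_dt / 2, spec.scd_dt)
    comps = _scd_components(spec, db)
    clean = np.zeros_like(t)
    for c in comps:
        clean += c["height"] * _gauss(t, c["rt"], spec.peak_width_sd)
    noise_sd = np.sqrt(spec.baseline_sd**2 + (spec.proportional_sd * clean) ** 2)
    y = (
        spec.baseline_offset
        + spec.drift_slope * (t - t0)
        + clean
        + rng.normal(0.0, 1.0, t.size) * noise_sd
    )
    truth = {
        "peaks": [
            {**c, "snr_true": (c["height"] / spec.baseline_sd if spec.baseline_sd > 0 else np.inf)}
            for c in comps
        ],
        "shmp_rts": list(SHMP_ENVELOPE_RTS) if spec.shmp_spike > 0 else [],
    }
    trace = Trace(channel="SCD", times=t, intensities=y, metadata={"matrix": spec.matrix, "seed": spec.seed})
    return trace, truth


def _hrms_species_amounts(spec: SyntheticSpec, db: list[PhosphateSpecies]) -> dict[str, float]:
    """µg/g of each species present in the extract (HRMS view)."""
    by_name = {sp.name: sp for sp in db}
    amounts = dict(spec.spikes)
    amounts["orthophosphate"] = amounts.get("orthophosphate", 0.0) + spec.ortho_level
    if spec.internal_standard_amount > 0:
        amounts["internal standard"] = spec.internal_standard_amount
    if spec.shmp_spike > 0:
        for name, frac in _LONGCHAIN_SHMP_FRACTIONS.items():
            ug = species_mass_from_p2o5(spec.shmp_spike * frac, by_name[name])
            amounts[name] = amounts.get(name, 0.0) + ug
    return {k: v for k, v in amounts.items() if v > 0}


def generate_hrms_scanset(spec: SyntheticSpec) -> tuple[ScanSet, dict]:
    """Simulate a centroided FS + DIA acquisition; returns (scanset, truth).

    An SHMP spike populates the six long-chain species (fixed fractions of
    the P₂O₅ amount), so the generator's long-chain set is the reference for
    fingerprint checks.  ``interconversion_fraction`` > 0 places the
    pyrophosphate ion under the orthophosphate and triphosphate peaks at
    that fraction of the host's intensity, mimicking in-source thermal
    transformation.
    """
    rng = np.random.default_rng(spec.seed + 1)
    db = species_db.default_database()
    by_name = {sp.name: sp for sp in db}
    amounts = _hrms_species_amounts(spec, db)
    t0, t1 = spec.hrms_time_range
    times = np.arange(t0, t1 + spec.hrms_scan_interval / 2, spec.hrms_scan_interval)
    sigma = spec.peak_width_sd
    pyro = by_name["pyrophosphate"]

    scans: list[Scan] = []
    jit = spec.mz_jitter_ppm * 1e-6
    for ti in times:
        mzs: list[float] = []
        ints: list[float] = []
        for name, ug in amounts.items():
            sp = by_name[name]
            amp = MS_COUNTS_PER_UG * ug * _gauss(np.array([ti]), sp.expected_rt, sigma)[0]
            if amp < 1.0:
                continue
            mz = sp.computed_precursor_mz() * (1.0 + rng.normal(0.0, jit))
            mzs.append(mz)
            ints.append(amp * (1.0 + rng.normal(0.0, 0.02)))
            # in-source interconversion: the pyrophosphate ion rides under
            # the ortho- and triphosphate elution profiles
            if (
                spec.interconversion_fraction > 0
                and name in ("orthophosphate", "triphosphate")
            ):
                mzs.append(pyro.computed_precursor_mz() * (1.0 + rng.normal(0.0, jit)))
                ints.append(spec.interconversion_fraction * amp)
        # sparse chemical background
        n_bg = 8
        mzs.extend(rng.uniform(50.0, 750.0, n_bg))
        ints.extend(rng.exponential(5.0, n_bg))
        scans.append(Scan(time=float(ti), mode="FS", mz_values=np.array(mzs), intensity_values=np.array(ints)))

        if spec.dia_enabled:
            for sp in db:
                if sp.chain_class == "internal_standard":
                    continue
                parent_ug = amounts.get(sp.name, 0.0)
                parent_amp = (
                    MS_COUNTS_PER_UG * parent_ug * _gauss(np.array([ti]), sp.expected_rt, sigma)[0]
                    if parent_ug > 0
                    else 0.0
                )
                fmzs: list[float] = []
                fints: list[float] = []
                if parent_amp >= 1.0:
                    for frag in sp.fragment_mzs:
                        fmzs.append(frag * (1.0 + rng.normal(0.0, jit)))
                        fints.append(DIA_EFFICIENCY * parent_amp * (1.0 + rng.normal(0.0, 0.02)))
                scans.append(
                    Scan(
                        time=float(ti) + spec.hrms_scan_interval * 0.01,
                        mode="DIA",
                        mz_values=np.array(fmzs),
                        intensity_values=np.array(fints),
                        isolation_center=sp.computed_precursor_mz(),
                        isolation_width=1.0,
                    )
                )
    truth = {
        "amounts": amounts,
        "longchain": sorted(
            (n for n in amounts if n in LONG_CHAIN_NAMES),
            key=lambda n: by_name[n].expected_rt,
        ),
    }
    return ScanSet(scans=scans, metadata={"seed": spec.seed}), truth


def generate_validation_batch(
    spec: SyntheticSpec,
    n_blanks: int,
    n_fortified: int,
    spike_level: float,
    species: str = "pyrophosphate",
) -> list[tuple[str, Trace, dict]]:
    """Blank and fortified conductivity replicates for screening validation.

    ``spike_level`` is µg/g expressed as P₂O₅ (the screening cut-off scale).
    Returns ``(label, trace, truth)`` triples; labels are 'blank'/'fortified'.
    """
    if n_blanks < 1 or n_fortified < 1:
        raise ValueError("need at least one blank and one fortified replicate")
    db = species_db.default_database()
    sp = species_db.get_species(species, db)
    spike_ug = species_mass_from_p2o5(spike_level, sp)
    out: list[tuple[str, Trace, dict]] = []
    for i in range(n_blanks):
        s = replace(spec, spikes={}, shmp_spike=0.0, seed=spec.seed + 1000 + i)
        tr, truth = generate_scd_trace(s)
        out.append(("blank", tr, truth))
    for i in range(n_fortified):
        s = replace(spec, spikes={species: spike_ug}, seed=spec.seed + 2000 + i)
        tr, truth = generate_scd_trace(s)
        out.append(("fortified", tr, truth))
    return out


def generate_calibration_series(
    levels,
    slope: float = 100.0,
    intercept: float = 0.0,
    proportional_noise: float = 0.01,
    additive_noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy linear calibration responses for the given concentration levels."""
    rng = np.random.default_rng(seed)
    x = np.asarray(levels, dtype=float)
    clean = slope * x + intercept
    y = clean * (1.0 + rng.normal(0.0, proportional_noise, x.size))
    if additive_noise > 0:
        y = y + rng.normal(0.0, additive_noise, x.size)
    return x, y


def window_signal(trace: Trace, rt: float, half_width: float = 0.3) -> float:
    """Maximum baseline-subtracted intensity in an RT window.

    The screening validation signal: what the detector shows where the
    spiked species elutes.
    """
    from .peakdetect import estimate_baseline

    base = estimate_baseline(trace)
    mask = (trace.times >= rt - half_width) & (trace.times <= rt + half_width)
    if not mask.any():
        raise ValueError("RT window outside the trace")
    return float(np.max(trace.intensities[mask] - base[mask]))
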