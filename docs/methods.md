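# Methods

This note documents the models, parameter choices and limitations behind
`polyphos`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Exact-mass database

Eleven target anions are curated: orthophosphate, pyrophosphate,
triphosphate, trimetaphosphate, the six long-chain species (tetra-,
tetrameta-, penta-, pentameta-, hexa-, hexametaphosphate) and a
¹⁵N-nitrate internal standard.  Monoisotopic masses use standard isotopic
values to ≥ 6 decimals (H 1.0078250319, N 14.0030740052, ¹⁵N 15.0001088984,
O 15.9949146221, P 30.97376151 Da); the [M−H]⁻ m/z subtracts the proton
mass (1.00727646688 Da), not a hydrogen atom.  Curated (printed) precursor
values are stored alongside and agree with the computed masses to
< 0.0001 Th; the *computed* masses are authoritative for matching.  A few
curated fragment m/z values have no verifiable elemental assignment (e.g. a
pyrophosphate fragment at 78.9561 vs the PO₃⁻ value 78.9591 used
elsewhere); they are stored as printed and flagged `unverified_fragments`,
and detection records carry a note when such a fragment is used.  Isotope
labels are first-class composition symbols (`15N`), so the internal
standard needs no special casing.

P₂O₅ equivalents — the unit of the regulation and of the spectrophotometric
reference method — use free-acid molecular masses, because the
chromatographic analytes are the anions of the free acids:
µg P₂O₅ = µg species × n_P × M(P₂O₅)/2 / M(species).  The conversion is
exactly invertible.

## Chromatographic signal model

The generator and detector assume Gaussian peaks with σ = 0.08 min
(baseline resolution for retention times 1–2 min apart, matching the
database RT spacing).  Traces carry a constant offset, linear drift
(default 0.05 units/min), white baseline noise (sd 1.0) and 1 %
proportional noise.

**Baseline.**  Rolling median (window 1.0 min) → mask points > 3·MAD above
it, mask dilated by half a window → interpolate the median across masked
spans → moving-average smooth.  This is unbiased in peak-free noise
regions (a rolling *minimum*, the more common quick choice, sits ~2–3
noise sd low over windows of hundreds of points), follows linear drift,
and bridges under isolated peaks.  Window edges use reflection so a single
noisy end point cannot dominate.

**Peak detection.**  Detection runs on a lightly smoothed copy of the
baseline-subtracted signal (Gaussian kernel, σ = 0.03 min — a matched
filter that leaves 0.08 min peaks ~94 % intact while suppressing
single-point noise by ~5×), with the apex height corrected for that known
attenuation.  Integration bounds descend on the smoothed signal to 1 % of
the apex or the first local minimum (valley split for overlap); the area
is trapezoidal over the raw baseline-subtracted signal.  The noise
estimate is 1.4826 × MAD, robust to residual peaks; S/N is apex height
over that noise.  A noise-free signal reports S/N = +inf.

No deconvolution of co-eluting peaks and no exponentially-modified
Gaussian shapes are attempted.

## Screening tier (conductivity)

Identification is by relative retention time: RRT = t_R / t_R(ortho), with
the orthophosphate anchor taken as the *earliest* detected peak (it is the
first-eluting target anion, and an anchor by elution order keeps the
decision invariant under uniform time-axis stretch — RRT is a ratio).  A
species matches when |RRT − RRT_ref|/RRT_ref ≤ 2.5 %, per peak.  The SHMP
envelope counts as matched when ≥ 3 *consecutive* envelope reference peaks
match — the envelope rule sets no minimum in general use, and three
consecutive hits resist single spurious peaks.  The screen is qualitative:
the 200 µg/g (P₂O₅) cut-off is a property of the spiked reference run, not
a concentration computed from the sample; quantification belongs to the
HRMS tier.  Replicate injections, when supplied, must both detect.

Validation statistics: the false-positive rule (fraction of fortified
samples below blank mean + 3 sd must be < 5 %), and calibration linearity
by OLS (R², with a constant response scored 0).

## HRMS tier

XICs sum centroids within ±5 ppm (the instrument resolution of 70 000
supports ppm-level windows; 5 ppm captures > 95 % of centroids jittered at
2 ppm sd).  Confirmation requires (a) a precursor XIC peak within 0.5 min
of the expected RT, (b) in DIA scans whose 1 Th isolation window covers the
precursor, at least one listed fragment peaking within 0.25 min
(rt_tol/2) of the precursor apex — DIA links precursor and fragment only
through the isolation window, so co-elution is the binding criterion.  The
mass error is the ppm offset of the intensity-weighted centroid across the
peak span.  The internal standard lists no fragments and is confirmed on
precursor RT + exact mass alone.  Fragment intensity ratios are not used
(no reference spectra), and isotope-pattern scoring is not implemented.

**In-source interconversion.**  Electrospray heat can make one species'
ion appear at another's retention time (canonically the pyrophosphate ion
under the ortho- and triphosphate peaks).  Confirmation and quantification
only ever use the peak at a species' own RT; a dedicated pass annotates
cross-RT signal as in-source transformation, and an unconfirmed ion found
only at a longer chain's RT is noted as that chain's in-source fragment.

**Fingerprint.**  The confirmed subset of the six long-chain species,
ordered by RT.  Non-empty ⇒ polyphosphate (E452) treatment; the species
are not quantifiable (no standards).

## Quantification

Calibration is ordinary least squares; `sd_intercept` is the closed-form
standard error s·√(1/n + x̄²/Sxx).  LOD = 3.3·SD/b, LOQ = 10·SD/b, so
LOQ/LOD ≡ 10/3.3.  For detection limits the low-concentration line (the
lowest three levels) is the intended input.  Sample amounts back-calculate
through the preparation — 2 g homogenate brought to 40 mL, 1:10 dilution
for HRMS, so µg/mL × 200 = µg/g — and censor below the limits on the
sample scale (ND, \<LOD, \<LOQ).  An unconfirmed record is never assigned a
number, whatever its signal.  Conductivity-channel quantities are P₂O₅
equivalents; HRMS quantities are nominal species mass.  The internal
standard is present in the database and the generator, but response-ratio
normalisation is off by default: the extraction protocol adds it, yet no
normalisation rule is defined for it, so using it silently would be
invention.  Weighted or robust regression and matrix-effect correction are
out of scope.

## Verdict logic

Label order: `no_evidence` < `trace_endogenous` < `short_chain_additive` <
`polyphosphate_E452`.  Rules: (1) any confirmed long-chain species ⇒ E452
(the invariant label ⇔ non-empty fingerprint holds by construction);
(2) otherwise a short-chain species quantified ≥ 1 µg/g or a positive
conductivity screen ⇒ short-chain additive; (3) otherwise any short-chain
signal — censored, or quantified below the 1 µg/g threshold — ⇒
trace-endogenous (endogenous polyphosphate of microbial/cellular origin is
real, so traces alone never assert treatment); (4) else no evidence.
Quantified-but-sub-threshold amounts count as traces, not as additive
evidence — this is what keeps products with, say, 0.2–0.8 µg/g residues of
plainly endogenous origin out of the additive class.

`ortho_elevated` is an independent flag: orthophosphate above a
matrix-specific ceiling (meat 2000, fish 2000, dairy 1500 µg/g).  The
ceilings are configurable; the defaults sit well above the endogenous
ranges observed in the bundled survey (meat ≤ 1105, fish ≤ 1299, dairy
≤ 786 µg/g for untreated rows) and below the hydrolysis-inflated levels of
the treated ones (≥ 2715 µg/g).  Elevated orthophosphate accompanies a
verdict (hydrolysed additive is a plausible source) but never creates one:
a high-ortho sample with pyrophosphate as the only residue is labelled
short-chain additive without asserting *which* additive was applied, since
hydrolysis products are ambiguous.  When the fingerprint is positive but
the conductivity screen was negative (possible for low-level or degraded
treatment), the verdict carries an explicit note that the evidence is
HRMS-only.

## Synthetic data: what it emulates, what it does not

The generator emulates: Gaussian peaks at the database RTs with response
proportional to P₂O₅-equivalent amount; matrix orthophosphate backgrounds
(defaults meat 800, fish 950, dairy 450 µg/g, within the survey's 30–1300
range); an optional interferent at 6.95 min (observed in some matrices,
cleanly separated from the pyro/trimeta RTs); a ten-peak SHMP envelope on
a synthetic grid (14–27.5 min, areas decaying geometrically at 0.85 — the
true envelope is instrument-specific and only known graphically); FS
centroids with 2 ppm jitter and sparse exponential background; DIA
fragments at 30 % of precursor intensity; optional in-source
interconversion as a fraction of the host peak.  An SHMP spike populates
the six long-chain species at fixed fractions (0.25/0.20/0.20/0.15/0.10/
0.10), which defines the ground-truth fingerprint.

Sensitivity: 0.5 height units per µg/g P₂O₅ against baseline noise sd 1.0,
i.e. a 200 µg/g single-species spike sits near S/N 80 and the *weakest*
peak of a 200 µg/g SHMP envelope near S/N 4 — the envelope, not the single
species, is what genuinely exercises the S/N ≥ 3 cut-off (a single
sensitivity constant cannot put both at S/N ≈ 10, since the tenth envelope
peak carries only ~4 % of the area).  Tests of detection-rate behaviour at
marginal S/N raise the noise explicitly (baseline sd 10 puts a 200 µg/g
spike at S/N ≈ 10).

Not emulated: physically realistic suppressed-conductivity response
curves, hydrolysis kinetics and storage-time effects, co-elution requiring
deconvolution, profile-mode spectra, isotope patterns, and real matrix
effects.  Passing tests therefore demonstrate the correctness of the
decision logic and statistics under the stated signal model — not
instrument-level performance; instrument-dependent figures (real LODs,
recoveries, CVs) are deliberately not reproduction targets, and the
parameter-recovery suites stand in for them.

## Problem sizes and determinism

Default simulations: conductivity traces 0–30 min at 0.005 min sampling
(6001 points); HRMS runs at 0.05 min per cycle with one FS scan plus ten
1 Th DIA windows, usually restricted to the RT span under study (e.g.
13–23 min for fingerprint work).  Stochastic suites use 50 seeds (200 for
calibration linearity); all randomness flows from a single integer seed
per spec, and identical specs produce identical output.  mzML I/O is
centroided, 64-bit, uncompressed; the writer's output is cross-checked in
the test suite against an independent mzML reader (Bioconductor mzR).
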