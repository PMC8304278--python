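# polyphos

Two-tier detection of undeclared (poly)phosphate additives in foods of
animal origin, as a tested Python library and CLI.

Condensed phosphates — pyrophosphate (E450), triphosphate (E451) and the
polymeric polyphosphates (E452) — are legal additives in many processed
foods, but their undeclared use on fresh meat, seafood and dairy products
retains water, masks spoilage and constitutes economic fraud.  Detection is
hard because the additives hydrolyse to orthophosphate, which is also
naturally abundant.  `polyphos` implements the analytical decision logic of
a combined ion-chromatography platform:

1. **Screening (conductivity channel).**  Peaks in the suppressed-conductivity
   chromatogram are identified by *relative retention time* (RRT):
   RRT = t_R(analyte) / t_R(orthophosphate), matched against a reference
   table from a run spiked at the 200 µg g⁻¹ (as P₂O₅) screening cut-off,
   with a ±2.5 % band and S/N ≥ 3.  Sodium hexametaphosphate (SHMP), a
   polymer mixture, is recognised by its multi-peak envelope (first ten
   peaks).
2. **Confirmation and quantification (HRMS).**  Each anion is confirmed by
   three coinciding criteria: an extracted-ion-chromatogram peak of the
   deprotonated molecule [M−H]⁻ at the expected retention time, an exact
   monoisotopic mass match (ppm scale), and at least one diagnostic fragment
   co-eluting in the DIA channel.  Detection of the six long-chain anions —
   tetra-, tetrameta-, penta-, pentameta-, hexa- and hexametaphosphate —
   constitutes the **confirmation fingerprint** for E452 treatment (these
   polymers have no commercial standards and are never quantified
   individually).  Short-chain species are quantified against calibration
   lines with LOD = 3.3·SD/b and LOQ = 10·SD/b (SD: standard error of the
   intercept, b: slope), and reported censored (ND, \<LOD, \<LOQ) below the
   limits.
3. **Verdict.**  Per sample, the orthophosphate level, quantified
   short-chain species, the conductivity screen and the long-chain
   fingerprint combine into a label: `no_evidence`, `trace_endogenous`,
   `short_chain_additive` or `polyphosphate_E452`.

A seeded synthetic-data generator (`polyphos.synthgen`) produces
conductivity traces and centroided FS+DIA scan sets with known ground
truth, so every stage is testable without an instrument.  A 43-sample
survey of undeclared market products (meat, fish, dairy) ships with the
package (`polyphos.classify.undeclared_survey`).

## Worked example

Simulate a dairy sample treated with SHMP at 150 µg g⁻¹ (P₂O₅), then run
HRMS confirmation:

```bash
$ cat spec.yaml
matrix: dairy
shmp_spike: 150.0
seed: 11
hrms_time_range: [13.0, 23.0]

$ polyphos simulate --spec spec.yaml --out demo
wrote demo/scd.csv, demo/hrms.mzML, demo/truth.json

$ polyphos confirm-hrms demo/hrms.mzML --out records.json
{
  "confirmed": [
    "tetraphosphate",
    "tetrametaphosphate",
    "pentaphosphate",
    "pentametaphosphate",
    "hexametaphosphate",
    "hexaphosphate"
  ],
  "fingerprint": [
    "tetraphosphate",
    "tetrametaphosphate",
    "pentaphosphate",
    "pentametaphosphate",
    "hexametaphosphate",
    "hexaphosphate"
  ]
}
```

All six long-chain anions are confirmed (RT + exact mass + DIA fragment),
so the fingerprint is complete and the command exits with code 11
("E452 confirmed"; 0 = clean negative, 10 = screening positive, 1 = input
error).  In the library the same verdict comes from:

```python
>>> from polyphos import classify_sample, undeclared_survey
>>> prawn = next(p for p in undeclared_survey() if p.name == "caramote prawn I")
>>> v = classify_sample(prawn)
>>> v.label, v.ortho_elevated
('polyphosphate_E452', True)
```

— high orthophosphate (9578 µg/g against the 2000 µg/g fish ceiling),
quantified trimeta- and triphosphate, and a four-species long-chain
fingerprint: the three-step evidence of (poly)phosphate treatment.

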