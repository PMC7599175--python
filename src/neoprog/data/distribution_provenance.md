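# Provenance of the packaged class-conditional distribution table

`class_distributions.csv` holds per-characteristic mean/SD pairs for the
delayed (Bayley-III scale score < 85) and non-delayed classes, for the motor
and cognitive outcomes separately. The 42 characteristics are the 5 metabolite
ratios (NAA/Cho, NAA/Cr, Cho/Cr, NAA/mI, mI/Cr) plus MD and FA in each of the
6 supraventricular white-matter regions (FWMR, FWML, CWMR, CWML, PWMR, PWML).
MD is in 10^-3 mm^2/s; FA and all ratios are unitless.

The values were transcribed from published summary tables of a very-preterm
MRS/DTI cohort. The source tables contain apparent typographic defects; the
following mechanical corrections were applied during transcription:

1. Motor-delayed FWMR FA printed as `1.16(0.03)`. FA is by definition in
   [0, 1]; read as a dropped decimal/digit and corrected to `0.16(0.03)`.
2. Cognitive-delayed PWMR NAA/mI printed as `4.13&1.07)`; punctuation repaired
   to `4.13(1.07)`.
3. A row label printed `PMWL` was read as `PWML` (parietal white matter left).

Anomalies noted but NOT corrected (transcribed as printed, since no
definitional constraint is violated and the intended value is not
reconstructible):

- Cognitive non-delayed FWMR MD `1.14(0.15)` is markedly lower than every
  other MD entry (all other regions/classes sit near 1.3-1.4); possibly a
  digit transposition of 1.41.
- Motor non-delayed FWML MD `1.04(0.15)` is similarly low.

These defaults parameterise the synthetic-cohort generator only; nothing in
the screening or prediction code reads this file.
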