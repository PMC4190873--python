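# Methods

## Scope and model

`srmquant` models a selected-reaction-monitoring (SRM) protein assay
from peptide selection through to a percent-of-controls report. The
measurement model is standard for stable-isotope-dilution SRM: for
each monitored peptide the endogenous (light) signal is proportional
to protein abundance times an unknown peptide-specific response
factor; the co-eluting heavy-labelled synthetic peptide, spiked at a
fixed amount, shares that response factor, so the light/heavy ratio of
summed transition areas cancels it. Dividing by the same ratio for a
reference protein (Hsp60, a mitochondrial loading control) cancels
per-sample loading, and expressing the result relative to the mean of
healthy-control runs cancels the remaining protein-level constants.
The final quantity is therefore a unitless percent of control that, in
the absence of noise, equals the true relative abundance exactly; the
whole chain is invariant to any global rescaling of instrument
response.

## Assay design

- **Digestion**: trypsin, cleaving after K/R except before P. The
  proline rule is standard trypsin specificity and is required for the
  monitored peptide panel to be released intact. Default missed
  cleavages 0 (all monitored peptides are fully cleaved); the
  uniqueness screen tolerates up to 2.
- **Uniqueness**: a peptide is proteotypic when exactly one protein's
  tryptic digest (0–2 missed cleavages) contains it. Matching is at
  the digested-peptide level, not free substring level, since only
  tryptic peptides appear in the measured sample. I/L equivalence is
  available as a flag (mass spectrometry cannot distinguish them) but
  off by default.
- **Candidates**: 2–4 per protein, required to be proteome-unique,
  library-supported, 7–25 residues, and K/R-terminated (so a heavy
  label exists). Ranked by summed intensity of the top five eligible
  library fragments; the published criterion ("high-intensity
  y-fragments") is qualitative, and summed intensity is our concrete
  reading of it. Ties break lexicographically on sequence for
  determinism.
- **Transitions**: y-ions only with fragment index ≥ 3 (y1/y2 are
  excluded as unspecific; the floor is configurable), the five most
  intense per peptide, ranks 1..5. Ties break on higher product m/z,
  then label. Default charges: precursor 2+, fragment 1+.
- **Masses**: monoisotopic residue masses (pyteomics) for all m/z;
  average masses for gel-window molecular weight. Heavy label deltas
  are the exact isotopologue masses 8.014199 Da (¹³C₆¹⁵N₂-Lys) and
  10.008269 Da (¹³C₆¹⁵N₄-Arg); the nominal "+8/+10 Da" emerge on
  rounding. Carbamidomethyl (+57.02146 Da) is a fixed modification on
  every cysteine, applied symmetrically to endogenous and synthetic
  peptides.

## Signal processing

- Apex finding uses a 5-point moving average; integration uses the
  raw samples (trapezoidal), so smoothing never biases areas.
- A peak is accepted when the smoothed maximum exceeds the trace
  median by k = 3 noise SDs. Noise is estimated robustly from median
  absolute successive differences (÷√2), which is insensitive to the
  peak itself.
- Integration boundaries are taken from the heavy-standard trace —
  the points where its smoothed signal falls to 5% of apex height
  above baseline — and applied to both members of the light/heavy
  pair. The heavy standard is always present; the light peptide may be
  absent, so it cannot anchor its own boundaries.
- Background under a peak is baseline level × integration width, with
  the baseline the median intensity outside the integration window.
  The exported-background definition of the upstream instrument
  software is not public; this median-times-width stand-in is an
  explicit design choice.
- Area is clipped at zero (a peak cannot have negative area); with a
  correct baseline the clip only engages on noise-level residuals.
- Co-elution QC: pass iff every |light − heavy| apex difference
  ≤ rt_tol (default 0.2 min). Transition-ranking QC: cosine
  similarity between the light and heavy observed area vectors; the
  heavy standard realizes the expected fragment pattern, so agreement
  near 1 indicates an interference-free endogenous signal.

## Detection level

For each protein one designated quantifier peptide (the top-ranked
candidate) provides background values from the n = 12 control runs.
The detection level is mean + 1.645·SD (sample SD, n−1 denominator —
deliberate at n = 12), the one-sided 95% bound on blank signal, and is
also expressed as a percent of the mean control light area for the
same peptide. A sample's protein is called `n.d.` when the quantifier
peptide's background-subtracted light summed area falls below this
level. Quantification, by contrast, averages the light/heavy ratio
over all candidate peptides whose light signal was detected, falling
back to the quantifier peptide when none is.

Reference stability is summarized as the CV of the reference protein's
light/heavy ratio across all samples, flagged (not dropped) above 20%.

## Synthetic data

The generator emulates the targeted experiment, not the instrument:

- **Proteome**: six target proteins whose monitored peptides are
  embedded between lysine-terminated linkers (linkers avoid K/R/P), so
  each peptide is released by digestion and occurs in exactly one
  protein; plus random decoys screened to contain none of the
  monitored sequences. Real FASTA input remains fully supported. The
  two Hsp60 peptides are synthetic stand-ins (plausible tryptic
  peptides), since no published panel exists for the reference
  protein.
- **Library**: entries exactly for the monitored peptides, 6–10
  y-fragments (index ≥ 3) with seeded pseudo-random relative
  intensities in [20, 100].
- **Runs**: per transition, a Gaussian elution peak (σ = 0.05 min on
  a 0.01-min grid — five grid spacings, enough for ≤1% trapezoidal
  error) over a truncated-Gaussian baseline (level 20, SD 2 intensity
  units). Heavy amplitude = spike level (1000) × peptide response
  factor × a rank-decaying fragment weight; light amplitude scales the
  same expression by true abundance/100, a per-sample lognormal
  loading factor (σ = 0.15) that the reference normalization must
  cancel, and a base of 800. The weakest transitions thus sit near
  S/N ≈ 80, comfortably above the S/N ≥ 50 regime where ±10% recovery
  is expected. Light and heavy apexes differ by uniform jitter within
  ±0.05 min, inside the 0.2-min co-elution tolerance.
- **Cohort**: 12 control runs (two individuals × three biological ×
  two technical replicates, the assumed structure of the n = 12
  design) at 100% for every protein, plus four patients in which both
  E1 subunits are truly absent and one patient additionally lacks
  MCAD; E2/E3/MCAD patient levels sit at roughly 90–180% of control.
  Every injected analytic area (amplitude·σ·√2π) is recorded as
  ground truth, and a fixed seed reproduces every file byte for byte.

What passing on this generator does **not** show: robustness to
interfering co-eluting peptides, detector saturation, retention-time
drift between runs, isotope-envelope effects, or non-Gaussian peak
shapes (tailing). Those are real-data hazards outside the generator's
scope.

## Numerical and design choices

- Trapezoidal integration is additive over adjacent intervals and
  grid-refinement stable; areas of scaled traces scale exactly.
- All selection steps have documented deterministic tie-breaks, so
  panel construction is reproducible without a seed.
- Percent-of-controls uses the arithmetic mean of control runs
  (median would be more robust but the conventional report uses the
  mean).
- Degenerate inputs raise typed errors: a zero heavy standard is a
  `StandardFailureError` (assay invalid for that peptide/sample), a
  non-positive reference ratio a `ReferenceFailureError` (sample
  invalid), fewer than three background values an
  `InsufficientBackgroundError`.
- The `n.d.` string is rendered literally in the report; the numeric
  sub-LOD estimate is retained in a companion table for transparency.

## Problem sizes

The default validation cohort is 16 runs × 14 peptides × 5 transitions
× 2 labels (≈ 25 000 trace points per run); oracle cross-checks use
100 random proteins of 80–200 residues; LOD coverage uses 100 000
Gaussian draws. These sizes make the full suite and the acceptance
script complete in tens of seconds while leaving every statistical
check well-powered.

## Known limitations

- No absolute (fmol) quantification or calibration curves; output is
  relative to controls only.
- Background definition is a stand-in (see above); absolute detection
  levels in percent depend on it, though the 95% coverage property
  does not.
- One global heavy-spike level; no dilution series.
- No scheduled-SRM window computation, collision-energy optimization
  or retention-time prediction.
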