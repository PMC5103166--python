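# nirseed

Near-infrared reflectance spectroscopy (NIRS) calibration of seed
composition, and QTL mapping of the resulting phenotypes in recombinant
inbred line (RIL) populations.

## The problem

Quantitative genetics of seed storage compounds (oil, protein, carbon,
nitrogen, as % of dry seed weight) needs phenotypes for hundreds of lines.
Wet-chemistry reference methods (Soxhlet extraction, phenol protein
extraction, Dumas combustion) are accurate but slow and destructive. NIRS
replaces them: a reflectance spectrum of intact seeds, acquired in seconds,
is mapped to composition by a calibration model built once against
reference values. `nirseed` implements that whole workflow for
*Arabidopsis*-scale seed studies, plus the downstream genetics:

- **Preprocessing** — multiplicative scatter correction (MSC), gap-segment
  ("Norris") first derivative (segment 5, gap 5 points), and restriction to
  the informative spectral windows (4100–4940, 5390–6690, 6900–7130,
  7185–9000 cm⁻¹), excluding the water bands.
- **Chemometrics** — PLS1 regression (NIPALS with X-deflation per factor),
  leave-one-out PRESS curves with everything (MSC reference, centering)
  refit inside each fold, and parsimonious factor selection.
- **Validation statistics** — SEC = √(Σe²/(n−k−1)), SECV = √(Σe²/n) over
  leave-one-out residuals, bias-corrected SEP, r² as squared Pearson
  correlation, and RPD = SD(reference)/SEP with the AACC 39-00.01 usefulness
  bands (≥ 2.5 screening, ≥ 5 quality control, ≥ 8 process control).
- **Calibration-set design** — greedy max–min (Kennard–Stone-style)
  selection on the PC1/PC3 plane of MSC-corrected spectra, extreme-value
  augmentation via a preliminary model, and a ranked 3:1
  calibration/validation split that keeps both concentration endpoints in
  calibration.
- **Phenotype analysis** — genotype × culture × replicate ANOVA reporting
  each term's sequential sum of squares as a percentage of the total.
- **QTL mapping** — Haley–Knott interval mapping on selfed-RIL genotype
  probabilities (Haldane map function with RIL expansion R = 2r/(1+2r)),
  genome-wide significance by permutation (n = 1000, p < 0.05),
  multiple-QTL cofactor scans, 1.5-LOD support intervals, and per-QTL
  additive effects (A→B replacement semantics) and R².
- **Synthetic data** — generators for mixture spectra with scatter
  artifacts, correlated reference concentrations, RIL populations, and
  planted QTL, so every stage is testable without instrument data.

## Worked example

```python
from nirseed import synthetic as syn
from nirseed.pipeline import develop_calibration

refs, _ = syn.simulate_concentrations(500, seed=1)   # reference values (%)
spectra, _ = syn.simulate_spectra(refs, seed=2)      # 500 x 751 absorbance
r = develop_calibration(spectra, refs, "oil")["report"]
print(r.n_factors, round(r.sec, 3), round(r.sep, 3), round(r.rpd, 2), r.interpretation)
```

prints

```
4 0.322 0.358 14.59 process-control
```

i.e. the PRESS curve selected 4 PLS factors; the calibration error (SEC) is
0.322 % oil, the external-validation error (SEP) is 0.358 %, and the RPD of
14.6 puts the model in the process-control band — comfortably beyond the
2.5 screening threshold needed for breeding-program use. `examples/` holds
one narrative script per capability (preprocessing, sample selection,
variance decomposition, QTL mapping); each prints the numbers it computes
and a line on what they mean. The `nirseed` CLI exposes the same stages
(`simulate`, `design`, `calibrate`, `predict`, `phenotype`, `qtl`, `run`).

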