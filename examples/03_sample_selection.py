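"""Designing the calibration set: PC-space diversity, extremes, 3:1 split.

A good calibration set spans both the spectral variability (diverse samples
on the PC1/PC3 plane of MSC-corrected spectra) and the concentration range
(samples a preliminary model predicts as extreme).
"""

from nirseed import msc_apply, msc_fit, pca_fit, rank_split, select_diverse
from nirseed import synthetic as syn
from nirseed.io import SpectraSet

refs, truth = syn.simulate_concentrations(300, seed=5)
spectra, _ = syn.simulate_spectra(refs, seed=6)

ref = msc_fit(spectra)
corrected = SpectraSet(spectra.grid, msc_apply(spectra.absorbance, ref),
                       list(spectra.sample_ids))
pca = pca_fit(corrected, 3)
print("explained spectral variance:",
      [f"PC{i+1}: {v*100:.1f}%" for i, v in enumerate(pca.explained_variance_ratio)])

diverse = select_diverse(pca.scores, spectra.sample_ids, axes=(1, 3), n_select=50)
print(f"selected {len(diverse)} spectrally diverse samples, e.g. {diverse[:5]}")

oil = refs.values_for("oil").loc[diverse]
cal, val = rank_split(oil)
print(f"ranked 3:1 split -> {len(cal)} calibration / {len(val)} validation")
print(f"validation range [{oil[val].min():.1f}, {oil[val].max():.1f}] lies inside "
      f"calibration range [{oil[cal].min():.1f}, {oil[cal].max():.1f}] "
      "(no extrapolation during external validation)")
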