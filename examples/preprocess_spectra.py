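"""Preprocess replicate vis-NIR scans: trim, average, SNV.

Shows the fixed production order (trim edge bands, average the three
replicate scans per sample, then Standard Normal Variate) and what SNV
does to each spectrum.
"""

import numpy as np

from soilsqi import default_config, simulate_dataset
from soilsqi.preprocess import average_replicates, snv, trim_wavelengths

cfg = default_config(n_samples=20, step_nm=10.0, seed=3)
_, spectra = simulate_dataset(cfg)
print(f"Raw scans: {spectra.n_scans} rows ({len(set(spectra.sample_ids))} samples "
      f"x {cfg.replicates_per_sample} replicates), {spectra.n_bands} bands")

trimmed = trim_wavelengths(spectra)  # drop <399 nm and >2451 nm
averaged = average_replicates(trimmed)
transformed = snv(averaged)
print(f"After trim+average: {averaged.n_scans} rows, {averaged.n_bands} bands")
print("Per-spectrum mean after SNV :", np.abs(transformed.values.mean(axis=1)).max())
print("Per-spectrum sd after SNV   :",
      transformed.values.std(axis=1, ddof=1).round(12).min())

# SNV gives every spectrum mean 0 and unit sample sd, removing additive
# offsets and the multiplicative scatter the generator injected.
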