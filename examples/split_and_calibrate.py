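"""Kennard-Stone nested split and per-property spectral calibration.

Splits SNV-preprocessed spectra into calibration / validation /
external sets (9/16, 3/16, 4/16 of the samples) and fits one rule-ensemble
model per soil property, reporting external-set R².
"""

from soilsqi import RegressorSpec, default_config, fit, nested_split, predict, r_squared, simulate_dataset, spectra_matrix

cfg = default_config(n_samples=800, step_nm=10.0, seed=12)
props, spectra = simulate_dataset(cfg)
X = spectra_matrix(spectra)  # trim -> average -> SNV
split = nested_split(X.to_numpy(), sample_ids=X.index.to_numpy())
print(f"Split sizes: cal={len(split.calibration_ids)} "
      f"val={len(split.validation_ids)} ext={len(split.external_ids)}")

spec = RegressorSpec("rule_tree", seed=12)
for name in props.columns:
    fr = fit(spec, X.loc[split.calibration_ids].to_numpy(),
             props.loc[split.calibration_ids, name].to_numpy(), target_name=name)
    pred = predict(fr, X.loc[split.external_ids].to_numpy())
    m = r_squared(props.loc[split.external_ids, name].to_numpy(), pred)
    print(f"  {name:>3}: external R^2 = {m.r2:6.3f}  (n={m.n})")

# Organic indicators (OM, TN) carry the strongest absorption features
# in the generator, so they calibrate best. Weakly encoded nutrients
# trail, and the heaviest-tailed ones (Ca, K) can swing negative: a
# single extreme external value that the model cannot see coming
# dominates the residual sum. Fraction-of-variance R^2 deliberately
# reports this (external validation of skewed soil nutrients shows the
# same behaviour in practice).
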