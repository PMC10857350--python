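# Methods

`soilsqi` implements a soil-quality-index (SQI) workflow for fertility
assessment from vis-NIR spectra, together with a synthetic data
generator that makes every stage testable without access to a real
spectral library. This note records the model, its assumptions, the
defaults that matter, and the design choices that were genuinely open.

## The index

Seven minimum-data-set (MDS) indicators describe fertility: organic
matter (OM, %), pH, total nitrogen (TN, %), available phosphorus
(P, µg/g), potassium (K, mg/L), calcium (Ca, mg/L), magnesium
(Mg, mg/L). Each indicator value `x` is mapped to a unitless score

    S = 1 / (1 + (x / x0)^b)

with `x0` the arithmetic mean of the indicator over a reference table
and slope `b = −2.5` ("more is better", rising) or `b = +2.5` ("less is
better", falling). At `x = x0` either limb gives exactly 0.5, and the
two limbs are exact complements. The index is the weighted sum
`SQI = Σ Wᵢ Sᵢ` with expert-opinion weights OM 0.35, pH 0.20, TN 0.15,
P 0.10, K 0.10, Ca 0.05, Mg 0.05 (sum 1), so SQI ∈ (0, 1).

**pH optimum.** pH quality rises towards an agronomic optimum band
(5.5–7.0) and falls above it. The source convention gives the band but
not the centring of the two limbs, so the construction is a policy
object: a rising limb centred at the low edge, a falling limb centred
at the high edge, combined by pointwise **minimum** by default. The
minimum is the unique combination that is continuous and piecewise
rising-then-falling (the limbs cross near the band midpoint at a score
of ≈0.58 for |b| = 2.5); a pointwise-maximum variant is selectable but
is discontinuous at the band edges. Neither choice yields in-band
scores near 1 at |b| = 2.5 — users wanting a plateau near 1 should
steepen `b` or fix the limb centres elsewhere; the rule object exposes
both.

**Centring and degenerate inputs.** `x0` is computed once on the full
measured property table, not per split; this keeps the measured index
independent of the data split (the predicted pathway scores its
property predictions against the *measured* centring for the same
reason). Measured zeros (OM and TN can be reported as 0.00) are
substituted by half the smallest positive reference value before
scoring — the power law is undefined at 0 and the substitution pins
such samples near the worst end. Samples missing any MDS indicator are
flagged and excluded from the index under the default complete-case
policy; an optional mode renormalizes the weights of the present
indicators instead. A linear min–max scoring variant exists but the
non-linear sigmoid is the default.

## Spectra and preprocessing

Spectra live on a strictly increasing wavelength grid (default
400–2450 nm). The production pipeline is fixed: trim bands outside
399–2451 nm (edge effects), average the replicate scans of each sample
(three by default), then apply a per-spectrum transform. Standard
Normal Variate (SNV — centre and scale each spectrum to mean 0, unit
sample sd with the n−1 divisor) is the shipped default; SNV-detrend,
Savitzky–Golay smoothing/derivatives, simple first/second differences
and the gap derivative are selectable. All transforms are fit-free
(per-spectrum), so preprocessing before splitting leaks nothing.
Derivative edges are truncated rather than padded, consistent with the
edge-trimming philosophy. Whether to average replicates before or
after transformation is not dictated by the transforms themselves;
average-then-transform is fixed here because the replicate mean is the
quantity the downstream models consume.

## Splitting

The Kennard–Stone max–min algorithm picks design-space-covering
points: seed with the pair at maximum Euclidean distance, then
repeatedly add the candidate whose minimum distance to the selected
set is largest. Ties break to the lowest original row index, making
the procedure fully deterministic; a brute-force greedy oracle verifies
exact agreement on small point sets. The nested split applies it
twice — ¾ of samples into the modeling pool (rest external), ¾ of the
pool into calibration (rest validation) — giving ≈ 9/16 : 3/16 : 4/16.
Fraction-to-count rounding is round-half-up clamped to keep every
subset non-empty for n ≥ 4. Distances are computed on the
SNV-preprocessed spectra (recorded in `SplitAssignment.feature_space`);
the larger, design-covering subset always goes to calibration.

## Regression

Three families sit behind one fit/predict contract, each modelling one
target at a time:

* **plsr** — PLS1 via NIPALS, implemented in-repo. Components are
  capped by the rank of the centred design; at full rank predictions
  coincide with ordinary least squares (a cheap oracle, tested to
  1e−6). Default components: min(20, rank).
* **rule_tree** — a Cubist-style rule-ensemble stand-in backed by
  gradient-boosted regression trees (defaults: 100 rounds per
  "committee", depth 8, min leaf 5, 25 % of features per split). Full
  Cubist (rules + instance-based correction) is deliberately not
  re-implemented.
* **random_forest** — bagged trees (500 trees, features-per-split 0.33).

Rows with missing targets are dropped and counted. Evaluation uses the
fraction-of-variance coefficient of determination
`R² = 1 − SS_res/SS_tot`, *not* squared correlation, so values below
zero are possible and meaningful on external data.

## The synthetic generator

The generator defines the study conditions for every test and
experiment. Marginals follow survey-scale descriptive statistics
(mean/sd per indicator: OM 5.33/12.50, pH 6.95/0.97, TN 0.24/0.37,
P 38.34/1.35, K 200.54/465.25, Ca 4235.08/9944.54, Mg 316.18/333.87).
Nutrients and OM/TN are log-normal with parameters moment-matched to
those targets (their survey medians sit far below their means — strong
right skew); pH is a truncated normal on the observed 3.29–9.07 range.
The printed P sd (1.35 against a 0.26–1506 range) is kept verbatim as
the default; `REALISTIC_P_SD = 400` is provided for users who want a
dispersion comparable to K's. Cross-indicator dependence is imposed on
a Gaussian copula before the marginal transforms, which preserves the
marginals exactly; because the transforms are monotone, it is the
*rank* correlation that is preserved (Pearson correlation of
heavy-tailed marginals is attenuated below the copula value, so tests
check Spearman against the (6/π)·asin(ρ/2) map). Missingness is
completely at random at a configurable rate.

Spectra are generated directly in absorbance-like units: a smooth
polynomial baseline plus one Gaussian feature per (indicator, band)
pair contributing `gain · z · exp(−(λ−c)²/2w²)`, then a multiplicative
log-normal scatter factor and i.i.d. Gaussian band noise per replicate
scan. `z` is the indicator standardized on the log scale for
concentration-like properties (absorbance responds to concentration
over decades; this also keeps the easy limit genuinely easy) and on
the raw scale for pH. Organic indicators carry strong features at
distinct centres from the mineral nutrients, so each indicator's
spectral predictability is tunable through its gain alone. The default
gains are deliberately heterogeneous — organics strong, P/K weak —
calibrated once so that per-indicator external R² at the default noise
level spans roughly 0.35–0.93, the spread reported for real soil
spectral libraries.

What the generator does **not** emulate: radiative transfer,
instrument drift and detector-splice artefacts, spatially correlated
sampling, and non-MCAR missingness. Passing tests therefore
demonstrate the pipeline's correctness and the error-propagation
mechanism, not field-scale accuracy on any real archive.

## The three pathways and error propagation

* **measured** (SQI_m): score the measured property table. Touches no
  spectra, and is split-independent by construction.
* **predicted** (SQI_p): fit one spectral regressor per indicator on
  calibration samples only, predict properties for held-out samples,
  score them with the measured centring.
* **direct** (SQI_dp): fit a single regressor from calibration spectra
  to SQI_m (complete-case calibration samples only); predictions are
  clipped to [0, 1] (the index is bounded by construction) with the
  clip count logged.

Comparisons restrict all pathways to the identical external-sample
universe and report the survey-style descriptive schema (Mean, Median,
Min, Max, s, n) plus external-set R² against SQI_m. The
error-propagation experiment repeats the full pipeline over a grid of
encoding-noise levels and seeds: at zero noise all pathways agree
(external R² > 0.95 pairwise); at the heterogeneous default level the
per-indicator errors of the plug-in pathway pass through the scoring
non-linearity and accumulate, while the direct model shrinks towards
the achievable signal, so SQI_dp tracks SQI_m more closely than SQI_p
in essentially every seed. This reproduces, at desk scale, the
qualitative ordering that motivates direct spectral prediction of
composite indices. The linear PLSR family does not reach the >0.95
easy limit for the predicted pathway — the log-scale encoding and the
sigmoid scoring are outside its span — which is why the rule ensemble
is the default comparison family.

## Problem sizes and numerics

Experiments run at n = 1000 samples on a 400–2450 nm grid at 10 nm
(206 bands) with 3 replicate scans — large enough for stable split
sizes (562/188/250) and small enough for quick desk runs; the default
1 nm grid (2051 bands) is used when grid resolution itself matters.
Numerical tolerances: SNV normalization to 1e−10; NIPALS stops
extracting when the residual covariance norm falls below ~1e3·eps
(constant targets then predict the training mean); PLSR-vs-OLS
agreement asserted at 1e−6; scoring identities at 1e−12. CSV
round-trips use pandas' round-trip float parsing so written spectra
reload bit-identically. All randomness flows from explicit integer
seeds; fixed seeds give bit-identical tables, spectra, splits and
predictions.
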