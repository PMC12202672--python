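# Methods

## The calibration problem

A transmission FTIR spectrum of a polyester film is, to first order,
`A(ν) = d · ε(ν) · c` (Beer–Lambert): every absorbance carries the same
unknown multiplicative factor `d` (film thickness / path length), which
varies between preparations. Absolute absorbances therefore correlate poorly
with molecular weight across films, and per-spectrum normalizations such as
the Standard Normal Variate (provided here as `snv` / `SNVScaler` for
comparison) remove the scale only approximately once additive detector noise
is present. The quotient of two absorbances of the *same* spectrum cancels
`d` exactly, which is why the pipeline works on the pairwise ratio surface

    R(ν1, ν2) = A(ν1) / A(ν2)

over all wavenumber pairs in the 800–1800 1/cm window — a generalized
internal standard in which every point normalizes every other point.
Absorbances at or below `A = 0.03` (strict comparison) are treated as noise;
ratios touching them are masked invalid rather than computed.

## Suitability selection

For every candidate pair the package computes, across the replicate spectra:

* Spearman ρ between R and M_w (average ranks for ties; tie-free data uses
  the exact `1 − 6Σd²/(n(n²−1))` formula so monotone series give exactly ±1),
* the OLS slope of R on M_w scaled to the unit interval over the training
  range, and
* Pearson r (reported for comparison only — it understates the saturating,
  monotone ratio–M_w trends).

The suitability indicator is the elementwise product `ρ · slope`. Sign
coherence makes it positive for genuine monotone trends in either
orientation; it vanishes for noise (ρ ≈ 0) and for the flat-ratio pathology
(slope ≈ 0: two strongly co-varying bands whose monotone ratio barely moves,
so a model input built on it would amplify small perturbations). Pairs with
suitability > 0.5 are selected.

Decisions taken where the design was open:

* **M_w scaling.** The slope has units of ratio per M_w-unit, so the 0.5
  threshold is meaningless without fixing the M_w scale. M_w is mapped onto
  [0, 1] over the training range (`MwScaler`, mode `unit_interval`), making
  suitability dimensionless and the threshold portable; a `kilodalton` mode
  exists for sensitivity analysis.
* **Candidacy.** A pair is a candidate only if both absorbances clear the
  threshold in *every sample's mean spectrum*; replicate-level flicker at the
  threshold must not change the candidate set. Statistics are then computed
  over the individual replicates (70 observations for 7×10), each replicate
  inheriting its sample's M_w.
* **Computation.** The full map is evaluated vectorized (Spearman as Pearson
  on ranks, ranks taken along the observation axis in bounded-memory chunks);
  a brute-force per-pair loop with the scalar operations serves as the test
  oracle on a small grid.

## Network inputs: capping the selected set

On a dense 1 1/cm grid the 0.5 threshold admits thousands of pairs, almost
all of them neighbouring grid points on the same band pair carrying the same
information. Feeding them all to the network would put the parameter count
far above the number of training spectra. The calibration therefore caps the
network input (default 8 pairs) using three rules, applied to the
suitability-selected set only:

1. **Replicate validity** — both points must clear the absorbance threshold
   in every individual training replicate, not only in the sample means.
   Pairs grazing the threshold are dominated by detector noise (the same
   smallness that inflates their regression slope), and imputing them would
   corrupt the feature.
2. **Signal-to-noise ordering** — pairs are ranked by |slope| divided by the
   feature's pooled within-sample standard deviation. The suitability
   product deliberately contains no noise term, so its top values sit on
   weak-absorbance shoulder points whose large slopes are artefacts of small
   denominators; the SNR ordering prefers ratios of well-measured bands.
3. **Diversity thinning** — a greedy pass keeps a pair only if it differs
   from every already-kept pair by at least 4 1/cm in numerator or
   denominator, so the few inputs are not near-duplicates (which would also
   ill-condition the Jacobian).

With 8 inputs and 5 hidden units the network has 51 parameters against the
56 spectra of the default training split — deliberately under-parameterized
so the fit cannot interpolate replicate noise.

## The network and its training

Architecture: one hidden layer of sigmoid units (3–5 are sufficient for the
smooth saturating trends; the calibration default is 5, `LMRegressor`'s
generic default 4; a second hidden layer is supported), one linear output
unit. Inputs are standardized per feature on the training split; targets are
affinely mapped to [0.1, 0.9] of the training range for conditioning.

The calibration regresses **log10(M_w)** and exponentiates predictions
(a `linear` option exists). Over a ~200× molecular-weight ladder a linear-M_w
squared loss is dominated entirely by the heaviest samples and leaves the
accuracy of the light ones to chance; the log scale balances relative
accuracy across the ladder, which is how such calibrations are used.

Training minimizes the sum of squared residuals with a damped Gauss–Newton
(Levenberg–Marquardt) iteration over the full parameter vector; the Jacobian
is computed analytically by reverse accumulation. The damping factor λ
(start 10⁻³, Marquardt diagonal scaling) is divided by 10 after an accepted
step and multiplied by 10 after a rejection. Stopping: gradient ∞-norm
< 10⁻⁸, five consecutive accepted steps with relative SSE improvement
< 10⁻¹⁰, damping exhaustion (no descent direction at λ = 10¹²), or 2000
iterations. Weights are initialized with the Nguyen–Widrow scheme (hidden
active regions tiling the standardized input range) — without it, early LM
steps routinely jump into sigmoid saturation and strand the run in a poor
local minimum.

Training is restarted from 10 seeded initializations. The deployed restart
is the one with the lowest final SSE regardless of which stopping rule fired:
the strict stationarity tolerances tend to fire inside sharp, poor local
minima, while excellent fits may still be micro-improving when the iteration
budget ends, so gating deployment on the convergence flags would
systematically prefer worse models. The flags are still reported per restart
in the `TrainingReport` as a convergence audit.

Two further calibration-level safeguards:

* **Candidate audit.** The network is fitted 5 times from independent seeds;
  each candidate is scored by its mean squared target-space error on
  training features jittered with their own within-sample standard deviation
  (5 seeded draws), and the least noise-sensitive candidate is deployed.
  Replicates of one sample differ only by measurement noise, so a
  trustworthy fit must map a row and its noise-perturbed copy to nearly the
  same M_w. The audit never touches validation rows.
* **Range guard.** Predictions are clipped to the training log-M_w range
  ±10%: a calibration carries no information outside the ladder it was
  trained on, and an unlucky fit evaluated far outside its plateaus could
  otherwise return absurd magnitudes.

The 80/20 replicate split is stratified by sample (each M_w level
contributes proportionally to validation); with 7×10 replicates this yields
56/14.

## The synthetic-data generator

The generator emulates a PHB alcoholysis ladder measured in transmission:
7 samples log-spaced over 4–780 kDa (dispersity 2.0 in the labels),
10 replicates each, Gaussian bands on the descending 1 1/cm grid 1800→800.
Default bands (centers/σ in 1/cm, amplitudes in absorbance units):

| center | σ | amplitude | role |
|---|---|---|---|
| 1724 | 8 | 0.90 | carbonyl backbone reference |
| 1278 | 10 | (0.90/R_max)·(1 + K/M_w) | ester band with chain-end contribution |
| 1380 | 9 | 0.25 | M_w-independent |
| 1057 | 8 | 0.30 | M_w-independent |
| 1188 | 7 | 0.40 | flat-pair numerator |
| 971 | 7 | 0.20 | flat-pair denominator (ratio ≈ 2 at every M_w) |

End-group concentration scales as 1/M_w, so the 1278 amplitude decays toward
a backbone floor and the carbonyl/ester ratio follows exactly
`R(M_w) = R_max·M_w/(K + M_w)` with defaults R_max = 12 and K = 50 kDa —
values at which the ratio spans ~0.9–11.3 across the ladder, peak absorbances
stay below ~1 AU, and the band sinks to ≈0.08 AU for the heaviest samples.
With additive detector noise of σ = 0.002 AU that makes the replicate scatter
at the top of the ladder comparable to the inter-level differences: the
inverse problem is ill-conditioned above roughly 200 kDa *by construction*
(the analytic sensitivity `dR/dM_w = R_max·K/(K+M_w)²` is exposed by
`inverse_sensitivity`). Each replicate is multiplied by a lognormal
film-thickness factor (σ = 0.05), which cancels in the ratio features but
not, exactly, under SNV — the comparative property motivating ratios.

What the generator does **not** emulate: baseline drift and sloped
scattering backgrounds, band-shape changes with crystallinity, wavenumber
calibration error, detector nonlinearity at high absorbance, and continuous
M_w distributions (labels are discrete levels). Passing tests on this
generator therefore demonstrate the pipeline's mechanics — thickness
cancellation, selection of monotone high-SNR ratios, rejection of the
flat-ratio pathology, the high-M_w accuracy loss — not performance on any
particular instrument's data. Because the levels are discrete and replicate
noise is the only within-level variation, a well-fitted network can
partially "memorize" levels; the accuracy split at 200 kDa is a robust
pattern under the default conditions but individual seeds can produce
unusually small high-M_w errors.

## Problem sizes and runtimes

Defaults used throughout the tests and the reproduction script: 70 spectra
(7×10) on the 1001-point window grid; full suitability maps over ~39 000
candidate pairs computed in seconds; network fits (10 restarts × 5
candidates, ≤2000 LM iterations each) in ~10–15 s; teacher–student checks
use 300 rows with a 5-3-1 network. The complete test suite runs in under a
minute; the reproduction script in about one to two minutes.

## Known limitations

* The suitability threshold 0.5 is calibrated to unit-interval M_w scaling;
  with `kilodalton` scaling the same threshold selects a different set.
* The selected-pair count on dense synthetic grids (thousands) is an
  artefact of grid resolution and band width, not comparable across
  instruments or resolutions.
* JCAMP-DX support covers AFFN `(X++(Y..Y))` tables only (no compressed
  DIF/DUP forms).
* `extract_features` refuses below-threshold pairs at predict time by
  default; the impute option substitutes training medians, which biases
  predictions toward the training mean and is logged loudly for that reason.
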