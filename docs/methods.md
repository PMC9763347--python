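# Methods

## Model and estimation procedure

The package treats a physiological recording as a realization of an
approximately H-self-similar process. For such a process the detail
coefficients of an orthogonal DWT satisfy Var(d_j) ∝ 2^(−j(2H+1)) with
j the level index (j = J−1 finest, 2^j coefficients per level), so the
log2 level energies S(j) fall on a line of slope −(2H+1) and
H = −(slope+1)/2. The slope is estimated by OLS on the pairs (j, S(j));
a Theil–Sen option exists for sensitivity analysis but is not the
default, and the log base is fixed at 2 so that the H relation stays
literal.

Level energies are the classical variance (denominator n) or the
squared sample distance variance ν²(x) = (1/n²) Σ A²_ij with the biased
1/n double-centering. The *squared* form is deliberate: it is
a²-scale-equivariant, so replacing the variance by ν² shifts the
spectrum by an intercept only and leaves the slope — and hence H —
unchanged in expectation. An un-squared (root) form would halve the
slope and break the H relation. The fast implementation reduces all
three pairwise-distance moments to prefix sums over the sorted vector
(O(n log n)); it is used everywhere, with the O(n²) double-centering
kept as the reference oracle.

## The canonical Hurst protocol

`estimate_hurst` composes truncation → detrending → pyramid transform →
spectrum → OLS. Three defaults deserve explanation; all are exposed as
parameters.

* **Periodic boundaries.** The transform uses periodization, which is
  the only boundary mode that keeps W exactly orthogonal with exactly
  2^j coefficients per level — properties the estimator and its tests
  rely on (Parseval to 1e−10, perfect reconstruction).
* **Bridge detrending (`detrend="bridge"`).** A drifting path (fBm
  with H large) ends far from where it starts; periodization sees that
  endpoint gap as a jump discontinuity and plants a handful of very
  large boundary coefficients at every level. These few outliers
  dominate the *variance*-based energies (empirically biasing H by as
  much as −0.4 at H = 0.9) while barely moving the distance variance.
  Subtracting the straight line through the first and last sample
  removes the jump; because every supported wavelet has ≥ 2 vanishing
  moments, the subtracted line is invisible to all interior detail
  coefficients, so nothing else changes.
* **Level selection (`min_level_size=8`, `drop_finest=1`).** Levels
  with very few coefficients contribute log energies with a large
  negative Jensen bias (E log₂ σ̂² < log₂ σ²; about −0.9 at n_j = 4),
  and the finest level carries the initialization bias of using raw
  samples as scaling coefficients. Excluding levels with fewer than 8
  coefficients and the single finest level removes both systematic
  terms. With these defaults the estimator recovers H ∈ {0.3, 0.5,
  0.7, 0.9} on exact fBm (n = 2^14) within ±0.025 mean bias for both
  energy estimators, and averages 0.499 on Brownian motion at the
  1024-sample / 9-level operating point.

`estimate_slope` itself stays a plain regression over whatever levels
the spectrum supplies; the guards live in `estimate_hurst` so that the
bare all-levels protocol remains one call away.

## The contamination experiment

The robustness experiment reproduces the estimator-comparison design:
per replicate a fresh Brownian path (n = 1024, theoretical H = 0.5) is
decomposed (db6, 9 levels), 100 coefficients per level (all of them on
levels shorter than 100) receive additive Gaussian noise, and H is
estimated from both spectra. Here the *bare* protocol is used — no
detrending, all levels in the regression — so the estimators face the
contamination unshielded; Brownian motion's endpoint gap is modest, so
the boundary issue above is immaterial at this operating point.

Noise scaling is a genuinely open choice: the experiment supports
per-level scaling (noise SD = each level's empirical coefficient SD,
the default, making the contamination comparable to signal energy at
every scale) and a global SD. The number of replicates and the scale
are reported in the output metadata.

Measured behavior at the default operating point (200 replicates): the
distance-variance H has a much smaller absolute median deviation from
0.5 (~0.01–0.03) than the variance-based H (~0.12–0.14), confirming
the robustness ordering in median bias. The interquartile ranges of
the two estimators, however, are statistically indistinguishable
(~0.19–0.21 both): with fresh paths the spread is dominated by
path-to-path sampling variability common to both estimators, and this
does not change with the noise scale or with a single-fixed-path
design (`fresh_path=False`). A spread advantage for the distance
variance at this design is therefore not established by this
replication; the corresponding assertion in the acceptance tests is
expected to fail and is kept as-is rather than weakened.

## Synthetic data: what it emulates and what it does not

`simulate_cohort` generates per-subject, per-session fractional
Brownian motion at the group's H, affinely rescaled to a pupil-like
range (mean 3.5, SD 0.3 — the slope is affine-invariant, so the
rescaling is cosmetic), with contiguous missing bursts placed at
random starts until the target missing fraction is reached. Defaults
mirror the targeted study layout: 28 cases vs 22 controls, 8 sessions
of 165,000 samples at 1 kHz, case H = 0.89 vs control H = 0.95 (cases
less regular), 30% missing in 200-sample bursts — a blink-heavy but
plausible pupillometry profile.

The fBm generator uses circulant embedding of the fGn autocovariance
(eigenvalue weights √(λ_q/m) on a complex Gaussian vector, real part),
which is exact in law; its covariance is verified elementwise against
(s^2H + t^2H − |s−t|^2H)/2 in the tests. A Cholesky fallback covers
the (theoretically impossible for fGn, defensively handled) negative
eigenvalue case and tiny n.

What the generator does *not* model: the pupillary light reflex,
task-evoked dilations, trial structure within a session, measurement
quantization, or any physiological difference between groups beyond
the Hurst exponent. Passing the end-to-end tests therefore shows that
the pipeline recovers and classifies *self-similarity differences*
through cleaning, windowing, and averaging — not that real case /
control cohorts are separable, which depends on the actual effect size
in recorded data.

## Pipeline conventions and degenerate inputs

* Cleaning is compaction: masked samples are deleted, never
  interpolated, and sessions > 80% missing are rejected. Windows are
  cut from the compacted signal, so sample times are not uniform
  within a window wherever data were removed — inherent to this
  design, and applied identically to both groups.
* Windows are non-overlapping, default 1024 samples; the per-window
  transform uses 5 detail levels by default (levels j = 5…9 at window
  size 1024, of which j = 5…8 enter the regression under the canonical
  guards). Deeper decompositions are available; at 1024 samples fewer
  than 4 usable regression points makes the OLS unstable and raises.
* Sessions of unequal cleaned length are aligned by truncating to the
  subject's minimum window count, and subjects to the cohort minimum.
* Degenerate windows (constant data → zero energies) yield a masked
  slope, excluded from session averages; a window position masked for
  every session yields a masked feature, median-imputed within class
  at train time and with overall train medians at test time.
* Fisher scores use ddof = 1 sample variances over subjects; zero
  pooled variance gives F = 0 with a warning. Ties in the ranking
  break toward the lower (earlier) window index.
* The 67/33 split is stratified per class with round-half-up counts
  (22 controls → 15 train); the logistic-regression threshold is the
  Youden-index optimum computed on *train* predictions — selecting it
  on test would leak. SVM (RBF, scikit-learn defaults) and KNN (k = 5)
  use their native decision rules; features are z-scored with
  train-fit parameters.

## Problem sizes used in validation

The validation suite runs at desk scale by design: 200 replicates for
the Brownian and fBm recovery checks (path lengths 1024 and 2^14), 200
replicates for the contamination experiment, 500 random vectors
(n ≤ 200) for the fast-vs-naive oracle, transforms up to n = 64 for
the explicit-matrix oracle, and end-to-end cohorts of 30 + 30 subjects
with 8 sessions of 2^13 samples. These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerances while keeping the
whole suite to a few minutes.

## Known limitations

* Hurst estimation assumes the signal is at least locally
  self-similar; the per-window r² is reported so users can check
  linearity of the spectrum rather than trust the slope blindly.
* The distance variance is robust to a minority of outlying
  coefficients, not to pervasive noise: when every coefficient at a
  level is perturbed, both estimators shift together.
* Compaction concatenates across gaps; for signals whose dynamics
  differ sharply before and after long gaps this stitches unrelated
  segments into one window.
* Single-split evaluation on small cohorts is high-variance; the
  harness accepts multiple split seeds, and summaries over seeds are
  recommended for cohorts of tens of subjects.
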