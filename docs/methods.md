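# Methods

## Optical model

The pseudophakic eye is a two-lens thin-lens system.  Distances stay in
millimetres and every vergence term uses `1000·n`, so powers come out in
diopters; the vertex distance is stored in metres because it multiplies
diopters directly.  Defaults: `n_aq = n_vit = 1.336` (the standard
pseudophakic convention) and `b = 0.012` m.  The emmetropic power of a
lens at depth `d` is

    P = 1000·n_vit/(AL − d) − 1000·n_aq/(1000·n_aq/Pc − d)

and a spectacle target `Rx` enters via `S = Rx/(1 − b·Rx)`, replacing
`Pc` with `Pc + S`.  Two inversions are closed-form:

* **Predicted refraction** given an implanted power: chain the post-IOL
  vergence requirement `z = 1000·n_vit/(AL − d) − P` back through the IOL
  plane to the corneal-plane error `S`, then `Rx = S/(1 + b·S)`.
* **Back-calculated lens position** given an achieved refraction: the
  vergence relation is a quadratic in `d`,
  `P·d² + [n′_vit − n′_aq − P(AL + q)]·d + [P·AL·q − n′_vit·q + n′_aq·AL] = 0`
  with `q = 1000·n_aq/(Pc + S)` and primes denoting ×1000.  The root
  inside the anatomically plausible window (1.5, 8.0) mm is taken; if
  both roots are plausible the one closer to 5.0 mm is chosen and an
  `AmbiguousRootWarning` is raised — never a silent pick.  Degenerate
  denominators below 1e−9 mm raise a singular-geometry error.

For the MM formula the corneal power is the unadjusted mean keratometry
`K = (K1 + K2)/2`; the transform is configurable for sensitivity analyses.

## Classical comparators

Each classical formula is its published ELP estimator plus the same
vergence chain with formula-specific internals (keratometers assumed
calibrated with index 1.3375, `r = 337.5/K`):

| formula | ELP estimator | corneal index | AL handling | notes |
| --- | --- | --- | --- | --- |
| SRK/T | corneal height from `r` and corneal width + A-constant offset (`0.62467·A − 68.747 − 3.336`), LCOR above 24.2 mm | `nc − 1 = 0.333` | + retinal thickness `0.65696 − 0.02029·AL` | discriminant clamped at 0 with a warning |
| Hoffer Q | `pACD + 0.3(AL − 23.5) + tan²K + 0.1·M(23.5 − AL)²·tan(0.1(G − AL)²) − 0.99166`, degree-based tangents, `M,G` switching at AL = 23 | K used directly | AL clamped to [18.5, 31] (warning) | vergence depth is ELP + 0.05 mm |
| Holladay I | anatomical ACD `0.56 + r − √(r² − AG²/4)` with `AG = AL·12.5/23.45 ≤ 13.5`, + surgeon factor | `nc = 4/3` | + 0.2 mm | |
| Haigis | `a0 + a1·ACD + a2·AL` | `nc = 1.3315` | unmodified | requires the measured ACD |

The equivalence of this vergence-chain formulation with the published
single-expression forms is verified in the test suite against
independently coded oracles (SRK/T closed form incl. the target-refraction
variant; Hoffer Q forward formula inverted by bracketed root-finding);
agreement is at machine precision.

**Constant optimization.** Single-constant formulas are tuned by Brent
root-finding so the training-set mean prediction error is zero (tolerance
1e−6 D) over published ranges pACD ∈ [2, 8], SF ∈ [−2, 4], A ∈ [110, 125];
an unbracketed root reports the searched interval.  Haigis is an ordinary
least-squares fit of ELPs back-calculated under its own optics on
`(1, ACD, AL)` (full 3-parameter mode by default; an `a0_only` mode keeps
the published slopes 0.4/0.1).  Eyes whose back-calculation has no
plausible root — typically long eyes with very low implanted powers,
where the vergence residual is nearly flat — are dropped and audited;
more than 20% of drops aborts with an error.  AL clamps warn rather than
fail so cross-validation folds survive extreme synthetic eyes.

## The MM effective-lens-position ensemble

Training targets are per-eye ELPs back-calculated from retrospective
outcomes (implanted power + achieved refraction) under the MM optics;
rows without a plausible solution are dropped and audited (>20% is a
data-quality error).  Predictors are exactly `(K1, K2, ACD, AL)`.

The default ensemble (`family="gbrt_linear"`) is a two-stage *ensemble of
regression models*: an OLS baseline in the four predictors, then
gradient-boosted trees (depth 2, 300 estimators, learning rate 0.05,
subsample 0.8, `min_samples_leaf` 20, early stopping with a 15%
validation split and 10-round patience) fitted to the baseline residuals.
Rationale: cohorts of 150–300 eyes yield back-calculated targets carrying
≈0.3 mm of propagated refraction noise; an unconstrained tree ensemble
spends capacity on that noise and can lose to a well-specified linear
comparator, whereas the two-stage design keeps the variance floor at the
linear model's level and lets the tree stage activate only where a
reproducible non-linear signal exists.  A plain gradient-boosted family
(`"gbrt"`) and a bagged-trees family (`"bagging"`) sit behind the same
interface.  Hyperparameters are fixed by configuration and never tuned
per fold, so the cross-validation harness measures the formula, not a
tuner.  One model is fitted per lens model, never pooled.

Predictions are deterministic given (hyperparameters, seed, data), clamped
to the plausible window with a flag, and persist via joblib with a format
version that refuses cross-version loads.  Recommended powers are rounded
to the 0.5 D manufacturing step with the raw value retained.

## Benchmark harness

Monte-Carlo cross-validation: k repetitions (default 100; the shipped
benchmarks and the acceptance script use k = 20, and the replicate-count
property test k = 10, sizes chosen to keep full runs in seconds) of a
random 80/20 split.  Within each repetition the four classical constant
sets are re-optimized *and* the MM ensemble is re-trained on the same
training split; the held-out prediction errors
(`PE = achieved − predicted`, positive = hyperopic surprise) are
accumulated across repetitions, so one eye can contribute several times —
the accumulated-sample convention; a last-repetition-only mode exists
behind a flag.  Failed repetitions are skipped and audited (>10% aborts).
Metrics per formula × axial-length stratum (short < 22 ≤ medium ≤ 24.5 <
long-medium ≤ 26 < long, plus all eyes): MPE ± SD, median PE, PE range,
MAE ± SD, median AE, and % within ±0.5/±1.0/±1.5 D with closed bands
(|PE| equal to the boundary counts as within).

## Statistical battery

All tests run at α = 0.05 on eye-paired columns: Shapiro–Wilk as the
normality screen; one-sample Wilcoxon signed-rank for zero-median checks;
Friedman across the five formulas' absolute errors with pairwise
signed-rank tests of MM against each comparator; Cochran's Q across
within-band indicators with pairwise McNemar tests carrying an
outperformed / underperformed / no-difference label from the discordant
counts.  Signed-rank handling: exact zeros dropped, average ranks for
ties, exact enumeration (a tie-aware dynamic program over doubled ranks)
for n ≤ 25 and the tie-corrected normal approximation above.  McNemar is
the exact binomial below 25 discordant pairs, else chi-square with
continuity correction.  P-values are unadjusted by default (Holm behind a
flag).  Identical-column inputs make the omnibus statistics 0/0 in
library implementations; the wrappers return statistic 0, p = 1 for that
degenerate case.  Known edge: at exactly balanced discordance (b = c) the
doubled exact McNemar p is 1.0 while the continuity-corrected chi-square
cannot exceed ≈0.86 — an artifact of the two-sided doubling rule.

## Synthetic cohorts

Profiles for three lens-model cohorts (monofocal SN60WF n = 265,
monofocal Softec HDO n = 256, trifocal AT LISA tri839 MP n = 160) carry
published marginal summaries (mean, SD, median, range) of age, AL, K1,
K2, ACD plus sex ratio.  (AL, K1, K2, ACD) are drawn from a truncated
multivariate normal with literature-plausible correlations —
corr(AL, ACD) = 0.45, corr(K1, K2) = 0.85, corr(AL, K) = −0.30,
corr(ACD, K) = 0 — then the flat/steep labels are re-ordered so `K1 ≤ K2`
always holds.  Re-labelling and truncation shift the observed means by up
to ~0.1 D, so the latent means are calibrated: an analytic fixed point
for the re-labelled K gap (when the published gap is below the
attainable minimum `0.8·σ_diff`, the latent means are set equal), then
two deterministic pilot rounds (fixed internal seed) subtract the
residual shift.  Generated marginals match the published means to
~0.05 D; the labelled K1–K2 correlation exceeds the latent 0.85 because
ordering induces extra dependence.

Ground-truth ELP: linear `d = 0.9 + 0.40·ACD + 0.08·AL` (Haigis-like) or
non-linear, adding `0.25·tanh((AL − 23.5)/1.5)` and a mild interaction
`0.04·(K − 43.5)·(ACD − 3.2)` — a saturating axial-length bend plus a
joint dependence no single linear model represents; ELP noise SD 0.10 mm.
Surgery is simulated forward: implanted power for the target refraction
at the true ELP, rounded to 0.5 D; achieved refraction computed exactly,
corrupted with 0.35 D Gaussian measurement noise and quantized to
0.125 D.  The refraction noise was calibrated once so that all-eyes
prediction-error SDs land near the 0.5 D scale typical of published
whole-cohort benchmarks (the example run shows SDs 0.40–0.64 across
formulas).  Optically infeasible eyes are skipped with an audit (>1%
errors out).  Age and sex are sampled for completeness but never used as
predictors.

**What the generator does not emulate:** real joint distributions beyond
second moments, surgeon/technique idiosyncrasies, IOL tilt and
decentration, device-specific biometry error, astigmatic axes (only
spherical equivalents), or outcome-dependent selection.  Passing tests
therefore demonstrate internal consistency and the advertised behaviour
*under the stated generative assumptions* — including that the MM
formula's cross-validated advantage holds where its non-linearity
assumption is true by construction — not clinical performance on real
eyes.

## Numerical choices and degenerate inputs

Vergence denominators below 1e−9 mm, zero post-IOL vergence and vertex
singularities raise typed errors naming the failing stage.  Quadratic
back-calculation rejects `P = 0` (degenerate linear case).  Brent
root-finding uses xtol 1e−10 with a re-polish if the objective exceeds
1e−6 D.  The rank of the Haigis design matrix is checked before solving.
Clamping (AL validity ranges, negative discriminants, out-of-window ELP
predictions) always warns and flags, never silently alters or aborts.
Input validation bounds: AL ∈ (15, 40) mm, K ∈ (30, 60) D,
ACD ∈ (1.5, 6) mm, powers ∈ [−10, 40] D, refractions ∈ [−10, 10] D;
`K1 ≤ K2` is not enforced on input (roles are fixed by field name).

## Known limitations

* Published formula variants differ between devices and papers; the
  implementations follow one fixed, oracle-checked published form each.
* The MM ensemble family and hyperparameters are engineering choices —
  the design space (tree ensembles on back-calculated ELPs) is fixed, but
  no claim is made that these defaults are optimal for real cohorts.
* Exact reproduction of any real clinic's benchmark tables is out of
  scope: no per-eye data are available, and all reported numbers here are
  computed on synthetic cohorts.
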