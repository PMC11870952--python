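# Methods

This note documents the models behind each module, the calibration of the
synthetic cohort generator, the numerical conventions, and the places where
the design was genuinely open and a choice had to be made.

## Survey design being emulated

The default calibration describes a nine-species, two-season (rainy/dry)
survey of carnivorous freshwater fish from a tropical floodplain river:
326 specimens across 18 species × season strata (128 rainy, 198 dry), with
per-stratum sample sizes, total length and weight (mean ± SE), condition
factor, hepatosomatic index, muscle T-Hg, and nematode prevalence and mean
intensity. Published stratum summaries of this kind never come with raw
tables, so stratum-level values that were not reported (muscle T-Hg for
four of the nine species, and infection figures for roughly half the
strata) are *synthetic stand-ins*, chosen once so that cohort-level
aggregates are realistic: overall mean T-Hg near 0.31 µg/g ww, a dry
season more heavily infected than the rainy season, and a seasonal Fisher
significance pattern concentrated in the species where it was reported.
They are marked as such in `defaults.py` and should not be read as data.

## Synthetic cohort generator

No distributional forms are published for surveys of this kind; the
generator's forms are the package's own stand-ins:

- **Length** — normal within a stratum, sd recovered from the reported
  standard error as SE·√n, truncated to positive values. The within-stratum
  coefficient of variation is capped at 0.35: two printed length SEs imply
  CVs above 1, biologically implausible for a single species and almost
  certainly typos; the cap keeps those strata sane and makes the
  positive-truncation bias negligible everywhere.
- **Weight** — allometric, W = a·L^b·exp(σ_w ξ − σ_w²/2) with b = 3 by
  default (so CF is length-stable) and σ_w = 0.08. The coefficient *a* is
  solved per stratum so that E[W] equals the target mean weight exactly,
  using E[L³] = µ³ + 3µσ². Per-fish CF then centres on 100·W̄/E[L³]. This
  generally differs from a *reported* mean CF, which averages per-fish
  ratios: the two disagree by a Jensen gap, and for some strata the printed
  (L̄, W̄, CF) triple is mutually inconsistent under any allometric model.
  The calibration test therefore checks CF against its model-implied value,
  and no attempt is made to reproduce printed per-stratum CF/HSI decimals.
- **Liver weight** — HSI-target·W/100 with mean-corrected lognormal noise
  (σ = 0.30), so E[HSI] matches the stratum target exactly.
- **Muscle T-Hg** — lognormal, moment-matched to the stratum mean and
  sd = SE·√n. Concentrations are positive and right-skewed; lognormal is
  the standard choice.
- **Parasite counts** — a hurdle model: infection is Bernoulli at the
  stratum prevalence π, and counts of infected fish are zero-truncated
  negative binomial (ZTNB) with mean equal to the stratum mean intensity µ
  and dispersion k = 1 (strong overdispersion, typical of macroparasite
  burdens). The hurdle factorization gives independent control of the two
  quantities surveys actually report and implies the identity
  mean abundance = π·µ. The underlying NB mean is solved numerically so
  the *truncated* mean equals µ; sampling realizes the truncation by
  rejection.
- **Determinism** — one master seed; every stratum draws from a substream
  keyed by CRC32 of "species|season", so adding, removing or reordering
  strata never perturbs the draws of the others.

What passing tests on this cohort do *not* show: the generator has no
within-stratum length–Hg or size–infection correlation (beyond what the
planted regression mode injects), no spatial or temporal autocorrelation,
no measurement error in morphometrics, and stratum stand-ins where noted.
Results that depend on those features of real data are out of reach of the
synthetic tests.

### Planted regression mode

For coefficient-recovery experiments the generator can override counts with
a planted linear model A = β₀ + β_Hg·Hg + β_CF·CF + ε, ε ~ N(0, σ), with
defaults β₀ = 6.728, β_Hg = 6.109, β_CF = −5.385 and σ = 8.0. The noise
level is derived from the survey scale this model describes: an abundance
SE of 0.47 at n = 326 gives sd(A) = 0.47·√326 ≈ 8.5, of which a fit with
adjusted R² ≈ 0.075 leaves a residual sd of ≈ 8.2. With this σ the
simulated coefficient standard errors (≈ 2.7 for Hg, ≈ 1.0 for CF) closely
reproduce the reported ones — i.e. the planted model has a *marginal* Hg
effect (t ≈ 2.1). A direct consequence, verified by simulation, is that
backward-AIC selection retains the exact {Hg, CF} set in only ≈ 69% of
replicates: a predictor with t ≈ 2 survives an AIC-backward step (threshold
|t| ≈ √2) roughly three times out of four. This is a property of the
survey's own effect size, not a defect of the selector; raising the
retention rate would require assuming less noise than the reported fit
quality allows. Coefficient recovery itself is unbiased at any noise level
(mean refitted β_CF within ±0.3 of −5.385 over 500 replicates). The
recovery experiments use the raw real-valued abundance (no rounding, which
would bias the coefficients); integer counts are produced only when a
cohort table is requested.

## Risk screening

Exposure follows the USEPA non-cancer screening chain with
C = 0.9·T-Hg (the assumed methylmercury fraction of muscle total mercury),
RfD = 0.1 µg/kg/day, and five consumer scenarios: adult (230 g meal,
70 kg), pregnant/lactating women (113 g, 75 kg), and children aged 3–5
(31.2/42.5/48.2 g, 13.4/15.7/21.1 kg). The pregnant/lactating body weight
of 75 kg — *heavier* than the reference adult — is kept as conventionally
printed in this literature, but is worth flagging. Choices:

- CRmw uses the generalized form 7·RfD·BW/(C·MS) rather than the
  adult-specific constant 49, which encodes 0.1·70·7; the adult case
  reproduces the constant exactly, and other scenarios scale with their own
  body weight.
- Whole meals are **floored**, never rounded: CRmw < 1 means the stratum
  should not be eaten even once a week.
- The risk verdict is "risk" iff HQ > 1 strictly; HQ = 1 is "minimal".
- Stratum-level results use the stratum mean T-Hg.
- For any positive concentration, CRmw_raw·HQ = 7 exactly (both derive
  from the same EDI); this identity is asserted in tests for every row.

## Statistical battery

- The normality gate is one-sample Kolmogorov–Smirnov against a normal
  with the sample's own mean and sd. Estimating the parameters from the
  sample makes the test anticonservative (the Lilliefors caveat); it is
  used anyway because it matches mainstream practice in this field, and
  every dispatch records its gate outcome in `decision_path`. Bartlett
  screens variance homogeneity; a zero-variance group fails the gate
  outright (Bartlett is undefined there).
- All tests are two-sided at α = 0.05, with no multiple-testing
  correction by default (matching field practice for descriptive
  surveys).
- Mann–Whitney uses exact enumeration for total n ≤ 10 without ties and
  the tie-corrected normal approximation otherwise.
- Fisher's exact test is two-sided by the standard small-p rule (sum of
  probabilities of all tables no more likely than the observed one).
- Partial Spearman rank-transforms all three series and applies the
  first-order partial correlation formula, with p from the t approximation
  on n − 3 df.
- PCA standardizes by default (the variables mix units) and
  eigendecomposes the correlation matrix; the sign convention makes each
  component's largest-magnitude loading positive. Missing data: pairwise
  complete for correlations, listwise for PCA and regression.
- Backward selection uses the Gaussian least-squares convention
  AIC = n·ln(RSS/n) + 2(k+1). Only AIC *differences* drive the selection,
  so the absolute values are not comparable across software conventions. A
  zero-residual fit gets a floored RSS (1e-300) to keep AIC finite.

## Histopathology

Ten lesion categories (ST, LY, MM, FB, HH, NH, NC, AP, HC, BC) scored 0–3.
The conventional severity ranges 0.0–0.4 / 0.5–1.4 / 1.5–2.4 / 2.5+ leave
gaps (e.g. 0.4–0.5); boundaries are realized at the gap midpoints (0.45,
1.45, 2.45) so binning is total on [0, ∞) and all conventional exemplar
values land in their stated bin. Clustering is agglomerative on Euclidean
distance with complete linkage — the default of the common R heatmap
tools — and is configurable. The default of four sampled livers per
species gives 36 clustered specimens for a nine-species survey.

## Phylogenetics

- Identity/p-distance exclude gap and N sites *pairwise* rather than
  deleting whole columns: short (~485 bp) amplicon alignments lose too much
  signal under complete deletion. Published tree-building tools do not
  always state their deletion convention; this one is explicit.
- Jukes–Cantor: d = −(3/4)·ln(1 − 4p/3), refusing p ≥ 0.75 (saturation).
- Neighbor joining is the classical Saitou–Nei algorithm. Determinism
  contract: Q-criterion ties break to the lowest (row, column) pair in
  current matrix order, and negative branch lengths are clamped to zero
  with a logged warning. On additive matrices the output tree reproduces
  every input distance to < 1e-9 (tested against a brute-force tree-metric
  oracle on random trees up to 8 taxa).
- Bootstrap resamples alignment columns with replacement, rebuilds JC + NJ
  per replicate, and reports integer percentage support for each internal
  bipartition of the point-estimate tree. Replicates with a saturated or
  incomparable pair are skipped and counted (warning above 5%); supports
  are normalized by successful replicates.

## Mercury QC

LOD = 3·sd(blanks) (n−1 denominator); RSD = 100·sd/mean over duplicates;
recovery = 100·mean(measured)/certified value with a configurable 90–110%
acceptance band (recovery is conventionally reported but rarely
thresholded; the band is this package's rule). Duplicates are averaged
before any downstream use. Sub-LOD samples are flagged and substituted at
LOD/2 — the common ecotoxicology convention, configurable — and the RSD
rule is not applied to them, since precision at the detection limit is
noise-dominated. Note 100·0.379/0.382 = 99.2%, the recovery this
arithmetic yields for the classic DORM-3 example values; sources quoting
99.8% for the same numbers presumably averaged per-replicate recoveries or
rounded differently.

## Problem sizes

Test and pipeline problem sizes are chosen for desk-scale runs: Monte-Carlo
calibration checks use 1 000–20 000 draws, the regression-recovery
experiment 500 cohorts of n = 326, bootstrap examples 50–200 replicates on
6–8 taxa (the CLI default remains 1 000), and simulated alignments 300–
100 000 sites depending on the precision the check needs. The full suite
runs in well under a minute apart from the 500-cohort experiment (~10 s).

## Known limitations

- Aggregate survey figures of this kind are often internally inconsistent
  (overall abundance vs total/examined; weighted seasonal prevalences vs
  the printed overall; printed intensity vs abundance/prevalence beyond
  rounding). The package computes each index from its definition and does
  not force agreement with any printed aggregate.
- The generator matches first moments per stratum; it does not attempt
  joint distributions across variables beyond the allometric link.
- Multiple-sequence alignment is an input, not a feature: sequences must
  be pre-aligned.
- The statistical battery fits ordinary least squares to count-valued
  abundance (as field practice does); a count GLM would be the more
  principled model and is deliberately out of scope.
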