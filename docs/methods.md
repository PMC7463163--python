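# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the package. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Connectivity model

Each participant contributes a time × channel table: four hippocampal seed
channels (left/right head and body) and one channel per target ROI. The
connectivity statistic for an edge (seed, target) is the sample Pearson
correlation of the two band-limited signals, Fisher-transformed
(z = atanh r). For white-noise channels of length T the null z is
approximately N(0, 1/(T−3)), which the property tests exploit.

**Band-pass filter.** The band 0.01–0.1 Hz is the conventional resting-state
window: it excludes scanner drift and high-frequency physiological noise
while retaining the slow BOLD fluctuations that carry functional coupling.
The realisation is a 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`, Gustafsson edge handling), i.e. zero phase with
the squared magnitude response. The contract — passband amplitude ≥ 0.9,
attenuation to ≤ 0.1 an octave beyond the edges — is verified by sinusoid
tests rather than by pinning a particular transfer function, since any
reasonable realisation of the band is acceptable. The upper edge must stay
below Nyquist (1/(2·TR); 0.167 Hz at TR = 3 s). No additional detrending,
nuisance regression or volume discarding happens here: denoising belongs to
upstream preprocessing, outside this package's inputs.

**Atlas.** The target atlas is consumed purely as a table
(`roi_id, x, y, z, network`); row order is canonical and fixes the column
order of every matrix. The 13-network partition treats "uncertain" as a
network like any other, because it participates in the contingency analysis
and can carry findings (e.g. in depression-score overlap checks). The
canonical 264-ROI table is distributed by its authors and is not bundled;
`synthetic_power264_atlas()` generates a synthetic stand-in with the
canonical network sizes (DMN 58, SOM 35, VIS 31, … summing to 264) and
placeholder coordinates, which no statistic reads. Any user-supplied table
with the right columns is treated as ground truth.

## Edge statistics

Binary design: per edge, a two-sample t on the z values, pooled variance by
default (Welch by flag), two-tailed p. Direction is the sign of
mean z(SMD+) − mean z(SMD−): "weaker in SMD+" means a negative difference
regardless of the sign of z itself; absolute-magnitude alternatives were
considered and rejected as changing the question. Continuous design: per
edge, Pearson r with the severity score, two-tailed p from the t transform
with df = n − 2. Sensitivity analyses use the first-order partial
correlation (closed form, df = n − 3) controlling one covariate at a time
(depression score; right whole-hippocampal volume raw or adjusted).

Significance is strict (p < α, α = 0.05 by default); ties at exactly α have
probability zero for continuous statistics. Degenerate edges (zero variance
across participants) are flagged, carry NaN statistics and are excluded
from every count rather than aborting the run. No edge-level multiplicity
correction is applied: with 264 targets per seed, α·264 ≈ 13.2 false
positives per seed are *expected* under the null, and that expectation is
the explicit benchmark against which raw per-seed counts are read. The
formal correction happens at the pattern level below.

## Permutation inference

Both procedures share one null: group labels (binary) or severity scores
(continuous) are shuffled across participants — preserving group sizes and
the score multiset by construction — and the **entire** per-edge battery is
recomputed for each of the B shuffles. Reshuffling only the significance
flags would be wrong: the statistic is a function of the data through the
tests, so the null must rerun the tests.

- *Difference score*: D = count(focal) − Σ count(other three seeds),
  with directional counts at α_edge. One-sided p = (1 + #{D* ≥ D})/(B + 1).
- *Network contingency*: per-network directional counts for the focal seed;
  per-network one-sided p against the same null; Benjamini–Hochberg FDR
  across the 13 networks. By default all 13 networks form the FDR family
  (including zero-count and atlas-absent networks, which get p = 1);
  restricting the family to nonzero-count networks is available by config.

The Monte-Carlo convention (1 + #{≥})/(B + 1) is one-sided ("greater than
chance"), never returns zero, and implicitly includes the identity
permutation; shuffles are drawn independently (sampling the permutation
group with replacement), standard Monte-Carlo practice. p therefore lives in
[1/(B+1), 1], and with B = 10 000 the resolution floor is ~1e-4. On cohorts
small enough to enumerate every group assignment, the Monte-Carlo p agrees
with the exhaustive p (tested on a 4+4 toy, all C(8,4) = 70 assignments).

The focal seed defaults to the seed with the maximum observed directional
count — the same post-inspection rule the analysis design implies — but can
be fixed in advance. Note the statistical caveat: the permutation p is
computed for the chosen focal seed and does not adjust for the selection of
that seed; type-I-error calibration tests therefore fix the focal seed a
priori. With a bounded count statistic the p floor is attainable only when
no permutation ties the observed count; near-identity relabelings of very
small cohorts can reproduce a saturated count, which is why power tests use
realistic cohort sizes.

Permutations are vectorised: a (B, n) batch of shuffled labels/scores is
reduced against the (n, 1056) z matrix with two matrix products per batch
(sums and sums of squares), making B = 10 000 at full study scale run in
under a second on one CPU.

## Volumetrics

Each of the 26 measures is residualised on age and eTIV by OLS
(`volume ~ 1 + age + etiv`) fitted on **all** participants pooled — not per
group — so group differences in residuals remain interpretable; residuals
are exactly orthogonal to both covariates and sum to zero, which implies
n₁·mean₁ + n₂·mean₂ ≈ 0 for the group means of residuals (a useful
consistency check on any reported summary table). Raw vs standardised
covariates change nothing about residuals; no age×eTIV interaction is
included.

Group tests are one-tailed with the a priori direction "smaller in SMD+".
Pooled-variance Student's t is the default because recomputing the worked
examples from published group summaries reproduces the printed p-values
best under pooled t (0.0412, 0.00875, 0.0293, 0.0344 for left whole
hippocampus, CA1, tail, CA4); one printed value (CA3, 0.0251) matches the
Welch variant instead, so Welch is available by flag. `ttest_from_summary`
recomputes t/df/p from (mean, SD, n) pairs alone and agrees with the
raw-data route to 1e-10 when the raw data reproduce the summaries.

FDR (Benjamini–Hochberg step-up, via statsmodels) is applied to the
subfield family only; whole-hippocampus measures are tested on their own at
0.05, mirroring the stated testing hierarchy (whole first, then subfields
as the corrected family). Severity correlations are one-tailed for the
predicted inverse relationship.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline was designed for;
its defaults are those conditions, not tuning knobs.

**Phenotypes.** 24 SMD− and 29 SMD+ participants. Ages N(71.9, 8.5) clipped
to [55, 95]; education N(16.1, 2.3); eTIV N(1.45e6, 1.4e5) mm³; sex 36%
male; GDS drawn from the empirical frequencies of a low-symptom cohort
(32:10:5:5:1 over scores 0–4). CCI: SMD− uniform on [12, 15]; SMD+
shifted-geometric above the threshold (p = 0.135, mean ≈ 23), clipped at a
severity ceiling `cci_max` = 41 — the top of the observed range in cohorts
of this kind; the questionnaire maximum of 60 is essentially never reached
and the ceiling also bounds the feasible severity-slope effects. The group
label is derived from the score, so the classification invariant
(SMD+ ⟺ CCI ≥ 16) holds by construction.

**Time series.** One standard-normal latent factor per network per
participant (T = 190 timepoints at TR = 3 s by default: a 10-minute scan
with 10 volumes discarded upstream). A target in network j is
ℓ·F_j + √(1−ℓ²)·ε with loading ℓ = 0.7; a seed is Σ_j c_j·F_j + √(1−Σc²)·ε
with base coupling c = 0.25 to every network. All channels have unit
variance, so the population edge correlation is exactly c_j·ℓ (0.175 at
defaults, a realistic hippocampo-cortical coupling). Effects subtract
group_delta (SMD+ only) or cci_slope·(CCI−12) from chosen (seed, network)
couplings; configs are rejected if any coupling can leave [0, 1) or the
couplings' sum of squares reaches 1 (which would break the unit-variance
normalisation). An optional white `noise_sd` scales all correlations by
1/(1+noise_sd²); it defaults to 0 so the closed form stays exact. "Strong
effect" in the power checks means group_delta = 0.2, i.e. the affected
edges drop from r ≈ 0.175 to ≈ 0.035.

What the generator does **not** emulate: hemodynamic autocorrelation,
motion and physiological artefacts, spatial smoothness, inter-individual
coupling heterogeneity, and non-Gaussian tails. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
block-covariance model, not that real preprocessing artefacts are handled.

**Volumes.** Per measure: intercept + β_age·age + β_eTIV·eTIV +
group_delta·1[SMD+] + N(0, sd). Default intercepts track typical automated
segmentation magnitudes (whole hippocampus 3400 mm³, CA1 620 mm³, …), age
slope −0.4%/year of the measure's size, eTIV slope proportional to size,
noise ~7% of size. This additive structure is exactly what the adjustment
regression assumes, so OLS recovery of a planted group_delta is an oracle
test.

**Randomness.** A single root seed; phenotypes, volumes and per-participant
time-series streams are independent children of it (numpy `SeedSequence`
spawning), so any subset regenerates identically.

## Pipeline

Input formats are plain text: phenotype CSV, volume CSV, per-participant
time-series TSVs, atlas TSV; the generator writes exactly these, so
simulated and real cohorts are interchangeable. Group labels are always
re-derived from the CCI column and the configured threshold. Modes: binary,
continuous (CCI), gds (exploratory, positive-direction counts and overlap
with the CCI-flagged edge set), or all. Each stage writes its result files
(edge tests, difference-score JSON, network-contingency CSV, adjusted
volumes, volume tests) and `report.json` echoes the configuration (minus
the output path) so identical runs produce byte-identical results — the
run log alone carries wall-clock timestamps. The demographic screening
section (t-test on age, rank-sum on ordinal variables, chi-square on sex)
is reporting plumbing, not part of the inferential core. Item-level GDS
data are not part of the input contract, so no item-10 subtraction check is
performed.

## Problem sizes in the test suite

The suite favours the smallest cohorts that still exercise each property:
toy atlases (5–30 targets) for unit tests; 500 replicate null cohorts at
n = 12+12, 60 targets, B = 500 for type-I-error calibration; 50 seeded
full-scale cohorts (24+29, 264 targets, B = 1000) for power; B = 10 000
only where p resolution matters (exhaustive-agreement and the worked
example). These sizes give the calibration checks binomial standard errors
of about 1 percentage point while keeping the whole suite around a minute.

## Known limitations

- Image-space processing (segmentation, denoising, registration, ROI
  extraction) is out of scope; the pipeline trusts its tabular inputs.
- The permutation p for the auto-selected focal seed is conditional on the
  selection rule (see above).
- Edge t-tests assume exchangeability across participants; within-scan
  autocorrelation affects the per-edge null only through the z variance,
  which the permutation procedures absorb but the nominal per-edge p does
  not.
- The bundled 264-ROI atlas is synthetic (real coordinates are not
  redistributable here); analyses of real data should supply the real
  table.
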