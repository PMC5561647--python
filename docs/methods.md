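# Methods

`flxsig` implements an end-to-end analysis for discovering a peripheral
(PBMC) protein biosignature of antidepressant response in the chronic
corticosterone mouse model: behavioral emotionality scoring, responder
classification, spectral-count protein inference, per-protein Poisson
differential testing, and a three-criterion signature-selection rule.

## Behavioral emotionality score

Each animal runs a three-test battery twice (before and after the
antidepressant phase): elevated plus maze (EPM; open-arm time and entries),
novelty suppressed feeding (NSF; latency to feed, right-censored at the
10-min test limit, with home-cage food intake as an appetite control), and
splash test (ST; grooming duration).

Every scored measure is standardized against the vehicle control group of the
*same session*,

    z = s · (x − μ) / σ,

with μ, σ the control mean and unbiased (n−1) SD, and s ∈ {−1, +1} chosen so
that larger z always means higher emotionality (s = −1 for open-arm time,
open-arm entries and grooming; s = +1 for NSF latency). Measure z-scores are
averaged within each test, and the three per-test means are averaged again,
so each test carries equal weight regardless of how many measures it
contributes (EPM contributes two). Food intake is never scored. The control
group is therefore self-normalizing: its mean composite is 0 by construction,
and the composite is invariant under any affine rescaling of a raw measure.

Censored NSF latencies enter the z-score at the ceiling value; no survival
modeling is applied inside the composite (survival analysis of NSF is a
separate, descriptive device and out of scope here).

Same-session referencing (rather than pooled or session-1 controls) was a
genuinely open choice; it was adopted because it absorbs session-to-session
drift that would otherwise masquerade as treatment effect.

## Responder classification

A fluoxetine-treated animal with relative decrease
`(pre − post) / pre ≥ 0.5` in its emotionality composite is a responder
(CORT/Flx-R); below that, a non-responder (CORT/Flx-NR) — the clinical
50%-improvement convention. The rule is undefined for a non-positive
baseline, so animals with `pre ≤ 0` are labeled not-applicable; by default
they stay in the cohort-rate denominator (counted as non-response), so the
rate is responders over all treated animals. An optional exclusion band
around the cutoff (default width 0, i.e. off) can mark borderline animals as
ambiguous.

"Most affected" animals for proteomics (defaults 5 CORT/V, 7 Flx-R, 6
Flx-NR) are ranked deterministically: CORT/V and Flx-NR by descending
post-treatment emotionality (most persistently affected), Flx-R by descending
relative decrease (clearest responders), ties broken by animal id. No
published criterion pins this down; the ranking is configurable.

## Protein inference and spectral counting

Starting from peptide-spectrum-match tables (peptide sequence and E-value,
protein accession(s) and E-value, sample, spectrum count):

1. **Filter**: keep PSMs with peptide E-value < 0.01 (strict); keep
   accessions with protein E-value < 1e−4 and ≥ 2 distinct retained peptide
   sequences; drop contaminants by list/prefix. Removal is iterated because
   dropping an accession can orphan peptides. If the protein E-value is
   absent it is reconstructed as the product of the accession's unique
   peptide E-values.
2. **Group**: accessions sharing ≥ 1 retained peptide merge into protein
   groups (connected components of the accession–peptide bipartite graph);
   within a group, any accession with ≥ 1 peptide specific to it is a
   *subgroup* — one subgroup is one reported protein. Group ids are the
   lexicographically smallest member accession, making the grouping
   deterministic and row-order independent.
3. **Count**: a subgroup's value in a sample is the summed spectra of its
   specific peptides ("unique-only"; no spectrum is counted twice). An
   optional "group-level" mode adds one row per multi-member group carrying
   the shared-peptide spectra. Distinct peptides are counted by sequence
   string equality.

## Differential testing

Spectral counts are modeled per protein as Poisson with a group factor
(CORT/V, Flx-R, Flx-NR):

    y_ij ~ Poisson(exp(β_g(j) + o_j)),

optionally with a log total-count offset `o_j` (off by default). With a
single categorical factor the MLE rates are (offset-weighted) group means and
the likelihood-ratio deviance against the intercept-only model is closed-form,

    D = 2 Σ_g S_g log(λ_g / λ_0),

referred to χ² with (groups − 1) df. All-zero rows are degenerate (p = 1,
flagged). This is a fixed-effects model: the per-protein group test described
has no random-effect structure. Group-effect p-values are BH-adjusted across
proteins; pairwise contrasts (R vs CORT/V, NR vs CORT/V, R vs NR) use
two-sided pooled-variance Student t-tests at raw p < 0.05, mirroring the
two-tier reporting convention (BH for the omnibus test, raw t-tests for
contrasts). Effect directions are `δ_g = log2((mean_g + c)/(mean_CORT + c))`
with pseudocount c = 0.5.

Under complete-null simulation at the study's sample sizes (5/7/6) and rates
5–50, the deviance test's rejection rate at p < 0.05 sits in the 4–7% band
and BH keeps the q < 0.05 fraction at the nominal level (checked in the
acceptance tests at 5000 proteins).

## Venn partition, correlations, signature rule

Significance sets R (Flx-R vs CORT/V) and NR (Flx-NR vs CORT/V) are
partitioned into common / solely-R / solely-NR by exact set algebra. Pearson
correlations of (δ_R, δ_NR) over these subsets quantify how
response-independent most fluoxetine effects are.

The response signature keeps proteins that are simultaneously (i)
significantly different between responders and non-responders, (ii)
significantly different between responders and untreated CORT animals, and
(iii) changed either in the *opposite direction* in the two treated groups,
or in the same direction with *greater amplitude* in responders —
i.e. proteins whose movement away from the corticosterone profile tracks
behavioral improvement. Amplitude is compared on the pseudocounted log2
scale as point estimates (no statistical superiority test — the rule as
stated is a point-estimate comparison); deltas within 1e−12 of zero count
as neither opposite nor greater. Output order is p(R vs NR) ascending, ties
by accession. Both significance criteria share α = 0.05.

## Clustering and ordination

For visualization-grade structure, counts are transformed `log2(count+0.5)`
and row-standardized (a protein reads as above/below its own average), then
proteins and animals are clustered independently with Euclidean distance and
UPGMA (average linkage); merge trees are exported as Newick. PCA is computed
on the animal profiles (centered); per-group clouds on the first two scores
are summarized as bivariate-normal (mean, covariance) densities for contour
drawing. The exact preprocessing behind published heatmaps of this kind is
rarely stated; log + row-standardization is the field convention for
above/below-average heatmaps and is configurable.

## Synthetic data: what it emulates, and what it does not

**Behavior.** Three arms (vehicle 14, CORT 12, CORT+fluoxetine 46 by
default), two sessions. Each measure has a nominal control location/SD
(open-arm time 60±20 s, entries 10±3, grooming 80±20 s, NSF latency
log-normal with median 90 s censored at 600 s, food 5±1.2 mg/g). A latent
emotionality state — group shift + stable per-animal trait + per-measure
noise — maps onto each raw scale in the measure's direction. Defaults:
corticosterone shift 1.5 nominal-SD on every scored measure;
`measure_noise_sd = 0.6` scaling all residual variation (30% of its variance
a stable animal trait, 70% iid), so the observed composite effect is ≈ 2.5
control-SD — the large separation this model shows on composite scores.
Latent responders (fraction 0.652) fully reverse the shift at session 2;
latent non-responders instead drift a further 0.5 nominal-SD (≈ +0.8
z-points) worse. Because all residual terms scale with `measure_noise_sd`,
the 50%-rule classification converges to the latent labels as noise → 0.
Not emulated: test order effects, sex, litter/cage structure, floor effects
other than non-negativity and the NSF ceiling — so passing recovery tests
shows the *rule* behaves, not that real cohorts are this clean.

**Proteome.** Proteins get a baseline rate uniform in 5–50 expected spectra
and one of six planted classes: null (0.62), common fluoxetine effect
(0.22), responder-only (0.04), non-responder-only (0.08), and two signature
classes — opposite direction (0.02) and same-direction/greater-amplitude
(0.02, non-responder amplitude 0.4× the responder's). The mix mirrors the
structure the analysis expects: common changes dominate, solely-NR changes
outnumber solely-R, true response-signature proteins are a small minority.
Planted |log2FC| defaults to 1.5. Counts are Poisson (matching the model); a
negative-binomial overdispersion option exists, OFF by default, to probe
robustness. The PSM layer plants protein counts on protein-specific peptides
(2–5 per protein, Dirichlet-split) and adds low-rate shared peptides mapping
to accession pairs to exercise grouping; peptide/protein E-values are drawn
below the default thresholds so identification filtering is exercised by
dedicated fixtures, not by the generator. Not emulated: peptide
detectability/length biases, missingness beyond Poisson zeros, batch or
run-order effects.

## Numerical and degenerate-input choices

- Strict inequalities at all E-value thresholds (a peptide at exactly 0.01
  is excluded).
- Zero-variance t-tests: p = 1 for equal means, p = 0 (flagged degenerate in
  spirit) for unequal means.
- All-zero count rows: deviance 0, p = 1, flagged.
- Constant proteins in clustering are centered but not scaled (no 0/0).
- UPGMA ties are resolved by the linkage implementation's deterministic
  cluster-index order; correctness is asserted via cophenetic distances,
  which are tie-order invariant.
- The pipeline seeds the behavioral and proteomic generators from a single
  run seed; manifests contain no timestamps, so identical config + seed is
  byte-identical.

## Problem sizes

Statistical checks run at sizes chosen to make their Monte-Carlo error small
relative to the asserted bands while keeping the suite quick: 5000 proteins
for null calibration (binomial SE ≈ 0.003 on a 4–7% band), 2000 for
signature recovery, 500 treated animals for the responder-rate recovery
check, ≤ 50 proteins / ≤ 12 leaves / n ≤ 8 for the brute-force oracle
comparisons (exact enumeration grows combinatorially).

## Known limitations

- Spectral counting is a coarse quantification; the Poisson model ignores
  overdispersion between biological replicates (by design, matching the
  analysis implemented; the generator can produce overdispersed data to
  measure the cost).
- No real cohort data ship with the package, so validation rests on
  synthetic ground truth and closed-form worked examples, not on an
  original experimental matrix.
- The "most affected" ranking and the ambiguous-animal exclusion are
  configurable conventions, not published rules.
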