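# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Exposure classification

A bird is classed *low* exposure iff `plastic_count < 5` pieces **and**
`plastic_mass < 0.5` g; otherwise *high*. Field definitions of this rule are
often phrased disjunctively in both directions ("either … or" for low,
"either higher" for high), which is contradictory for mixed cases (e.g. 3
pieces at 2 g). We resolve it conjunctively for *low* because (i) lavage
systematically under-recovers plastic when a large bolus blocks the stomach,
so ambiguous birds are more plausibly high-exposure, and (ii) the rule is
then monotone: adding plastic can never demote a bird from high to low (a
property-tested invariant). Both thresholds are configurable
(`ExposureRule`).

## Baseline comparisons

Continuous morphometrics (body mass g, wing mm, culmen mm, head+bill mm) are
compared with Welch's *t* (Satterthwaite degrees of freedom), avoiding the
equal-variance assumption; right-skewed variables (plastic mass) are first
Box-Cox transformed. Piece counts use a Poisson GLM with log link; for the
two-group design the MLE rates are the group means, so the deviance
chi-square has the closed form

    G² = 2 Σ_g n_g ȳ_g log(ȳ_g / ȳ),   df = 1,

which the tests cross-check against a statsmodels GLM fit. Deviance is the
default report; a Wald chi-square is available. The family of baseline
p-values is adjusted by step-down Holm–Šídák:
adj_(i) = max_{j≤i} 1 − (1 − p_(j))^(m−j+1), clipped at 1.

Box-Cox λ is chosen by profile likelihood over the fixed grid
[−2, 2] in steps of 0.1 (coarse enough to be stable at n ≈ 30, fine enough
that the transform is effectively continuous in its effect); non-positive
data are shifted by a constant (reported alongside λ) before transforming.

## Differential abundance

Missingness in detection-limited LFQ data is missing-not-at-random: a value
is absent mostly because the protein's abundance fell below the limit in
that run, so absence itself discriminates groups. The stage therefore tests
twice:

1. **Presence/absence** — two-sided Fisher exact test on the 2×2
   detected/not × group table, for every detected protein.
2. **Abundance** — restricted to proteins detected in strictly more than
   70% of samples in *both* groups (">" read strictly; a protein seen in
   exactly 7/10 fails a 0.70 threshold). Two-sided Mann–Whitney *U* on the
   non-missing values: exact enumeration when both groups have ≤ 10
   observations and no ties, otherwise the tie-corrected normal
   approximation with continuity correction. Test-suite enumeration oracles
   bound the approximation error at well under 0.01 in the decision-relevant
   tail.

The fold-change estimator is log₂(median_high / median_low) of non-missing
intensities — robust, and consistent with a rank-based test; no
transformation is applied before ranking since ranks are invariant to
monotone transforms. Benjamini–Hochberg runs separately within the
presence/absence family (all detected proteins) and the abundance family
(filtered proteins only): the two tests answer different questions and
merging their families would dilute both. A filtered protein with fewer than
two non-missing values in a group is flagged, reported without a statistic,
and excluded from the FDR family.

**Z-scores** standardize each protein row over its non-missing entries
(sample SD, ddof = 1); constant rows are emitted as zeros and flagged.
**Scaled PCA** treats samples as observations and proteins as variables,
each variable centred and scaled to unit variance after log₂ transform.
Missing values are handled by policy: the default `complete-proteins` drops
proteins with any missingness (no imputation enters the ordination);
`half-minimum` imputes below-limit cells with half the protein's observed
minimum, the conventional detection-limit stand-in.

## Background-constrained permutation enrichment

For a nonmodel organism the expected pathway composition of a random
protein set cannot come from genome-wide annotation tables; it comes from an
empirical background — by default the proteins detected in the low-exposure
group (configurable to the filtered set). With background size N, pathway
membership K within it, and m significant proteins of which k fall in the
pathway, each of B resamples draws a uniform m-subset of the background
without replacement and counts pathway members; the add-one upper-tail
p-value is p = (1 + #{k* ≥ k}) / (B + 1), never zero at finite B. As B → ∞
this converges to the hypergeometric tail P(X ≥ k | N, K, m) — verified
against the exact tail in the tests — and the permutation form is kept
because it generalises to statistics without a closed-form null.

Resampling is over *protein sets*, not sample labels: the quantity under
test is the pathway composition of a fixed significant set against
background annotation frequencies; relabelling samples would re-run the
differential stage, conflating two inferences. The default test is
upper-tail (over-representation); a two-sided flag doubles the smaller
tail. BH adjustment runs within each annotation source (GO, KEGG,
WikiPathways) as separate families. The reported "enrichment fraction" is
k/K: significant-set members over background members per pathway.

Because the null count is discrete, the add-one p-value is conservative for
small pathways: P(p ≤ α) ≤ α, with the gap roughly the point mass at the
rejection boundary (~pmf ≈ 0.1/σ of the hypergeometric SD σ). The
calibration experiments therefore use large pathways (σ ≈ 11), where the
null is effectively continuous and the rejection rate sits near the nominal
5%; for small pathways the test errs on the safe side, never
anticonservative.

## Dose response

Tissue cohorts show more within-group spread than plasma, so the tissue arm
regresses each protein's (Box-Cox transformed) abundance on the continuous
plastic burden in grams: OLS, two-sided slope *t* test, BH across the
screened set. The dose covariate stays in grams (untransformed); the
square-root mass scale is a display convention only and lives in the
plotting layer. Box-Cox is monotone increasing, so slope signs on noiseless
monotone data are transform-invariant (tested). Constant mass is rejected
(no contrast); constant abundance is flagged degenerate with p = 1.

## ΔΔCt relative expression

Replicate wells (triplicates typically) are averaged arithmetically on the
Ct scale, with a flag when the replicate SD exceeds 0.5 cycles. ΔCt
subtracts the housekeeping Ct within the same sample, cancelling per-sample
loading/plate offsets exactly (a tested invariance). ΔΔCt is referenced to
the *mean* ΔCt of the reference (low-exposure) group rather than a single
calibrator sample — the natural choice for a group-comparison design — and
fold change is 2^(−ΔΔCt), i.e. amplification efficiency fixed at 2.0;
efficiency-corrected (Pfaffl) quantification would need standard-curve data
that the design does not include. Group tests are linear models on ΔCt
(the log2-scale quantity), optionally Box-Cox transformed.

RNA quality gates: concentration ≥ 100 ng/µl, A260/280 in [1.9, 2.1],
A260/230 in [2.0, 2.2], boundaries inclusive. The concentration gate is the
universal low-concentration *exclusion*; a literal `< 100 ng/µl` inclusion
mode exists behind a flag for protocols written that way.

## Synthetic cohort generator

`simulate_cohort` draws the latent log₂ abundance of protein i in bird j as

    z_ij = μ_i + δ_i·1[j ∈ high] + ε_ij,   ε ~ N(0, σ²)

with μ_i uniform over a 6-log₂-unit dynamic range starting at 16 (typical of
plasma LFQ after search-engine normalisation), σ = 0.8 log₂ units of
within-group variation, and δ_i = +1 log₂ for affected intracellular
proteins, −1 log₂ for affected secreted proteins (30% of proteins affected;
45% of proteins secreted, plasma being secretome-rich). The reported
intensity is 2^z, and the value is MISSING iff z < 16.5 (the detection
limit) — missingness is thus strictly MNAR and group-informative for
affected proteins. Defaults: 13 low / 18 high birds, 800 proteins.

Plastic burden: low birds get 0–4 pieces and near-zero mass; high birds get
a lognormal mass (clipped to [0.65, 45] g, spanning roughly two orders of
magnitude) with piece counts scaled to mass — the heavy tail is what powers
the dose-response arm. Annotations: 20 pathways of 10–40 members across
three sources; ~30% of pathways are "truly enriched", drawing half their
members from affected proteins. Ground truth (per-protein class and effect,
per-pathway enrichment flag, baseline means) is returned for
parameter-recovery tests. All randomness flows through one
`numpy.random.Generator` keyed by a single integer seed.

What the generator does **not** emulate: peptide-level roll-up, batch and
run-order effects, correlated protein co-regulation, heteroscedastic
intensity noise, partial annotation coverage, or the real cohort's exact
values. Passing recovery tests therefore demonstrates that the statistical
machinery is correct and calibrated under the assumed signal structure, not
that any particular biological dataset will behave this way.

`simulate_ct` draws triplicate Ct values with a shared per-sample loading
offset (so only housekeeping-normalised quantities are meaningful); a gene
with true log₂ effect e has its high-group Ct lowered by e cycles, hence
expected ΔΔCt = −e and fold 2^e.

## Problem sizes in the validation suite

The test suite and acceptance script use: one study-scale signal cohort
(13/18 birds, 800 proteins) for recovery; a 2,600-protein null cohort so
that ≥ 2,000 filtered proteins enter the Mann–Whitney calibration; 200
enrichment datasets × 10 large pathways (N = 2,000, m = 1,000, K = 500,
B = 999) for enrichment calibration; 2,000 replicates for the Poisson GLM;
20 toy instances (N ≤ 30) at B = 10,000 for the hypergeometric oracle; and
30 simulation replicates for ΔΔCt recovery. These sizes put Monte-Carlo
error comfortably inside each check's tolerance while the whole suite runs
in well under a minute on one CPU.

## Known limitations

- Intensities are assumed cross-run normalised upstream; the package never
  renormalises.
- The Fisher and Mann–Whitney stages treat proteins independently; no
  covariance-aware multiplicity correction is attempted.
- Enrichment requires the significant set to lie inside the background; a
  protein significant by presence/absence but undetected in the low group
  is excluded from the default (low-group) background test.
- The dose-response arm fits straight lines after Box-Cox; genuinely
  nonlinear dose-response shapes are out of scope.
- The permutation enrichment p is conservative for small pathways (see
  above); interpret near-threshold q-values for 5–10-member pathways
  accordingly.
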