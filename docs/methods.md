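# Methods

## Scope and data model

The package analyzes a promoter regulatory element two ways: inferential
effect sizes for semiquantitative assays of element variants (gel-shift
band densities, reporter-gene ELISA), and taxonomically weighted
conservation of the element across an aligned set of mammalian promoter
sequences. Raw inputs are replicate tables (film id, variant, replicate,
signal), an aligned multi-FASTA with a species taxonomy, a rooted or
unrooted newick tree with branch lengths, and literal TF-site strings.
Promoter coordinates run ..., −2, −1, +1, +2 with no position 0; regions
are closed intervals; the PRE is −76..−47 (30 positions).

## Assay standardization

**Film standardization (subtractive scale).** Autoradiography films have
arbitrary exposure offsets and scales. Within each film every signal is
replaced by (x − film mean)/film SD, after which the film's control
(wildtype) value — averaged if the control is replicated on the film —
is subtracted from all of the film's values. Both additive and
multiplicative film effects cancel exactly, and the control's adjusted
mean is exactly 0 by construction. A film with zero signal SD or a
missing control is a hard error, not a silent NaN.

This standardization divides by the *across-variant* spread within a
film, which contains the true between-variant signal as well as noise.
Consequently the estimated standardized effects are an attenuated,
monotone transform of the generating effects δ: simulations recover
direction and ordering of effects exactly, and the pipeline is verified
replicate-by-replicate against an independent direct-formula
recomputation, but the numeric value of *g* should not be read as an
unbiased estimate of δ.

**Ratio normalization.** Reporter levels are divided by a positive
per-record covariate (cotransfection efficiency control), then all values
are divided by the control's adjusted mean, fixing the control at
exactly 1. Nonpositive signals or covariates are domain errors.

**Normality gate.** ANOVA residuals (values minus group means) are tested
with Anderson–Darling (p-value via `statsmodels`). If p < α and the data
are strictly positive, a Box–Cox transform is applied with λ chosen by
maximum likelihood on the grid [−3, 3] in steps of 0.01; reported group
means are back-transformed, while inference (ANOVA, Dunnett) runs on the
transformed scale. The gate only ever fires for ratio-scale assays, since
subtractive-scale values are signed.

## Effect sizes

A balanced one-way ANOVA (equal n per group, k ≥ 2, n ≥ 2) pools the
within-group mean square MSerror with df = k(n−1). That single pooled
variance is the denominator for every effect size in the assay:

- **Hedges g** per variant:
  g = (m_j − m_c)/√MSerror · J(n), where
  J(n) = Γ(df/2) / (Γ((df−1)/2)·√(df/2)) with df = 2n−2 is the
  small-sample bias correction (J(3) ≈ 0.7979). The delta-method SE
  √(2/n + g²/(2·df_error)) is reported alongside.
- **Ψ (root-mean-square standardized effect)** per assay:
  Ψ = J(n)·√( Σ_j (m_j − GM)² / ((k−1)·MSerror) ), the spread of the k
  group means around the grand mean in √MSerror units, on the same scale
  as g via the same J(n). Ψ = 0 iff all means coincide. The (k−1)
  denominator (rather than an F-based estimator) is used because it is
  the form consistent with the reproducible published assay-level values;
  F statistics are computed and reported but are sensitive to whether a
  transformation preceded them.
- **Dunnett's multiple t.** Each variant is compared to the control with
  statistic |m_j − m_c|/√(2·MSerror/n). The two-sided equicoordinate
  critical value for k−1 simultaneous comparisons uses the
  equicorrelated (ρ = ½, balanced-n) multivariate t: conditioning on the
  shared control variate and the pooled scale reduces the joint
  probability to a 2-D integral, evaluated with 257-point Gauss–Legendre
  rules (z ∈ [−9, 9]; scale over the essential χ support) and inverted by
  Brent root finding to absolute tolerance 1e−4. For k = 2 this collapses
  to the Student t quantile (2.776 at df = 4, α = 0.05); for k = 8,
  df = 16 it agrees with a 10⁶-draw Monte-Carlo multivariate-t quantile
  within 0.01, and the realized family-wise error on null simulations is
  ≈0.03–0.05 at α = 0.05.

MSerror = 0, n = 1, or a missing control raise errors. When only
published summary tables are available, `sqrt_mserror_from_g` recovers
the pooled scale from one row's (mean, g) pair; this is a fixture helper
for table reproduction, not a pipeline stage. Reproduction from printed
2-decimal means carries visible rounding error (up to ~0.03 on a g of
order 1), and two published columns (the PC12 reporter column and the
PC12 band-I column, both printed with asymmetric standard errors
indicating a transformation) do not satisfy the shared-scale identity
relating printed means and g; they are excluded from identity checks.

## Correlation meta-analysis

Paired effect sizes (g from binding, g from expression) are correlated
with the product-moment r, the control's (0, 0) pair included — inclusion
reproduces the published coefficients, and the pair is a genuine datum
(the control's effect is identically zero on both axes). Significance of
r ≠ 0 is the one-sided sign-crossing fraction of a case bootstrap
(default B = 100,000, seed mandatory): resample the n pairs with
replacement, recompute r, and report the fraction of the bootstrap
distribution on the opposite side of zero from the observed r.
Degenerate resamples (zero variance on an axis) are skipped and counted.
At r_observed = 0 the p converges to ½; strongly correlated pairs at
n = 8 yield p < 0.05 in ≥95% of simulations. Two bootstrap distributions
are compared by percent overlap of relative-frequency histograms on a
common 50-bin grid spanning the pooled range (the bin count is recorded
in output metadata; overlap is symmetric and shift-invariant but, like
any histogram statistic, mildly bin-sensitive).

## Taxonomic weighting and information content

Species receive base weights (positive integers, larger in densely
sampled clades), converted to raw weights 2^(1/base weight) and
max-normalized within the analysis scope so the largest working weight is
exactly 1 — a mild down-weighting that partially compensates for clade
over-representation. Clade scopes are nested: primates ⊂
euarchontoglires ⊂ boreoeutheria ⊂ eutheria ⊂ mammals.

Per column, weighted base frequencies are computed over non-gap rows
(gap rows carry no frequency mass; weights renormalize to the non-gap
total), and information content is R_i = 2 + Σ_b p_b log₂ p_b bits. No
small-sample correction is applied, so a homogeneous column scores
exactly 2 bits and a uniform column exactly 0. Columns with fewer than 2
non-gap residues are undefined and excluded downstream. The SD of R_i is
a weighted bootstrap over species rows (default B = 1000, seeded).
Weighting satisfies a duplication invariance: duplicating a species and
halving its weight changes no frequency, information, or homology value.

**Window track.** Per-column R_i is averaged in a sliding window
(default 100 nt, roughly the internucleosome distance), over columns not
gapped in any primate row; the CI is the Student t interval on the
per-column values within the window, optionally Bonferroni-adjusted for
clade-level contrasts. Centers are reported in reference coordinates.

**Homology.** Per region column, the weighted fraction of species
(reference included, matching itself) whose residue equals the
reference's; gaps count as mismatches, so lineage-specific insertions
depress homology as they should. The region value is the mean over
columns with its SE over columns.

**Logos.** Letter height = p_b·R_i, so heights sum to the column's
information; bootstrap SDs provide error bars. Region totals sum R_i over
the reference-coordinate columns only (columns inserted relative to the
reference are not counted), bounded by 2 bits per position.

## Molecular-clock outlier test

The tree is rooted on the single edge separating two complementary
monophyletic tip sets (e.g. marsupials vs. eutherians); the root sits at
the midpoint by default (configurable fraction), preserving all path
lengths — including when the tree is already rooted on that edge, where
the two root branches are treated as one edge and the root repositioned
along it. Root-to-tip distances (sums of branch lengths) are compared to
their mean ± t_{1−α/(2m), N−1}·SD with m defaulting to the tip count;
tips above the band are "faster", below "slower". Because each tip
contributes to the mean and SD it is compared against, the test is
conservative under the null (realized family-wise error ≈0.01 at nominal
α = 0.05 in simulation); it is a screening heuristic, not an exact test.
A single 5×-rate terminal branch on a 35-tip clock tree is flagged
essentially always; note that with N tips the largest possible
studentized deviation is (N−1)/√N, so no single outlier can be flagged
below ~13 tips at these settings.

## Site scanning

Catalog entries are literal forward-strand strings (lowercase letters are
flanking context, matched case-insensitively as part of the site; variants
supply 3′ plasmid context when scanning such entries). Scanning is exact
substring search reporting all offsets; reverse-complement scanning is
available behind a flag. Variant diffs are set algebra on (factor, site)
pairs: deleted = scan(wt) \ scan(variant), created = scan(variant) \
scan(wt). Southwestern bands match factors whose molecular weight lies in
band ± 10% of the band estimate (closed interval, monotone in the
tolerance). Literal-string diffs reproduce the published per-mutant PuF
site assignments exactly; factor-level published diff tables derived from
matrix-based scanners are broader than literal-string results for
multi-string or context-dependent factors, and are not asserted beyond
the single-string PuF case.

## Synthetic data

The generators encode the study design: 8 variant groups in triplicate
(one exposure per film, 3 films) with film offset SD 0.5, scale SD 0.1,
and unit residual SD for densitometry; lognormal multiplicative noise
(default σ 0.3) and a Uniform(0.5, 2) covariate for reporter ratios; a
35-taxon nested taxonomy (9 primates, 9 further euarchontoglires, 9
further boreoeutherians, 5 further eutherians, 3 marsupial-level tips)
evolving a 528-nt sequence by uniform substitution (default 0.05 per
site per branch) with a 30-nt block at −76..−47 substituting at 0.25×
the flank rate, optional marsupial-only insertion; and ultrametric
coalescent trees of depth 1 in which coalescences are confined to the
older 75% of the depth so every terminal branch is at least 0.25·depth —
without that floor, random trees give many near-zero terminal branches
and terminal-rate perturbations would be undetectable by construction.
What the generators do not emulate: correlated noise across variants on
a film, realistic indel processes, context-dependent substitution, or
non-independence between the binding and expression assays. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to those real-data features.

## Numerical choices and degenerate inputs

- Box–Cox grid [−3, 3] step 0.01, ML criterion, gate α = 0.05.
- Dunnett integration: 257-point Gauss–Legendre per axis, χ support cut
  at 1e−12 tails; critical-value tolerance 1e−4; values cached per
  (k, df, α).
- Bootstraps and simulations take mandatory integer seeds
  (`numpy.random.default_rng`); identical seeds give identical results.
- Hard errors (never NaN): zero film SD, missing control, unbalanced
  ANOVA, n = 1, MSerror = 0, nonpositive ratio data, <2 non-gap residues
  per column, position 0 or out-of-span coordinates, negative branch
  lengths, non-bipartitioning clade splits.
- Test problem sizes: 2,000-replicate null calibrations, 10⁵-rep
  bootstraps, 10⁶-draw Monte-Carlo oracle, 100–200-replicate recovery
  runs — chosen to give Monte-Carlo error well inside each asserted
  tolerance while keeping the default suite fast.

## Known limitations

- The film standardization estimates attenuated effects (see above);
  comparisons are meaningful within and between assays analyzed the same
  way, not against raw-scale effect sizes.
- Published-table reproduction inherits 2-decimal input rounding
  (±0.01–0.03 on g and Ψ) and is impossible for columns whose printed
  means were back-transformed.
- The overlap statistic depends on the bin count; the default (50) is
  recorded in output metadata.
- The clock test assumes independent, approximately Gaussian tip
  distances; shared internal branches violate independence, one more
  reason it should be read as a screen.
- Conservation analyses consume an existing alignment; alignment and
  tree estimation are upstream of this package.
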