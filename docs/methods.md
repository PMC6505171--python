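# Methods

## The model

A quantitative trait (days to heading, DTH) in a biparental selfing cross
is controlled by a small number of loci with additive effects, optional
dominance, and optional pairwise epistasis.  For a plant with genotype
class `g_l ∈ {0, 1, 2}` (dosage of the second parent's allele) at locus
`l`:

    DTH = baseline + year_effect(year)
        + Σ_l a_l · s_l(g_l) + Σ_l d_l · [g_l = 1]
        + Σ_(l,m) offset_lm[g_l, g_m]
        + Normal(0, noise_sd)

where `s_l(g)` is −1 for the homozygote of the parent whose allele
shortens the trait, +1 for the other homozygote and 0 for the
heterozygote; `a_l ≥ 0` is the additive effect in days, `d_l` the
heterozygote deviation from the homozygote midpoint, and `offset_lm` a
3×3 matrix of additive offsets indexed by the two-locus genotype classes.
A line's value is the mean of its phenotyped plants.  All analysis
statistics operate on line means whenever line structure exists.

Transmission is Mendelian with the Haldane map function: crossovers per
chromosome per meiosis are Poisson with mean map-length/100 (no
interference), positions uniform on the genetic map, so the recombinant
fraction at distance *d* cM is `(1 − e^(−2d/100))/2`.  Alleles are
parental-origin labels tracked jointly at all marker and trait-locus
positions.

## The simulated study design

The `study_preset` reproduces a tail-selection design: 248 F2 plants from
a single F1; 132 random F2 plants each found an F3 line; F3 lines are
phenotyped (six plants each) and the 15 earliest plus 15 latest lines
homozygous at the conditioning locus (*Hd1*) are selfed to F4; F4 lines
are genotyped at three plants each over a 1402-marker ddRAD-like panel
with a 20 % per-call dropout rate.  Markers called in ≥ 80 % of plants are
retained ("reliable"), then collapsed to line-level consensus calls: a
line is called homozygous only when every non-missing plant call agrees;
any disagreement is reported as heterozygous (a segregating line), and a
line with no calls is missing.  The F4 founder is one random plant of the
selected F3 line (the design is modelled as one founder per line).

Preset architecture: six loci with effects 5.0 (chr 4), 3.0 (chr 10),
2.0 (chr 6), 1.8 (chr 1), 1.5 (chr 2) and 1.25 days (*Hd1*, chr 6); the
second parent (Kitaake) carries the shortening allele on chromosomes 4,
10, 6 and 2, the first parent (A58) on chromosome 1 and at *Hd1*.  These
effect sizes are configuration anchored to the reported MGV ranges, not
measured constants.  One epistatic pair: the A58 homozygote at the chr 1
locus combined with the Kitaake homozygote at the chr 10 locus gains an
extra −4 days, making that combination the earliest.  Baseline 80 days;
year effects 0 / −10 / −11 / −4 days for 2013–2016 (the F3 year headed
~10 days earlier than F2, the 2016 season later than 2015); residual noise
SD 2 days.  Physical coordinates follow genetic ones at a constant
300 kb/cM so the 3.5-Mb clustering rule is exercisable.

What the generator emulates: complementary minor-QTL architecture, selfing
heterozygosity decay (1/2)^(g−1), tail selection conditioned on one locus,
genotyping from few plants per line, ddRAD-like missingness, year effects.
What it does not: real linkage-disequilibrium block structure (ddRAD SNPs
arrive in clumps at restriction sites; simulated markers are uniform),
genotyping error (only dropout), interference in recombination, G×E beyond
additive year shifts, and selection other than phenotype-tail truncation.
Consequently the simulated scan flags more linked chains of markers than
the sparse clumped panels of real data would, and passing tests show
correct statistical behaviour of the methods — not that a particular real
dataset would yield a particular flag count.

## Statistical choices

* **Distortion test**: Pearson χ² of the homozygote counts against 1:1,
  heterozygous/missing calls excluded, df = 1, upper-tail p.  Markers with
  no homozygous calls in scope carry an `untestable` status.  Flagging is
  at raw p < α (default 0.05); a Benjamini–Hochberg column is reported but
  never used for flagging.  Scope is configurable: `pooled` (one test over
  all samples), `either_population` (flag if either tail is distorted; the
  default) and `per_population` (the conservative conjunctive reading —
  every testable tail distorted).  Under the null the pooled test's size
  is close to nominal for ≥ ~40 lines; the either-tail scope roughly
  doubles the marker-wise false-flag rate at the 11–15 homozygote counts a
  15-line tail yields — this is inherent to testing two small samples per
  marker and is reported, not hidden.
* **Call-rate filter** retains markers genotyped in ≥ 80 % of samples
  (reading "appeared in more than 80 % of plants" as a reliability
  threshold; the threshold is configurable).
* **Homozygote contrast**: Welch's t-test (unequal variances), requiring
  ≥ 2 lines per class; otherwise `untestable`.
* **MGV**: `A = |B − C|/2` over line means.  The alternative definition
  via the deviation from the overall mean equals `(B − C)/2` only for
  equal class sizes; the half-difference is taken as canonical.
* **Clustering**: markers sorted by (chromosome, bp) and chained while the
  running span ≤ 3.5 Mb; chains below `min_size = 2` are reported as
  unclustered singletons, never silently dropped.  Representative = member
  with the largest MGV, ties to the smaller bp.
* **Epistasis**: 2×2 homozygote cell means of line means;
  `Δ = (m[A,A] − m[A,B]) − (m[B,A] − m[B,B])`.  Significance by
  Freedman–Lane permutation: residuals of the additive (two-main-effects)
  least-squares fit are permuted and added back to the fitted values
  before recomputing Δ, with `p = (1 + #{|Δ*| ≥ |Δ|})/(n_perm + 1)`.
  Permuting raw phenotypes would also destroy the main effects and makes
  the interaction p conservative whenever main effects exist; the residual
  scheme gives an approximately uniform p under a purely additive model,
  which the suite verifies by simulation.  A two-way ANOVA is available as
  a cross-check.  Degenerate (constant) phenotypes give p = 1.
* **Pipeline focus set**: downstream two-locus scanning and MGV-weighted
  line scoring use the top `n_top_loci = 6` cluster representatives by
  MGV — the number of loci the original design carried forward; requiring
  homozygosity at every representative of every cluster would leave no
  eligible line.

## Numerical and calibration notes

* The χ² upper tail is the asymptotic approximation.  Against full
  multinomial enumeration at totals ≤ 12 the approximation is accurate to
  ≤ 0.17 in absolute p wherever either p ≤ 0.1 (the inference region);
  in the bulk of the distribution at tiny totals the discrete exact p can
  exceed the asymptotic p by much more (up to 0.68 at total 1).  The test
  suite pins exactly this envelope rather than pretending pointwise
  agreement.
* Tie-breaks are deterministic everywhere: line-mean ties in tail
  selection break by line id; representative MGV ties break to the
  smaller bp.
* All randomness flows from `numpy.random.default_rng` seeded by the run
  configuration; identical seeds reproduce every table byte for byte
  (hashes recorded in the run manifest).

## Problem sizes used in the verification experiments

Simulation-based checks use sizes chosen a priori by power analysis:
estimator recovery uses 200 replicates of 500 unselected F2 plants; scan
calibration uses 1000 fully unlinked markers in 50 unselected F4 lines
(enough lines that the discrete test size is near nominal); scan power
uses 200 replicates per effect size of the full 248/132/15+15 selection
design; epistasis detection uses 200 replicates of 2000 F2 plants
genotyped at the six preset loci (sized for ≥ 95 % predicted top-rank
probability at Δ = 4 days); the end-to-end check uses 100 full preset
replicates.

## Known limitations

* No interval mapping or LOD-based QTL models — the method is count- and
  mean-based by design.
* MGV estimates at markers are attenuated by marker–QTL recombination and
  inflated for loci participating in epistasis (the offset leaks into the
  marginal class means); rank order, not magnitude, is the robust output.
* Tail selection makes within-tail allele frequencies non-independent
  across linked markers; flagged markers therefore arrive in chains and
  cluster counts exceed the number of true QTL.  Interpretation should
  rest on the strongest clusters and their MGVs.
* The study-file adapter assumes a wide marker-by-line sheet and a long
  phenotype sheet; column layout and call symbols are configurable but
  unverified against the original files, which are not redistributable.
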