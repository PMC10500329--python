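# Methods

`antheat` implements a comparative analysis of heat tolerance and the
heat-stress transcriptome across six ant species — four desert species (two
*Cataglyphis*, one *Melophorus*, one *Ocymyrmex*) and two temperate
outgroups (*Formica*, *Myrmica*), spanning the Formicinae and Myrmicinae
subfamilies.  This note records the models, the numerical choices, and what
the synthetic data do and do not establish.

## Survival dose-response

Tube-level assays expose groups of workers to a fixed temperature for a
fixed time; deaths per tube are binomial.  Death probability is modelled as

    logit P(death | T) = beta0 + beta1 * T,        LT50 = -beta0 / beta1.

The fit is a binomial GLM with logit link, solved by IRLS (deviance
tolerance 1e-8, at most 100 iterations).  Complete or quasi-separation is
common in these assays — a steep species can go from 0% to 100% kill
between adjacent tested temperatures — and is detected by any of: failure
to converge, |beta1| > 15 per degC, a slope z-score below 2 (a nearly flat
likelihood along a diverging direction), or a perfect alive/dead split in
dose order.  Separated data are refit with Firth's Jeffreys-prior
penalization (score modified by the hat-matrix leverages), which gives
finite, slightly shrunken estimates; the fit is flagged `method="firth"`.

The LT50 standard error uses the delta method with gradient
`(-1/beta1, -lt50/beta1)` on the coefficient covariance; the 95% CI is
`lt50 ± 1.96 se`.  Delta-method (not Fieller) intervals were chosen as the
standard construction behind the ratio test below; the policy is isolated in
one function and swappable.

**Ratio test.** Two species' LT50s are compared through the log ratio:
`se(log LT50) = se(LT50)/LT50`, the variances add (independent fits), and
`z = log(LT50_A/LT50_B) / se` is standard normal under the null of equal
LT50s.  The test is exactly symmetric under swapping the species.

**Upper thermal limit (UTL).** The operational definition is the highest
tested temperature whose survival does not differ significantly from the
best-surviving group.  A one-way ANOVA runs on tube-level survival
proportions (raw, no arcsine transform); Tukey HSD contrasts each
temperature against the reference group — the one with the highest mean
survival, ties resolved toward the lowest temperature — using the
studentized-range distribution on the ANOVA mean square error.  Testing
"against 100%" literally would compare against a zero-variance constant, so
the best-surviving group stands in for full survival.  Degenerate inputs
(all tubes identical) return the highest tested temperature with a flag.

**Decline width** is `t_zero - t_high`, where `t_high` is the highest
temperature with mean survival >= 0.90 and `t_zero` the lowest with mean
survival <= 0.05.  The 0.90/0.05 thresholds operationalize "from about 100%
to about 0%" and are configuration parameters; non-monotone survival yields
a warning, and a side that never crosses its threshold is reported as
undefined with the reason.

## Expression response

**TMM normalization.** Between-sample scaling factors follow the trimmed
mean of M-values as published: reference sample = the one whose
75th-percentile count fraction is closest to the sample mean; per sample,
M (log2 ratio of count fractions) and A (average log2 abundance) are
computed over transcripts nonzero in both sample and reference; 30% of M
and 5% of A are trimmed from *each* tail (rank-based, average ranks on
ties); the factor is 2 to the precision-weighted mean of the surviving M
values, with weights from the asymptotic binomial variance
`(N-x)/(Nx) + (Nr-xr)/(Nr xr)`.  Factors are rescaled to geometric mean 1.
The implementation reproduces Bioconductor edgeR's `calcNormFactors(method
="TMM")` to 1e-6 on a frozen test matrix.  Normalized values are counts per
million on the TMM-effective library size (library size x factor).

**Differential callers.** The original study intersects two external
pipelines; this package keeps that consensus design self-contained with two
built-in callers of deliberately different character:

1. *NB exact-style test* (`de_test`).  A common negative-binomial
   dispersion is estimated by the method of moments — the mean of the
   per-gene `(s2 - mu)/mu^2` over genes with adjusted mean > 50, where that
   ratio is nearly unbiased, falling back to the pooled moment equation
   when few genes qualify; floored at 1e-4.  Per transcript, the HS and NHS
   count totals are compared conditional on their sum: `P(S_A = a | total)
   ∝ f_NB(a; mu_A, phi/n_A) f_NB(total-a; mu_B, phi/n_B)`, and the
   two-sided p sums the probabilities of all splits less likely than the
   observed one plus half the ties (mid-p, which removes the conservatism
   of discrete exact tests; null p-values pass a KS uniformity check in the
   suite).  Totals above 20,000 switch to the normal approximation of the
   same conditional law.  log2FC is the ratio of TMM-CPM condition means
   with a 0.5 pseudo-value.
2. *Moderated t on log2(CPM + 0.5)* (`de_test_logcpm`).  Gene-wise pooled
   variances are shrunk toward the median gene variance with 10 pseudo
   degrees of freedom.  At four replicates per condition an unmoderated
   t-test cannot reach the FDR <= 1e-3 regime regardless of effect size;
   the moderation supplies the missing degrees of freedom the way
   empirical-Bayes expression tests do.

Both callers report Benjamini-Hochberg FDR.  All-zero transcripts get
(log2FC 0, p 1).

**Consensus filter.** A transcript is differentially expressed (a DET) iff
FDR <= 1e-3 in *both* callers, the two log2FC estimates share a sign, and
the mean absolute log2FC is >= 2.  Sign concordance is required because a
"consensus" transcript with opposite directions in the two callers is
uninterpretable.  Transcripts present in only one table are excluded and
counted.

**HSP panel.** Transcripts are matched case-insensitively against the six
literal search substrings (Hsp70, Hsp 70, Heat shock protein 70, and the
90 counterparts).  Per family the representative isoform is the match with
the highest mean normalized expression across all samples; the family's
differential flag records whether any member passed the consensus filter.

**Profiles and strategies.** The responsive profile bins the DET percentage
of the full transcriptome at 0.3% and 5% — cut-points chosen to separate
the weak (0.12/0.14%), medium (0.60/1.53%) and strong (8/12.71%) published
fractions; both are configurable.  The strategy call then combines habitat
and evidence: desert + weak profile + no HSP induction = constitutive
(chaperones already high in controls); desert + medium/strong profile +
HSP induction = reactive; temperate species are temperate-like by
definition; anything else is unclassified with its evidence listed.  The
percentages use the full transcriptome size as denominator, which is what
reproduces the published fractions.

## Cross-species overlap

DET lists are reduced to unique, meaningful annotation names: trimmed,
case-folded, deduplicated, with unannotated entries and any annotation
containing "uncharacterized protein" dropped.  Name matching is exact after
this normalization — no fuzzy or partial matching, mirroring the purely
computational comparison (the original study's subsequent manual curation
is out of scope).

The significance of an observed overlap k between two species uses a
Monte-Carlo null: each iteration draws the same number of *transcripts*
(not names) uniformly without replacement from each species' full
transcriptome, reduces both draws to unique meaningful names, and records
the overlap; 10,000 iterations by default.  Sampling transcripts first
matters because isoform redundancy makes names non-uniform.  The empirical
p is `(1 + #{null >= k}) / (N + 1)`, never zero; "expected" and "(sd)" in
the pairwise table are the null mean and standard deviation (ddof 1).  Each
species gets its own seeded stream keyed by the sorted pair label, so the
test is exchangeable: swapping the two catalogs reproduces identical
results.  On toy universes where every name is unique the null mean has the
closed form `s * (nA/|A|) * (nB/|B|)`, used as an oracle.

The transcriptome-size vs DET-count association is a plain Pearson
correlation with the t-based two-sided p.

## Orthogroup categories and restricted genes

Orthogroups (an OrthoFinder-style table is the input; orthology inference
itself is out of scope) are classified from their species-presence pattern
with precedence V -> IV -> II/III -> I -> mixed_partial:

- **V** exactly one species present;
- **IV** two or more species, all one genus (the *Cataglyphis* pair here);
- **II** / **III** two or more species, all Myrmicinae / all Formicinae;
- **I** all study species present;
- **mixed_partial** spans both subfamilies without covering every species.

The five published categories do not cover cross-subfamily partial
orthogroups; they are treated as conserved (presence in both subfamilies
implies an ancestral gene), a choice the classifier makes explicit rather
than silently folding them into a numbered category.  Genes inherit
restricted status (categories IV/V) or conserved status (I/II/III/
mixed_partial); catalog genes in no orthogroup are unassigned and excluded
from enrichment by default (restricted genes are defined via
lineage-specific *orthogroups*, not singletons; a flag can include them).

Per species, a 2x2 table {DET, non-DET} x {restricted, conserved} is tested
with the two-sided Fisher exact test (point-probability summation; the
suite checks it against a full enumeration over fixed margins to 1e-12).
The odds ratio uses the Haldane 0.5 correction only when a cell is zero,
flagged.  The orthology summary reports per-species and study-wide counts
and percentages; a counts-level constructor allows computing the summary
arithmetic directly from published tables, including an override for the
study-wide species-specific total where a source's per-species breakdown
does not add up to its stated total.

## Synthetic studies

The generator emits complete studies in exactly the formats the readers
consume, with a ground-truth record and an audit pass that re-derives the
truth from the emitted files on every run (shared-name counts, category
presence patterns, mean/log2FC consistency).  One master seed spawns one
child seed per stage via `numpy.random.SeedSequence` in a fixed order
(survival per species, transcriptomes, orthogroups, counts per species), so
stages are independently regenerable and the whole study is bit-reproducible.

Default design (the study conditions):

- **Assay**: 7 temperatures (39-51 degC in 2-degree steps) x 6 tubes x 10
  workers; binomial deaths on the species' logistic curve.
- **Species**: true LT50s 44.83, 46.0, 49.83, 46.8, 42.0, 39.91 degC.
  Logit slope 5/degC for the abrupt-decline species — at that steepness
  survival one 2-degree grid step below the LT50 is ~98-99%, so the UTL
  lands one step below the LT50 and the survival crash spans two degrees,
  matching the printed pattern — and 1/degC for the two gradual-decline
  species (a six-degree decline).
- **Transcriptomes**: published sizes at 1/20 scale (1,936-4,239
  transcripts) for desk-scale runtime; 55% unique names, 70% of them drawn
  from a 3,000-name cross-species pool, 25% "uncharacterized protein"
  rows, redundant isoform names for the remainder.  Seven HSP70/HSP90
  names are always included so every species has chaperone isoforms.
- **Counts**: NB with gene-wise log-normal means (meanlog 4, sdlog 1.5) and
  common dispersion 0.1; 4 HS + 4 NHS replicates; library depths uniform
  within +-30%.  Stress genes (HSP-annotated transcripts first) are
  chaperone-like and well expressed (meanlog 5.5, sdlog 0.8).  Reactive and
  temperate-like species shift stress-gene HS means by 2^3 (30% of them
  down-shifted); constitutive species lift stress-gene means by e^2 in
  *both* conditions with no shift, so their true DET set is empty.
  Stress-gene counts per species track the published DET fractions at
  scale (13, 50, 50, 35, 250, 540).
- **Orthogroups**: 1,200 orthogroups with category mixture I 26%, II 3%,
  III 1%, IV 2.6%, V 26.9%, mixed 40.5% (shaped after the published
  category counts); 1 + Poisson(0.3) genes per present species, consumed
  from the catalogs without reuse; leftover genes stay unassigned.

What the synthetic data do **not** emulate: read-level noise and mapping
ambiguity, gene-wise dispersion trends, GC/length biases, annotation errors
and partial name matches, per-species assignment-rate differences, and
correlation between orthogroup category and expression.  Passing tests
therefore establish the correctness and calibration of the statistics under
a faithful generative model of the designs, not the biological conclusions
on real data; the published percentages that are pure arithmetic are
reproduced exactly from the printed counts.

## Numerical notes and limitations

- Empirical p-values are never 0 by construction; Fisher p of a degenerate
  (empty-DET) table is 1 with a flag.
- The UTL is grid-valued: it can only be one of the tested temperatures,
  and its operational definition is an interpretation of "not significantly
  different from full survival".
- The NB exact-style test plugs in an estimated common dispersion; at very
  small transcriptome sizes the dispersion estimate is noisy and the test's
  calibration degrades gracefully toward conservative.
- With only two Myrmicinae species, categories II and IV patterns are
  single subsets; classifier coverage of richer clade structures is tested
  through the generator's mixture machinery.
- The consensus of the two built-in callers is not a reimplementation of
  the external pipelines the original study intersected; it is the same
  *decision rule* applied to two independent in-package analyses.
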