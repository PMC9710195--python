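# Methods

## The analysis model

The pipeline treats per-SNP outputs of two allele-frequency models as
given: a *clinal* model (frequency regressed on latitude across
populations) and a *seasonal* model (spring vs. fall across paired
samples), each contributing a p-value and a signed coefficient per SNP.
All signed quantities — coefficients, per-sample frequencies, allelic
effect signs — are polarized to one designated focal allele per SNP,
fixed at input time; the analysis only ever consumes products of signs,
so any consistent polarization yields identical results.

### Matched controls

Each distinct eQTL SNP is matched to non-eQTL SNPs sharing its
chromosomal arm, its 0.05-wide expected-heterozygosity bin (bin index
⌊het/0.05⌋, with het = 0.5 assigned to the closed top bin 9), and its
inversion status.  Status is evaluated against every inversion on the
SNP's arm jointly: per inversion, *breakpoint* means within the margin
(default 0.5 Mb, boundary inclusive) of either endpoint, *inside* means
strictly between the endpoints excluding the breakpoint zones, and
*outside* is the rest of the arm; the match key carries the full tuple,
so a 3R SNP is matched simultaneously on its status with respect to
In(3R)P, In(3R)K and In(3R)Mo.

For each eQTL, `n_sets` controls (default 1000) are drawn uniformly
from its candidate pool — without replacement within the eQTL's list
when the pool is at least `n_sets`, with replacement (and a warning)
otherwise.  One SNP may serve as control for several eQTLs.  Control
set *k* is the *k*-th draw of every eQTL, which preserves the per-eQTL
matching structure across sets and makes every set the same size as the
eQTL list.  An occupied match key with no candidate at all is a hard
error by default; `on_empty="drop"` instead removes those eQTLs from
the analysis with a warning, since they cannot be tested against
matched controls.

### Enrichment

P-values are converted to ranked quantiles rank/n with ties sharing the
maximum rank of their group, computed once over the *analysis
universe* — by default the union of the eQTLs and every matched
candidate control, so a "top 5%" cutoff means the same thing for both
groups (`universe="all"` ranks over the whole SNP table instead; the
choice is echoed in the run summary).  At threshold *t* the odds ratio
against control set *k* is (A·D_k)/(B·C_k) from the counts at/below
("≤") and above *t*.  If any cell is zero, 0.5 is added to all four
cells (Haldane–Anscombe) and the result flagged, so the 1000-set null
keeps its full size.  Reported per test: mean log₂ OR over sets, a
half-width of 1.96 × sample SD (ddof = 1) of the set log₂ ORs, and an
empirical p-value comparing the eQTL proportion A/(A+B) to the set
proportions C_k/(C_k+D_k).

*Block thinning.* To break local linkage, one eQTL is retained per
non-overlapping 10-kb window per arm (windows anchored at coordinate
1), the analysis rerun on the retained eQTLs and their control columns,
and this repeated 100 times.  The quantile cutoffs are held fixed at
the full-universe ranking across replicates.  The aggregate reports the
across-replicate mean of the per-replicate mean log₂ OR, a spread of
1.96 × SD of those per-replicate means, and the median per-replicate
empirical p-value (a median keeps the aggregate insensitive to a few
degenerate replicates).

*Partitions.* The same single-threshold analysis (default top 5%) runs
per whole arm and per inversion region.  Because controls are matched
on the joint status tuple, an eQTL's controls lie in its own region by
construction and each stratum analysis simply restricts rows.  Strata
with zero eQTLs are reported not-testable, never an error.  Arm counts
equal the sum of any one inversion's three region counts; this
partition additivity is exercised in the tests.

*Per gene.* A gene's test uses its own eQTLs against their control
columns at the top-5% cutoff; only genes with at least one eQTL at or
below the cutoff are reported.  The excess summary gives, among genes
significant at emp.P ≤ 0.05, the proportion enriched (mean log₂ OR
> 0) with a two-sided exact binomial test against 0.5.

### Directionality

The predicted direction of an eQTL record is
π = effect_sign × de_sign × σ(label, axis), with σ = +1 on both axes
for latitudinal, chill-coma, starvation and low-temperature DE sets and
σ = −1 for heat-shock and high-temperature sets; spring is the positive
pole of the seasonal axis, mirroring north (spring populations are
treated as the more winter-adapted ones).  Observed direction ω is the
sign of the model coefficient (cross-population comparisons) or of a
pairwise frequency difference (north−south endpoints, or spring−fall
within a locality).  The concordance score is #{π·ω = +1} / #{ω ≠ 0};
records with ω = 0 are excluded from the denominator and counted
separately (zero coefficients are measure-zero in practice; the count
is reported).  The latitudinal DE set defaults to female plus
non-sex-biased eQTLs (the underlying expression contrast was measured
in females); treatment sets default to non-sex-biased eQTLs.

The null replaces each eQTL's ω with that of its matched controls,
which inherit the eQTL's π (controls carry no effect sign of their
own); one score per control set, the same sets reused across pairwise
comparisons.  An eQTL annotated to several DE genes contributes one
record per (gene, set) membership.  Verdicts: *concordant* if the score
exceeds 0.5 with emp.P at or below the Bonferroni-adjusted threshold,
*discordant* if below 0.5 and significant, *neutral* otherwise.  The
pooled score is identically the eQTL-count-weighted mean of per-gene
scores (asserted at run time), and genes holding more than half of a
set's scored records are flagged dominant, since a pooled score then
mostly reflects one locus.

### Empirical p-values and multiplicity

With observed statistic S and control-set null S₀ of size N,

P = (1 + Σ 1[S ≥ S₀ₖ]) / (N + 1),  emp.P = 2 × min(P, 1 − P).

Ties S = S₀ₖ carry half weight in the count.  Full-weight ties on
either side make the degenerate self-comparison (S identical to every
control value, which happens naturally because S and S₀ live on the
same count grid) come out maximally significant on one side; with half
weight it comes out maximally null (emp.P → N/(N+1)), while tie-free
cases — including S strictly outside the whole null, which gives
emp.P = 0, displayed as "< 1/N" — are unchanged.  N is the number of
control sets.  Bonferroni families default to the tests actually run in
an analysis call and can be pinned (`bonferroni_m`) to a fixed family
size; thresholds are displayed at 3 decimals (15 tests → 0.003,
22 → 0.002, 23 → 0.002).

## The synthetic-data generator

The generator emulates the statistical structure the analysis consumes,
with injectable, directly recoverable ground truth.

- **Positions.** Four autosomal arms at release-5 lengths carrying the
  six cosmopolitan inversions at their reference breakpoints.  Genes
  are placed uniformly (arms weighted by length); each gene receives
  1 + Poisson(mean − 1) eQTLs within ±`cis_window` (default 20 kb);
  background SNPs are uniform.  Duplicate (arm, pos) collisions are
  resolved keeping eQTLs.
- **Heterozygosity.** het = 2·maf·(1 − maf) with MAF uniform on
  (0.1, 0.5).  The lower bound keeps every occupied heterozygosity bin
  well populated, so matching strata retain usable candidate pools at
  desk scale (a sharp low-MAF cutoff leaves one bin with a sliver of
  mass and produces empty micro-strata); the range is a config knob.
- **Enrichment injection.** Non-eQTL p-values are uniform on (0, 1].  A
  fraction φ of eQTL p-values is drawn below the q = 5% cutoff, with
  φ = θr/(1 + θr), r = q/(1−q), so the odds ratio of eQTLs versus
  background at the cutoff equals the target θ.  Enrichment is injected
  this way, rather than by simulating selection, because the pipeline
  consumes p-values, not trajectories — θ becomes a directly
  recoverable parameter.  Defaults θ_c = 2, θ_s = 1: a clinally
  enriched genome against a seasonally null background.
- **Directionality injection.** Effect signs are symmetric ±1.  The six
  DE sets are sampled *disjointly* from the gene catalogue (sizes
  default to 39 latitudinal, 57 heat-shock, 16 chill-coma,
  28 starvation, 19 high- and 20 low-temperature; direction signs ±1
  with probability ½), so each gene has a single predicted direction
  and the concordance rate is well defined.  Per axis, each eQTL's
  coefficient sign equals its predicted π with probability κ (default
  0.6), independently per axis; genes outside every DE set get a
  symmetric random target.  Coefficient magnitudes are half-normal with
  scale 0.01 frequency/degree (clinal) and 0.02 (seasonal) — the real
  effect-size distribution is unknown, so these are stand-ins sized to
  plausible clinal slopes, and config knobs rather than claims.
- **Sample frequencies.** Two clinal endpoints (FL at 25.5°N, ME at
  44.8°N) and 20 spring–fall localities.  Per sample, frequency =
  baseline + clinal_beta × (latitude − mean) or ± seasonal_beta/2, plus
  Gaussian noise (default SD 0.05), truncated to [0, 1].
- **Determinism.** All draws descend from one integer seed through
  labelled substreams (`genes`, `de_sets`, `snps`, `freqs`; labels are
  CRC-32-folded into a `SeedSequence`), so identical configurations
  give byte-identical tables and each stage reproduces in isolation.

What the generator does **not** emulate: linkage disequilibrium beyond
cis clustering of eQTL positions (no haplotype structure, no sweeps),
the X chromosome, demography, relatedness between samples, or
measurement error in the upstream models.  Passing tests on synthetic
data therefore demonstrate that the statistics recover injected
parameters under the assumed independence structure — not that the
matched-control design removes every confounder present in real data.

## Problem sizes and numerical choices

- Default generator scale is 4 × 50,000 SNPs, 400 genes, ~5 eQTLs per
  gene: the full pipeline runs in minutes while strata keep large
  candidate pools.  The test suite and the acceptance script scale
  panels and replicate counts to desk size (12,500–50,000 SNPs per arm,
  100–200 control sets, 20–50 replicates), chosen so the checked
  quantities keep comfortable Monte-Carlo margins.
- Calibration facts the suite verifies: with θ = 1 and κ = 0.5 the mean
  log₂ OR is zero within Monte-Carlo error and concordance empirical
  p-values are approximately uniform; with θ_c = 2 the 1.96 × SD
  interval covers log₂ 2 = 1 in well over 90% of replicates; with
  κ ∈ {0.6, 0.8} the cross-population score recovers κ to binomial
  precision; label permutation within match-key strata (the self-null)
  drives every statistic to its null.
- Zero cells use the Haldane–Anscombe +0.5 on all four cells (flagged)
  rather than dropping sets, keeping the null at full size.
- Ranked-quantile ties take the maximum rank of the tie group, making
  "at or below the threshold" well defined under ties.
- BED input (0-based half-open) is converted to the internal 1-based
  inclusive convention at the boundary; interval length is preserved.
- Floats round-trip through TSV at 12 significant digits.

## Known limitations

- The concordance null inherits π from the matched eQTL; alternative
  null constructions (e.g. permuting effect signs) would test a
  different exchangeability assumption and are not implemented.
- Block thinning aggregates with the median empirical p-value across
  replicates; no combined-replicate inference is attempted.
- Controls are matched on arm, heterozygosity and inversion status
  only — not on recombination rate, gene density or wild allele
  frequency.
- Pairwise comparisons drop SNPs with missing frequencies (logged); no
  imputation is attempted.
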