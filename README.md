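# clineseas

Enrichment and directionality analysis of clinal and seasonal
allele-frequency change at expression QTLs (eQTLs), for population
geneticists studying local adaptation in *Drosophila melanogaster*-style
sampling designs: populations collected along a latitudinal cline and in
paired spring–fall samples.

The package answers two questions about a panel of eQTLs relative to
matched non-eQTL control SNPs:

1. **Enrichment** — are eQTLs over-represented among SNPs whose allele
   frequency changes with latitude (clinal) or between seasons
   (seasonal)?  For a ranked p-value quantile threshold *t*, count
   eQTLs at/below and above *t* (A, B) and the same for each of 1000
   matched control sets (C<sub>k</sub>, D<sub>k</sub>), and form the
   odds ratio

   OR<sub>k</sub> = (A·D<sub>k</sub>) / (B·C<sub>k</sub>)

   Results report the mean log₂ OR over control sets with a
   1.96 × SD confidence half-width, genome-wide over a quantile grid,
   after 10-kb block thinning (one eQTL per window × 100 replicates),
   partitioned by chromosome arm and by inversion region (breakpoint /
   inside / outside of the six cosmopolitan inversions), and per gene.

2. **Directionality** — do eQTL alleles move in the direction predicted
   from differential-expression (DE) data?  For an eQTL linked to a DE
   gene, the predicted sign is π = (allelic effect sign) × (DE
   direction) × σ, where σ encodes the axis hypothesis (genes up in the
   north, or induced by chill-coma / starvation / low temperature, have
   their upregulating alleles expected more common in the north and in
   spring; heat-shock and high-temperature genes the converse).  The
   **concordance score** is the fraction of eQTLs whose observed sign of
   frequency change (regression coefficient, or a pairwise frequency
   difference such as Maine−Florida or spring−fall) matches π; its null
   expectation is 50%.

Every test statistic is compared against a null distribution built from
control SNPs matched on chromosomal arm, heterozygosity (0.05-wide
bins) and joint inversion status (1000 matched controls per eQTL;
column *k* across eQTLs forms control set *k*).  Significance uses the
two-step empirical p-value

P = (1 + Σ 1[S ≥ S₀ₖ]) / (N + 1),  emp.P = 2 × min(P, 1 − P)

with Bonferroni correction within each analysis family; emp.P = 0 is
reported as "< 0.001" at N = 1000.

A synthetic-data module generates complete input bundles with known
ground truth (injected enrichment odds ratio θ, concordance rate κ), so
the entire pipeline runs and is testable with no external data.

## Worked example

Run the whole pipeline on a synthetic dataset (4 × 10,000 SNPs, 400
genes, ~2,000 eQTLs, clinal enrichment injected at θ = 2, seasonal
null, concordance rate κ = 0.6, 200 control sets):

```python
from clineseas.pipeline import RunConfig, run_pipeline, report
from clineseas.synthetic_data import SimConfig

cfg = RunConfig(out_dir="runs/demo",
                sim=SimConfig(n_snps_per_arm=10_000, n_genes=400, n_pairs=5),
                seed=42, n_sets=200, block_reps=20)
summary = run_pipeline(cfg)
print(summary["counts"])
print(report("runs/demo"))
```

prints (abridged):

```
{'enrichment_tests': 216, 'enrichment_significant': 10,
 'direction_tests': 48,
 'direction_verdicts': {'concordant': 0, 'discordant': 0, 'neutral': 48}}

# clineseas run digest
seed: 42; control sets per eQTL: 200; SNPs: 39999 (2053 eQTLs)

## Enrichment (log2 odds ratio, mean over control sets +/- 1.96 SD)
- clinal genome female q<=0.001: log2 OR = 2.122 +/- 1.725 (enriched, emp_p 0.0348259)
...
- clinal genome non_sex_biased q<=0.05: log2 OR = 0.604 +/- 0.519 (enriched, emp_p < 0.005) *

## Directionality (concordance score vs null of 50%)
- latitudinal crosspop_clinal: score = 0.587 (n = 155, emp_p 0.0149254, neutral)
```

Reading this: clinal enrichment is detected (positive log₂ odds ratios,
starred rows significant after Bonferroni) while every seasonal test is
null, matching the injected θ_c = 2 / θ_s = 1; the latitudinal
concordance score of 0.587 recovers the injected κ = 0.6 but does not
clear the Bonferroni threshold at n = 155 scored eQTLs — raising the
panel size or the number of control sets sharpens both.  The run
directory also holds every result table (`enrichment.tsv`,
`concordance.tsv`, `gene_*.tsv`), the simulated inputs,
`ground_truth.json` and `summary.json`.

The same stages are available from the shell:

```sh
clineseas simulate --out-dir data/ --seed 1
clineseas match    --snps data/snps.tsv --eqtls data/eqtls.tsv \
                   --inversions data/inversions.bed --out data/controls.tsv
clineseas enrich   --snps data/snps.tsv --eqtls data/eqtls.tsv \
                   --inversions data/inversions.bed --model clinal --out enr.tsv
clineseas run      --out-dir runs/full --seed 1 --synthetic
clineseas report   runs/full
```

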