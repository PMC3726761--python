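# koaudit

Audit pipeline for **passenger-region confounding** in knockout-mouse
RNA-Seq studies. When a knockout line is made on a donor-strain ES-cell
background, a chromosomal segment flanking the targeted locus survives
backcrossing; genes inside it are cis-deregulated and strain-informative
SNPs cluster there, confounding genotype–phenotype inference. This package
implements the complete analysis chain that exposes such a region, plus a
synthetic-data generator with recoverable ground truth so every stage is
testable by parameter recovery:

| stage | module | what it does |
|---|---|---|
| differential expression | `koaudit.de` | median-of-ratios normalization, pooled method-of-moments common NB dispersion, exact conditional NB test (two-sided, small-p rule), BH FDR |
| signature shifts | `koaudit.signatures` | exact two-sided sign test on the log2FC of predefined gene sets (CON/LZS/DZS/NVS/CBS) and ad-hoc gene families |
| variant scan | `koaudit.regionscan` | strain labeling against a SNP panel, variants per 50-kb window, run-based calling of high-density regions |
| positional enrichment | `koaudit.enrichment` | 2×2 chi-square (no continuity correction) + Fisher exact for concentration of top-N DE genes in a called region |
| methylation | `koaudit.methylation` | per-element capture-coverage loads (TSS/EXN/INT/ING), Mann–Whitney class comparison, per-TSS Pearson correlation |
| simulation | `koaudit.simulate` | NB counts with an injected cis-deregulated region, clustered strain SNPs, signature offsets, null/perturbed methylation; scenario presets `GC`, `activated`, `naive`, `null` |
| orchestration | `koaudit.audit`, `koaudit.cli` | single-config end-to-end run with a deterministic JSON report |

Internal coordinates are 0-based half-open (BED); VCF positions convert on
read/write. Counts travel as TSV or MatrixMarket, annotation as BED6 +
GTF-like exons (or a pre-classified element BED), variants as VCF v4.2,
coverage as BedGraph.

## CLI

```sh
# full audit on a simulated scenario
koaudit run --simulate GC --seed 1 --out audit_out

# or stage by stage
koaudit simulate --scenario GC --seed 1 --out sim
koaudit de --counts sim/counts.tsv --groups sim/groups.tsv --fdr 0.01 --out de.tsv
koaudit signatures --de de.tsv --sets sim/sets
koaudit scan --vcf sim/variants.vcf --panel sim/panel.vcf \
    --chrom-sizes sim/annotation/chrom.sizes --window 50000 --threshold 5
koaudit enrich --de de.tsv --region scan.regions.bed \
    --genes-bed sim/annotation/genes.bed --chrom-sizes sim/annotation/chrom.sizes \
    --elements-bed sim/annotation/elements.bed --top 100
koaudit methyl --cov-a sim/coverage_a.bedgraph --cov-b sim/coverage_b.bedgraph \
    --genes-bed sim/annotation/genes.bed --chrom-sizes sim/annotation/chrom.sizes \
    --elements-bed sim/annotation/elements.bed
```

`koaudit run --config audit.yaml` accepts a declarative YAML config
(keys: `simulate` *or* `inputs`, plus `de`, `signatures`, `scan`,
`enrich`, `methyl`, `seed`, `out`). Reports are byte-identical across
reruns with the same config and seed.

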