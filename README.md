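# trapsil

Gene-trap integration-site mapping and matched-control ROC enrichment
analysis of KRAB/KAP1-mediated transcriptional silencing.

## The problem

Tethering a KRAB-domain repressor (which recruits the universal corepressor
KAP1/TRIM28 and heterochromatin factors) to a promoter-trapping provirus
silences some trapped genes but not others. Asking *which* genomic and
chromatin features distinguish repressible from non-repressible loci
requires a pipeline that

1. turns raw barcoded LM-PCR pyrosequencing reads into mapped,
   phenotype-labelled integration sites (**REP** = reporter silenced upon
   repressor binding, **NREP** = not silenced; lentiviral **LV** vs
   MLV-based **MLV** gene-trap vectors),
2. assigns integrants to a non-redundant gene model and classifies
   multiply-hit genes by their silencing-vs-distance pattern, and
3. scores the enrichment of genomic/chromatin features around each site
   group against random matched controls, across interval scales from
   0.1 kb to 10 Mb.

`trapsil` implements this pipeline as a tested, reusable library plus CLI,
together with a synthetic-data generator that plants known structure
(phenotype depending on distance-to-TSS and on local feature density) so
every stage can be exercised and validated without any external download.

## The statistic at the core

For case sites *i = 1..n*, each with its own set of *m* random matched
control positions, and a feature quantified at every site and control, the
matched-control ROC area is

```
A = (1/n) Σᵢ ( bᵢ + tᵢ/2 )
```

where `bᵢ` is the fraction of site *i*'s controls with a feature value
strictly below the site's value and `tᵢ` the fraction tied. `A = 1` means
the feature is fully enriched at case sites, `A = 0` fully depleted,
`A = 0.5` no difference. REP-vs-NREP contrasts are tested both by a
likelihood-ratio χ² (df = 1) for the group × feature interaction in a
conditional (matched-set) logistic regression, and by a label-permutation
test on `|A_REP − A_NREP|`.

Other implemented pieces: exact-primer/barcode demultiplexing (barcodes
LI `TGAC/AGTC`, LR `CTGA`, MI `TCGA/AGCT`, MR `GTAC`), 20-bp junction-tag
mapping tolerating ≤2 mismatches (pigeonhole seed split + Hamming
verification, exactly equivalent to an exhaustive both-strand scan),
aggressive same-strand transcript overlap clustering, gene-group calls
(group 1 "long-range repression", group 2 "limited repression", group 3
"absence of repression"), SGA/BED track I/O, ±40 kb anchored profiles,
40-bin metagene profiles, and Wilcoxon rank-sum comparison of gene-group
expression (exact by enumeration at small n).

## Worked example

Simulate a small study (two 500-kb chromosomes, 24 genes, 300 integrants)
and run the whole pipeline on it:

```python
from pathlib import Path
from trapsil import SynthConfig, pipeline, synthetic_data

cfg = SynthConfig(genome_length=500_000, n_chromosomes=2, n_genes=24,
                  gene_size_range=(8_000, 40_000), n_sites=300, seed=42)
out = Path("demo")
bundle = synthetic_data.gen_genome(cfg)
synthetic_data.write_bundle(bundle, out)
sites = synthetic_data.gen_integrants(cfg, bundle)
reads = synthetic_data.gen_reads(sites, bundle, cfg)
synthetic_data.write_fasta(reads, out / "reads.fasta")

run_cfg = pipeline.RunConfig(
    reads=str(out / "reads.fasta"),
    genome=str(out / "genome.fasta"),
    transcripts=str(out / "transcripts.refflat.tsv"),
    outdir=str(out / "results"),
    tracks={"DNase_HS": str(out / "DNase_HS.bed"),
            "H3K4me3": str(out / "H3K4me3.sga")},
    scales=(1_000, 10_000),
    seed=7,
)
manifest = pipeline.run_all(run_cfg)
print(pipeline.report(manifest))
```

prints

```
# trapsil run report

## Read accounting
total reads      300
kept             300
discarded        0

## Mapping outcomes
mapped       300

## Pools x intragenic (sites isolated / mapped / intragenic-sense)
LVtotal    mapped=148    intragenic=133    (89.9%)
MLVtotal   mapped=152    intragenic=63     (41.4%)
LV-REP     mapped=79     intragenic=72     (91.1%)
LV-NREP    mapped=69     intragenic=61     (88.4%)
MLV-REP    mapped=112    intragenic=44     (39.3%)
MLV-NREP   mapped=40     intragenic=19     (47.5%)

## Gene groups
group 1             6
group 2             5
group 3             3
group unclassified  4
```

With zero read noise every read survives the exact-primer filter and maps
back to its planted position. The intragenic fractions reflect the planted
vector biology — LV integrants land inside gene bodies while MLV integrants
cluster around the TSS (half of them just upstream, hence intergenic). The
per-(feature × scale) ROC areas, the REP-vs-NREP p-values from both tests,
significance stars and a Benjamini–Hochberg column land in
`demo/results/heatmap.tsv`; `sites.tsv`, `clusters.tsv`,
`assignments.tsv` and `groups.tsv` hold the per-stage tables, and
`manifest.json` the hashed inputs and all counts.

The same workflow is available from the shell:

```sh
trapsil simulate --out demo --seed 42
trapsil demux --reads demo/reads.fasta --genome demo/genome.fasta --out sites.tsv
trapsil run --config run.yaml
```

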