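# genehurst

Long-range correlation profiling of bacterial genes, and distributional
analysis of the Hurst exponents of essential versus nonessential genes.

## The problem

Essential genes — genes whose disruption is lethal — are still identified
mostly by wet-lab mutagenesis. A purely sequence-derived feature that
separates essential from nonessential genes would be valuable for
computational essentiality prediction and for minimal-genome design. One
candidate feature is the **Hurst exponent** *H* of a gene's nucleotide
sequence: DNA exhibits long-range correlation, and *H* quantifies it
(*H* = 0.5 memoryless, *H* > 0.5 persistent, *H* < 0.5 anti-persistent;
for a long-memory series the autocovariance decays as
γ(k) ∝ k^(2H−2)).

The analysis this package implements asks a *distributional* question: for
a bacterial genome with an annotated essential/nonessential gene list, do
the per-gene Hurst exponents of a gene group follow a normal (or uniform,
Poisson, exponential) distribution? The reported pattern on real genomes
is that the essential group's normality significance level is markedly
higher than the full gene set's, while the nonessential group stays close
to the full set — suggesting the distribution of essential-gene Hurst
exponents as a classification index.

## What the package does

1. **Digitization** (`genehurst.codec`) — reads FASTA genomes and a
   tab-separated gene table, extracts each gene (1-based inclusive
   coordinates, minus-strand genes reverse-complemented) and digitizes it
   as A→0, G→1, C→2, T→3, e.g. `AGCTTTT` → `0123333`.
2. **Hurst estimation** (`genehurst.hurst`) — nine estimator modes behind
   a statsmodels-style model object: rescaled range (`rs`), spectral
   regression (`spec_standard`, `spec_smoothed`, `spec_robinson`),
   autocovariance fit (`acvf`), detrended fluctuation analysis (`dfa`),
   Whittle likelihood (`whittle`), aggregated variance and Higuchi curve
   length (`block_aggvar`, `block_higuchi`).

   ```python
   from genehurst import HurstModel
   res = HurstModel(series, method="dfa").fit()
   res.H, res.slope, res.rsquared
   print(res.summary())
   ```

3. **Normality statistics** (`genehurst.normality`) — one-sample
   Kolmogorov–Smirnov significance levels against normal / uniform /
   Poisson / exponential with sample-estimated parameters (the classic
   SPSS dialect; a Monte-Carlo Lilliefors correction is available), the
   0.05 acceptance rule, and Blom-position normal Q–Q data.
4. **Synthetic data** (`genehurst.simulate`) — exact fractional Gaussian
   noise via Davies–Harte circulant embedding, quartile coarsening to
   4-letter DNA, and whole synthetic genomes whose essential /
   nonessential groups draw per-gene H from configurable distributions —
   so the entire pipeline is verified by parameter recovery, with no
   downloads.
5. **Pipeline + CLI** (`genehurst.pipeline`, `genehurst` command) —
   end-to-end runs with per-gene exclusions logged (never silent), TSV
   outputs, and an organism summary of the essential-vs-full contrast.

## Worked example

Generate a synthetic organism (50 essential genes with H ~ truncated
Normal(0.62, 0.04); 200 nonessential with H from a bimodal mixture) and
analyze it:

```sh
$ genehurst simulate --n-essential 50 --n-nonessential 200 --seed 7 --out-prefix demo
wrote demo.fasta (290164 bp, 250 genes)
$ genehurst run --fasta demo.fasta --genes demo_genes.tsv --out results
analyzed 250/250 genes (0 excluded)
essential_more_normal_than_full: True
nonessential_vs_full: unchanged
$ cat results/summary.txt
...
p[full_gene_set][normal]: 0.024592
p[essential][normal]: 0.861184
p[nonessential][normal]: 0.016402
essential_more_normal_than_full: True
```

Reading: for the primary mode (smoothed spectral regression) the K–S
normality significance of the full gene set is 0.025 (< 0.05, normality
rejected — the bimodal nonessential majority distorts it), while the
essential group reaches 0.861 (normality comfortably accepted), and the
nonessential group tracks the full set (0.016, "unchanged"). That is the
qualitative pattern reported on real genomes. `results/` also contains
`hurst_per_gene.tsv` (every gene × mode estimate with regression
diagnostics), `normality_report.tsv` (every group × mode × family), and
`qq_<group>.tsv` plot-ready Q–Q tables.

Real genomes run the same way: supply the genome FASTA and a gene table
with header `gene_id replicon_id start end strand essentiality`
(tab-separated, strand `+`/`-`, essentiality
`essential`/`nonessential`/`unknown`).

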