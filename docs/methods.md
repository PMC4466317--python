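# Methods

## Model and procedure

A gene's nucleotide sequence is treated as a categorical time series and
digitized A→0, G→1, C→2, T→3. The digitized series is analyzed as an
ordinary real-valued series (no purine/pyrimidine collapsing, no binary
walk): the object of inference is the Hurst exponent *H* of its
long-range dependence, under the working model of a stationary
long-memory process whose autocovariance decays as γ(k) ∝ k^(2H−2) and
whose spectral density behaves as f^(1−2H) near the origin. Fractional
Gaussian noise (fGn) is the reference member of that class and the
calibration target throughout.

Downstream, per-gene H values are grouped (full gene set; essential;
nonessential — the labelled groups are subsets of the full set, not a
partition) and each group's sample is tested against four candidate
families with a one-sample Kolmogorov–Smirnov test using
sample-estimated parameters and the asymptotic significance level. The
organism-level outcome is the contrast between the essential group's
normal-family significance and the full gene set's.

## Estimator modes

All nine modes first standardize the series (subtract the mean, divide by
the standard deviation), which makes every estimate exactly invariant
under shifts and positive rescalings, and then exploit one scaling law:

- **rs** — for each block size n of a log-spaced grid, the series is cut
  into ⌊N/n⌋ non-overlapping blocks; per block, R is the range of the
  cumulative sum of deviations from the block mean and S the block
  standard deviation; H is the slope of log mean(R/S) against log n.
  Blocks with S = 0 are skipped; a scale with no usable block is dropped.
- **dfa** — the profile (cumulative sum) is detrended per box by a
  least-squares polynomial (default order 1); H is the slope of the
  log RMS fluctuation against log box size.
- **spec_standard / spec_smoothed** — least-squares regression of the log
  periodogram on log frequency over the lowest 1/8 of Fourier
  frequencies; H = (1 − slope)/2. The smoothed mode first applies a
  centered moving average (span 7, edge windows shrink) to the
  periodogram ordinates.
- **spec_robinson** — semiparametric local-Whittle estimate: bounded
  scalar minimization of
  log(mean_{j≤m} I_j f_j^{2H−1}) − (2H−1)·mean log f_j with
  m = ⌊N^0.65⌋.
- **whittle** — full-band Whittle fit: minimize mean(I_j / g_H(f_j)) over
  H with the scale profiled out (shape normalized to unit geometric
  mean). The spectral shape g_H is the exact fGn spectral density,
  (1 − cos 2πf) Σ_j |f+j|^(−2H−1), with the aliasing sum truncated at 10
  terms plus an integral tail correction. An ARFIMA(0,d,0) shape was
  evaluated in its place and rejected: fitted to fGn it is misspecified
  at high frequencies and overestimates H by up to +0.07 at H = 0.85,
  whereas the exact shape is unbiased to ±0.002 across H.
- **acvf** — the sample autocovariance at lags 1..⌊N/8⌋ is transformed to
  asinh(γ̂(k)/(2γ̂(0))) and matched, by bounded scalar minimization over
  H, to the same transform of the exact fGn autocorrelation. A plain
  straight-line fit in the asinh-vs-log-lag plane was evaluated and
  rejected: when the correlation signal is weak the statistic is flat in
  log-lag and the line-fit degenerates to H ≈ 1 even for white noise.
  The model fit recovers H ± 0.065 over H ∈ [0.55, 0.85] and ~0.50 on
  white noise; the least-squares line through the asinh plot is still
  reported as a diagnostic (slope, intercept, R²).
- **block_aggvar** — sample variance (ddof 1) of non-overlapping block
  means against block size; H = 1 + slope/2.
- **block_higuchi** — Higuchi curve length of the profile at stride k,
  averaged over the k offsets; slope = −D, H = 2 − D.

Estimates are **not clipped** to [0.5, 1]: anti-persistent values and
small excursions above 1 propagate as-is so the group distributions are
not artificially truncated. The optimizer modes use deterministic bounded
scalar minimization (absolute tolerance 1e−6); the Whittle/ACVF search
interval is (0.01, 0.99), the Robinson interval (0.01, 1.49).

### Scale grids and defaults

Scales are log-spaced, rounded to integers and deduplicated; at least 4
distinct scales are required (series shorter than 64 are rejected, and
the pipeline excludes genes shorter than 64 bases). Per-mode grid
defaults, chosen on fGn/white-noise simulations before the test suite was
frozen and overridable via `EstimatorConfig`:

| parameter | default | why |
| --- | --- | --- |
| min scale, rs | 16 | the small-block rescaled range is biased upward (Anis–Lloyd effect); with blocks ≥ 16 the white-noise mean is 0.54 |
| min scale, dfa | 8 | boxes must comfortably exceed the detrending order |
| min scale, other block/lag modes | 4 | |
| max scale fraction, block modes | 1/16 | block statistics at scales near N/4 are systematically low (bias −0.08 at H = 0.85 vs −0.045 at 1/16) |
| max scale fraction, rs/dfa | 1/4 | conventional |
| scales requested | 16 | |
| spectral cutoff | lowest 1/8 of frequencies | low-frequency scaling regime |
| smoothing span | 7 | |
| Robinson bandwidth exponent | 0.65 | |
| ACVF max lag fraction | 1/8 | |

Measured accuracy at N = 8192 (mean over replicates): all modes within
±0.065 of the true H over H ∈ {0.55, 0.65, 0.75, 0.85}, the noisier
block/ACVF modes being the widest; every mode's white-noise mean lies in
[0.48, 0.55].

## Kolmogorov–Smirnov dialect

`ks_statistic` evaluates D = sup |ECDF − F| on the distinct order
statistics with cumulative tie counts (ties collapse into one jump).
`ks_pvalue` uses the asymptotic Kolmogorov series with Stephens'
small-sample adjustment λ = (√n + 0.12 + 0.11/√n)·D, truncated when a
term falls below 1e−12. Family parameters are plugged in from the sample
(normal: mean, sd with ddof 1; uniform: min/max; exponential: 1/mean;
Poisson: mean of the integerized sample). **No Lilliefors correction is
applied by default** — this reproduces the SPSS one-sample K–S procedure
the group comparison is defined against, and it is conservative (biased
toward acceptance) when parameters are estimated. A clearly labelled
Monte-Carlo Lilliefors option (`lilliefors_mc`) re-estimates parameters
per simulated null sample for honest reanalysis. Poisson is discrete, so
continuous H samples are integerized (×100, rounded — configurable) and
the result carries an `integerized` flag. Acceptance threshold: p ≥ 0.05,
reported alongside the raw p. Q–Q data use Blom plotting positions
(i − 3/8)/(n + 1/4) and sample-moment normal quantiles (the SPSS Q–Q
convention).

## Synthetic data generator

`simulate_fgn` implements Davies–Harte circulant embedding: the
autocovariance out to the next power of two ≥ N is embedded in a circular
row, eigenvalues come from one real FFT, and the series is synthesized
from seeded Gaussian variates — exact in distribution for every
H ∈ (0, 1). Eigenvalues below −1e−8 raise (they would indicate a
covariance bug); tiny negative roundoff is clipped with a logged warning.

`fgn_to_dna` coarsens a real series to 4 symbols by its own empirical
quartiles (rank map, class counts equal up to rounding). The monotone map
preserves the dependence structure; exact preservation of H is *not*
claimed — measured attenuation is ≈ −0.02 at H = 0.8 — and all recovery
tolerances absorb it.

`generate_genome` draws per-gene H from its group's distribution and gene
length from a log-normal model (median 900 bases, log-sd 0.55, clipped to
[150, 6000] — the scale of bacterial protein-coding genes), synthesizes
each gene as coarsened fGn, assigns a random strand (minus-strand genes
are stored reverse-complemented so extraction recovers the generated
series bit-exactly), and joins genes with iid-digit spacers of 20–200
bases that carry no long-range structure. A truth sidecar records each
gene's target H.

Group H distributions (defaults): essential ~ Normal(0.62, 0.04)
truncated to (0.05, 0.95); nonessential ~ ½ TN(0.52, 0.03) +
½ TN(0.84, 0.05). The mixture's mode separation (0.32) was fixed by a
power analysis: per-gene estimation noise at the default length scale is
sd ≈ 0.07–0.14, and a separation much below 0.3 is washed out, making
the essential-vs-full contrast undecidable at the default 50/200 group
sizes. With these defaults the contrast reproduces in ≳ 95% of seeded
runs. What passing tests show is therefore that the *pipeline detects a
distributional contrast that is genuinely present*; they do not certify
the effect size or the H distributions of real genomes, which the
generator does not attempt to emulate (no codon structure, GC skew or
compositional heterogeneity).

## Numerical and design choices

- Coordinates are 1-based inclusive (GenBank convention); minus-strand
  genes are analyzed on the coding strand.
- Residues outside {A,C,G,T} are never value-substituted: the default
  policy excludes the gene with a logged reason ("skip-gene"); a strict
  mode errors. Record conservation (analyzed + excluded = input rows)
  holds for every run.
- Multi-replicon organisms: genes resolve against their own replicon and
  pool into one organism-level gene set.
- The full gene set includes genes with `unknown` essentiality, so
  essential + nonessential ≤ full.
- Per-gene and per-family failures inside a pipeline run are logged at
  warning level and skipped (e.g. a negative H estimate makes the
  exponential/Poisson families inapplicable for that group); they never
  abort the run.
- The qualitative nonessential-vs-full classification uses
  |Δp| ≤ 0.01 → unchanged, Δp ∈ (0.01, 0.1] → slight increase,
  Δp > 0.1 → increase, Δp < −0.01 → decrease (configurable).
- Method ranking (`compare_methods`) orders modes by essential-group
  normal-family p, descending, ties broken lexicographically; a mode
  covering under half the genes is dropped with a warning.
- Determinism: every estimate is a pure function of (series, config);
  every simulation is a pure function of (spec, seed); pipeline reruns
  with identical config produce byte-identical outputs.

## Problem sizes used in the checks

Estimator recovery is validated at N = 8192 with 100 replicates per H
level (H ∈ {0.55, 0.65, 0.75, 0.85}), the white-noise anchor at N = 4096
with 100 replicates, generator exactness at N = 512 with 5000 replicates,
and the group contrast on 100 synthetic organisms of 250 genes each; the
acceptance script reports the same quantities at 50 replicates/organisms
per configurable seed.

## Known limitations

- The nine modes are classical published forms with conventional tuning;
  they do not attempt bit-compatibility with any historical R
  implementation of the same estimator names.
- Digitized 4-level series are bounded and non-Gaussian; all estimators
  treat them as ordinary real series, which is exactly what the study
  design prescribes, but small-sample bias on very short genes
  (≈ 150–300 bases) is substantial (sd ≈ 0.14).
- The plug-in asymptotic K–S p-value is conservative with estimated
  parameters; cross-group *comparisons* of these p-values are meaningful,
  their absolute calibration is not (use the Lilliefors option for
  calibrated single-group inference).
- No multifractal/wavelet estimators, no GenBank/GFF parsing (convert to
  the simple gene-table TSV), no download clients.
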