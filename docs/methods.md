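# Methods

## The screen and its data model

A dual-crRNA double-knockout screen reads out the relative abundance of
crRNA arrays — single cassettes encoding two Cas12a guides — in a pooled
cell population under negative selection. The canonical design enumerated
here pairs every kinase gene with every metabolism gene (DKO arrays), every
targeting gene with every non-targeting control spacer (SKO arrays, gene in
position 1), and every ordered control pair (NTC-NTC arrays): with 15
kinase, 12 metabolism and 5 control spacers that is
15·12 + 27·5 + 5² = 180 + 135 + 25 = 340 arrays. The control count of 5 is
the library parameter consistent with that composition and is configurable.
The cassette reference is `DR-spacer1-DR-overlap-DR-spacer2-DR`; the direct
repeat and the SOE-PCR overlap are bench-specific sequences supplied as
configuration, with documented placeholder defaults (a canonical Cas12a-style
repeat and a synthetic GC-balanced 20-mer) used by the simulator. Spacer
design rules checked by `check_spacer_rules`: 20-nt guide, `TTTV` PAM
context, GC fraction within an inclusive 30–70% band, computed over the
spacer only.

## Counting

Read pairs from the cassette amplicon are merged by the longest *exact*
suffix/prefix overlap of read 1 against the reverse complement of read 2,
requiring more than 30 nt (minimum 31). No mismatches are tolerated and an N
inside a candidate overlap counts as a mismatch: the amplicon is a fixed
short cassette, so exact overlaps are the expected case and approximate
merging would only admit chimeras. Each merged read is assigned to the
unique array whose counting signature — the full inter-spacer cassette
`spacer1 + DR + overlap + DR + spacer2` — it contains as an exact substring
(forward first, then a reverse-complement retry); the full signature rather
than the spacer pair alone prevents collisions between SKO/NTC arrays that
share spacers. Reads matching zero or two-plus signatures are discarded and
tallied in the per-sample QC report.

Counts are normalised per sample to reads per million (rpm). Fold-change is
`(final + pc) / (initial + pc)` with a 1-rpm pseudocount by default (exposed
as a parameter) and LFC is its log2. Library QC reports the detected
fraction at a count threshold and a p90/p10 skew ratio using
linear-interpolation percentiles; the skew metric is a descriptive stand-in —
no standard "homogeneity" definition exists — and is flagged undefined when
the 10th percentile is zero.

## Interaction models

Both models consume rpm abundances; sample roles come from the sample
metadata. The tumour screens are measured against the *injected cell pool*
(the earliest cell timepoint, day 4 in the canonical layout): tumour LFCs,
the enrichment medians' cell-side denominators, and the cell axis of the
cell-vs-tumour regression all default to it, with explicit overrides
available (e.g. contrasting tumours against the day-14 in-vitro endpoint).

**Enrichment outlier model.** Per pair, eight medians are taken on the rpm
scale: the DKO array's median across each condition's replicate samples, each
gene's median over all of its SKO arrays × samples, and the NTC-NTC median
over all control arrays × samples. Observed enrichment
`(D_t/D_c)·(N_c/N_t)` is regressed (OLS) on the additive expectation
`(A_t/A_c)·(N_c/N_t) + (B_t/B_c)·(N_c/N_t)`; each pair's externally
studentized residual is tested two-sided against t(n − 3) and BH-adjusted.
The NTC normalisation makes a neutral pair a fixed point: an array that
behaves exactly like the controls has observed enrichment 1 regardless of
global depletion. Pairs with a zero median in a denominator are skipped with
a recorded reason rather than failing the whole screen. A numerically
perfect regression fit is treated as having no outliers (all residuals 0).

**Rank-sum model.** Per pair, the DKO array's per-tumour-sample LFCs are
compared with the pooled per-sample LFCs of both genes' SKO arrays
(two-sided Mann–Whitney; the pooling is a strategy option, with a
conservative per-gene-maximum alternative), BH-adjusted across pairs. The
exact null distribution is used for small tie-free samples (both sides at
most 8, or at most 10 observations in total); otherwise the normal
approximation with tie and continuity corrections. At the canonical sizes
(12 DKO values vs 120 pooled SKO values) the approximation branch applies.

**Cell-vs-tumour regression screen.** Entities are the DKO arrays plus
per-gene collapsed SKOs (mean over a gene's SKO arrays; median available).
Abundances are log2(rpm + 1) averaged over each condition's replicates —
the log scale stabilises the variance of count ratios; the raw-rpm scale is
obtainable by passing precomputed series. OLS of tumour on cell abundance,
studentized-residual outlier test, BH adjustment.

Significance is `BH-adjusted p < 0.05` throughout, with alpha a parameter of
`fit()`.

## Virtual double-knockdown survival screen

For each pair the cohort is stratified by the per-sample mean of the two
genes' normalised expression into bottom (0–25) and top (75–100) quartile
groups; percentiles use linear interpolation and boundary-equal samples are
included in their group. Survival of the strata is compared by the
Mantel–Cox log-rank test (the specific test is our choice; the source
procedure names only KM survival differences) — degenerate comparisons with
no events in either group return p = 1 with a flag. Single genes are
stratified the same way. The pair score against gene X is
`log1p(p_pair / p_X)` (natural log). The literal ratio is the default
because it is the ratio as defined; note that with it, "both scores > 1"
selects pairs whose joint p-value is *larger* than the single-gene
p-values. The `reciprocal` orientation (`log1p(p_X / p_pair)`) highlights
pairs whose joint stratification separates survival more strongly than
either gene alone, which is what a screen for synergistic pairs wants; both
are first-class options and every recovery analysis here states which it
uses. Classification: both scores > 1 and the low-expression stratum
survives longer → favourable; both > 1 and it survives worse → unfavourable;
otherwise neutral. Direction comes from comparing KM median survival of the
two strata (final survival probability as fallback when neither median is
reached). Non-finite scores are dropped and logged; no other trimming is
applied. Sample exclusions (e.g. viral-aetiology filters) are an optional
boolean column on the cohort, not hard-coded.

## Synthetic data

The generators produce data with the statistical structure the analysis
assumes, so every stage is testable without external sequencing data.

**Screens.** Initial plasmid composition is log-normal (σ = 0.5, a
realistically but not pathologically skewed library). Each array's expected
terminal relative abundance is its baseline × `2^(f_g1 + f_g2 + ε)`: f is
per-gene log2 fitness (controls 0), ε the planted interaction of a DKO pair,
and fitness acts once per screen interval (day 4 → day 14, or cell pool →
tumour) since the analysis only uses endpoint ratios. Counts are drawn at an
expected depth of 1000 reads/array (100 in the fast count-fidelity check)
with negative-binomial noise parameterised as variance = μ + α·μ², α = 0.1
by default — typical pooled-screen overdispersion. The overdispersion is
applied to post-outgrowth samples (day-14 cells, tumours), where it
biologically arises from clonal-expansion stochasticity; pre-expansion pools
(plasmid, day-4 cells) carry Poisson sequencing noise only. This placement
matters: overdispersing the day-4 comparator would give every array a ~25%
shared abundance error across its replicate median, which the downstream
per-array contrasts would read as signal. Each tumour first passes the pool
through an independent multinomial bottleneck (default 10⁵ cells — smaller
than a real engraftment so that drift is visible at desk scale) before
selection and counting. The default layout is 1 plasmid sample, 3 cell
replicates at days 4 and 14, and 6 tumours at each of days 10 and 18.

**Reads.** `simulate_fastq` emits one read pair per planted count, spanning
the cassette from both ends with a guaranteed >30-nt overlap, constant
quality, and a seed-shuffled read order; the merge/count round-trip recovers
the planted counts exactly, which is the pipeline's self-consistency oracle.

**Cohorts.** Per-gene log expression is normal around gene-specific means
(expression values are its exponential, upper-quartile-FPKM-like in scale);
z is the standardized log expression. The per-sample hazard is

    h = h₀ · exp( Σ_g β_g z_g + Σ_(A,B) β_int · max(−z_A, 0) · max(−z_B, 0) )

with h₀ = 1/1000 per day. The interaction covariate is the *rectified*
joint-low product, non-zero only when both genes are lowly expressed, so
β_int < 0 means joint loss of expression is protective — the situation the
screen's favourable class describes. A raw product of z-scores was rejected
as the interaction covariate: its conditional expectation given the pair
mean is an even function of that mean, so the bottom-vs-top-quartile design
is blind to it by symmetry and no calibration could detect it. Event times
are exponential at the sample's hazard; censoring replaces a
`censor_fraction` (default 0.3) of times with an independent uniform draw on
(0, t), achieving the fraction in expectation. Cohort size defaults to 400.

**What the simulations do not emulate:** guide-efficiency variation between
spacers (each array is one perfectly acting construct), multiplicity of
infection and multiple integrations, PCR jackpotting beyond the NB
dispersion, in-vivo clonal dynamics beyond a single bottleneck, correlated
expression between genes, and non-proportional hazards. Passing recovery
tests therefore demonstrates the *statistical machinery* is correct and
calibrated under its assumed noise model, not that any particular real
screen meets those assumptions.

## Numerical choices and edge cases

- Externally studentized residuals with a t(n − 3) reference (simple
  regression); BH rather than Bonferroni for multiplicity, everywhere.
- Perfect fits (SSR ≤ 1e-12 of the response scale) yield all-zero residuals
  instead of 0/0 noise amplification.
- rpm columns must have a positive total; all-zero columns are an error, not
  silently NaN.
- Deterministic library enumeration: lexicographic array ids
  (`gene1__gene2`) within category blocks, so two runs are identical.
- All generators take integer seeds and are bit-reproducible; derived seeds
  stay below 2³¹.

## Known limitations

- Exact-substring counting cannot rescue reads with sequencing errors inside
  the ~100-nt signature; at realistic error rates a few percent of reads per
  sample go uncounted (unbiased across arrays, so ratios are unaffected).
- The enrichment model's additive expectation is a sum of abundance ratios;
  with strong single-gene effects the observed/expected relation curves and
  the linear outlier test loses calibration in the tails.
- The rank-sum model inherits sensitivity to *any* difference between DKO
  and SKO distributions, including pure additivity of two fitness effects;
  it is a synergy test only in conjunction with the enrichment contrast.
- Quartile stratification discards the middle half of the cohort; with
  small cohorts the log-rank comparison is underpowered, and the screen
  tests association, not causation.
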