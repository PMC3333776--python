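# Methods

This note documents the models behind rhizoclass, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical conventions for degenerate inputs.

## Array processing model

A two-color slide hybridizes two mRNA pools (conditions) labeled with
different fluorophores.  Per spot we observe foreground and local background
intensities in each channel.  Processing:

1. **Background correction.**  `corrected = max(fg - bg, floor)` per channel
   with `floor = 0.5`.  A spot with `fg <= bg` in either channel is *flagged*
   but kept; the floor keeps log-ratios finite while the flag preserves the
   information that the spot is unreliable.  Flagged genes are excluded from
   normalization fitting and from replicate statistics, and a gene flagged on
   every replicate is reported with P = 1 and an `all_flagged` flag rather
   than dropped.
2. **MA transform.**  M = log2(ch1/ch2), A = (log2 ch1 + log2 ch2)/2.
3. **Lowess normalization.**  M' = M - f(A), where f is a locally weighted
   linear regression (tricube weights) with span 0.3 and 3 robustifying
   iterations — conventional two-color defaults.  The robustifying passes
   matter: differentially expressed genes are outliers against the null mass
   and are down-weighted, so the fitted trend tracks the dye bias of the
   unchanged majority rather than the biology.  Fitting requires >= 20 usable
   spots; flagged spots receive the interpolated trend.  Because lowess
   absorbs any constant offset, M' is invariant to slide-wide multiplicative
   scaling of one channel.
4. **Replicate aggregation.**  Dye-swapped slides have M negated so every
   replicate reports numerator/denominator.  Per gene: mean log2 ratio over
   unflagged replicates, fold = 2^mean, and a two-sided one-sample t-test
   against 0.  No multiple-testing correction is applied by default — the
   classification rules below filter on raw P <= 0.05 — and down-regulation
   is expressed as fold < 1, not negative fold.
5. **Indirect contrasts.**  When two conditions were each hybridized against
   a shared baseline, their ratio is derived as the difference of mean log2
   ratios, with a Welch two-sample t-test from the per-contrast summary
   statistics.  Welch rather than pooled-variance because replicate counts
   typically differ across contrasts (e.g. 5 vs 3 biological replicates).

Degenerate-statistics conventions (deterministic and flagged): zero-variance
replicates give P = 1 if the mean is 0, else P = 0 with a `degenerate` flag;
a single usable replicate gives P = 1 with an `insufficient` flag.

## Specificity rules

Elevation: a rhizosphere gets a primary call at fold >= 3 and P <= 0.05; if
any rhizosphere has a primary call, rhizospheres at fold >= 2 join the
elevated set.  Whether the secondary (two-fold) members must also satisfy
P <= 0.05 is a genuinely open convention; the default requires it, for
symmetry with the primary call, and `require_secondary_p=False` gives the
pure fold-based variant.  Down-regulation: fold <= 0.3 at P <= 0.05 in at
least one rhizosphere, extended to DOWN_ALL when every remaining rhizosphere
is <= 0.5-fold (no P requirement on the extension, which mirrors how the
rule is stated); all folds in [0.4, 0.8] without a DOWN call is SLIGHT_DOWN,
applied on folds only.  A gene satisfying both an elevation and a repression
rule keeps the elevation label with a conflict flag, so the up/down
categories stay mutually exclusive.

Reconciliation of the indirect (vs. baseline) and direct
(rhizosphere-vs-rhizosphere) designs uses the intersection: a gene counts as
strictly specific to a focal rhizosphere only when its indirect category is
the focal singleton *and* its direct fold against each other rhizosphere is
>= 3 at P <= 0.05.  Intersection is the conservative reading of "supported
by both designs".

The rhizosphere set is configurable; the default trio (pea, alfalfa, sugar
beet) uses the field vocabulary for its categories (ALL, LEGUME, PEA_ONLY,
...), other sets get generated names.

## Synthetic data model

The generator's defaults are the study conditions the tests exercise:

| parameter | default | rationale |
|---|---|---|
| n_genes | 5000 | order of a rhizobial genome (~7.3k genes), desk-scale |
| replicates/contrast | 4 | within the study's 3-5 biological replicates |
| noise_sd_log2 | 0.25 | typical replicate SD for two-color arrays; not stated by the study, exposed in config |
| dye_bias_amplitude | 0.4 | visible but realistic MA-plot curvature |
| intensity range | (6, 14) log2 | usual dynamic range of array scanners |
| category proportions | 10% DE total, 90% null | the study's scale: ~764 of ~7.3k genes >= 3-fold in the pea rhizosphere |

Categories are converted to per-rhizosphere expression ratios with
margin-separated ranges: one randomly chosen *primary* member of each
elevated category draws fold ~ U[3.5, 30], other members U[2.3, 2.9],
excluded rhizospheres U[0.9, 1.05], fully repressed genes U[0.1, 0.25], and
null genes are exactly 1 (so a pure-null cohort is a calibrated type-I-error
benchmark).  The margins are deliberate: lowess normalization re-centers
log-ratios on the (90% null) majority, shifting every fold by up to ~0.1
log2 units when 10% of genes are differentially expressed, and the direct
pea-vs-other ratio of a pea-specific gene must stay >= 3 (worst case
3.5/1.05 = 3.3) for the reconciliation round-trip to be exact.  With these
ranges a noise-free cohort is classified with zero error, which the tests
assert, and truth remains unambiguous — the generator plants effects, the
classifier only has to find them.

Slides: per spot, A ~ U(intensity range); the channel log-ratio is
`orientation * (planted log2 fold + N(0, noise_sd)) + bias(A)` with
`bias(A) = amplitude * x^3`, x the intensity scaled to [-1, 1].  The bias
rides on the channels (it keeps its sign under a dye swap, as a physical
dye artifact does), even replicates are dye-swapped, and an additive
per-channel background U(40, 120) is planted so background subtraction is
exactly invertible.  Pea-specific genes are placed on plasmid pRL8 with
probability 0.37 (echoing that plasmid's documented bias toward
pea-rhizosphere-specific genes); other genes draw replicons from fixed
genome-shaped weights.

Competition counts invert the RCI definition: expected wild-type recovery =
baseline_pct / true_rci, and each plant contributes `cfu_scale` total CFU
with a binomial wild-type count.  Ct tables offset the target gene's
treatment Ct by -log2(planted ratio) with Gaussian cycle noise.

**What the generator does not emulate** — spatial slide artifacts, print-tip
effects, saturation, amplification bias, correlated (non-i.i.d.) replicate
noise, plant-to-plant overdispersion beyond binomial counting, or qPCR
efficiency differences between genes.  Passing tests therefore demonstrate
that the *analysis chain* is correct and calibrated under a clean generative
model, not that real hybridizations meet these assumptions.

## qPCR

ddCt assumes doubling per cycle (efficiency 2); `efficiency` is exposed for
assays with measured amplification efficiencies (fold = E^(-ddCt)).  The
significance test is a generic two-sided permutation test on
replicate-paired dCt values with the +1 correction — a documented
simplification in the spirit of randomization-based qPCR ratio tests, not a
re-implementation of any published tool.  Note its granularity: with n
replicates per condition there are C(2n, n) label splits, so the smallest
achievable two-sided P is 2/20 = 0.1 for triplicates and 2/70 = 0.029 for
quadruplicates.  Triplicate assays can therefore never reach P <= 0.05 with
this test; the pipeline's demonstration stage and the calibration tests use
4-5 replicates per condition, where the nominal 5% level is achievable.

## Pipeline

`run_all` chains simulate -> process -> classify -> rci -> qpcr from one
`RunConfig` (YAML-loadable; CLI flags override).  All randomness flows from
the single config seed through named substreams, so repeated runs are
byte-identical; intermediate tables are written as TSV and the summary as
sorted JSON.  Thresholds are validated (primary >= secondary >= 1) before
any stage runs.

## Problem sizes used in tests

Statistical checks run at 5,000 genes x 4 replicates (category accuracy,
type-I calibration, bias removal), 2,000 genes for the zero-noise
round-trip, 8 plants x 10^4 CFU for RCI recovery, and 300 simulations x
1,000 permutations for permutation-test calibration — sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances on a single CPU.

## Known limitations

* The lowess trend is fitted per slide on all usable spots; print-tip-group
  or within-block normalization is out of scope.
* The elevation rule's secondary-threshold behaviour near fold = 2 is
  sensitive to normalization shifts; on real data with >> 10% regulated
  genes, lowess re-centering will bias folds downward (an assumption shared
  by all majority-null normalizations).
* RCI is reported without a significance test between mutants; the SEM of
  the recovery percentage is provided for that purpose.
* The permutation test's P-value floor (above) limits triplicate designs.
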