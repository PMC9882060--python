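# Methods

## The measurement model

A paired half-cell experiment yields, for each bisected cell *i*, two TPM
profiles (anterior and posterior). All analysis runs on the adjusted log
scale: `v = ln(1 + TPM)` plus the half-sample's gene-mean of `v`. The natural
log is used; the base only rescales both the numerator and denominator of the
skew and is recorded in the `AdjustedMatrix` metadata. The adjustment offset
is computed per half-sample over *all* genes, before gene filtering, because
filtering decisions themselves depend on the adjusted values.

The per-gene, per-pair skew is `(a − p)/(a + p)`. Because adjusted values are
non-negative, the statistic is bounded in [−1, 1], antisymmetric under
swapping the halves, and zero when the halves agree. When `a + p = 0` the
skew is stored as missing (NaN), never as 0; with the default abundance
filter this cannot occur for retained genes, but the guard exists. Note that
the adjustment offset (roughly the mean log TPM, ≈5 for a TPM-normalized
profile of ~2000 expressed genes) sits in the denominator, so estimated skews
are numerically much smaller than the underlying abundance asymmetry: a gene
whose anterior half holds 70% of its transcripts (`s = 0.4` in the simulator)
has an estimated skew near 0.04. Effect-size thresholds must live on this
compressed scale.

## Gene filters

- abundance: mean TPM across all half-samples ≥ `min_mean_tpm` (default 1.0;
  a conventional floor for "expressed" in TPM units — the cutoff is a free
  parameter of the method).
- dispersion: sample variance / mean of the *adjusted* values across all
  half-samples (controls and knockdowns pooled) strictly `< 2`. The strict
  inequality is part of the contract (a gene at exactly 2 fails). The scale
  (adjusted vs raw) is configurable through which matrix is passed in; the
  pooled adjusted scale is the default because it is the scale the skew is
  computed on.

## Control-space PCA and the AP axis

PCA is center-only (genes centered by their control means, no unit-variance
scaling — adjusted log values already share a scale), computed by full SVD on
the samples × genes control matrix; default `n_components = min(5,
n_samples − 1)`. Component signs follow a fixed convention (the
largest-|loading| gene of each component is positive), which makes fits
deterministic across runs and platforms. Projection is the exact affine map
`(x − control means) · loadingsᵀ`, so training samples reproduce their fitted
scores to machine precision and no information from the projected set leaks
into the space.

The AP axis is the component with maximal |Welch t| between anterior and
posterior scores (ties to the lower index) — detected rather than assumed,
because with so few samples the AP signal can surface on PC1 or PC2 depending
on the experiment. Separation strength is the standardized mean difference
|Δmean|/pooled sd; the knockdown-to-control ratio of SMDs on the *control's*
AP component quantifies global loss of regionalization.

## Flip detection

Candidate selection treats genes as variables and pairs (cells) as
observations: PCA on the pairs × genes skew matrix (genes centered by their
grand-mean skew; missing skews imputed with the gene's grand mean *for
selection only*), then the component whose pair scores best separate control
from knockdown by |Welch t| supplies the ranking, and the top K = 500 genes
by |loading| (ties broken by gene id) are tested. K = 500 matches the scale
of candidate sets used in this kind of screen and is a flag. Like the sample
PCA, the selection PCA keeps `min(5, n_pairs − 1)` components: the leading
components carry any condition structure, and restricting the max-|t| search
keeps the null calibration of the selection statistic close to a single t
distribution.

Each candidate gets an unpaired two-sided Welch t (control vs knockdown
cells are independent), observed values only. Genes with fewer than two
observed skews in either condition are flagged untestable and excluded from
the BH adjustment, which runs across the tested candidates. Significance is
BH q < 0.05 by default (raw p < α available as a mode). Classification:

- `anti_correlated`: significant, both condition means ≥ `min_effect` in
  magnitude, opposite signs;
- `lost`: significant, |knockdown mean| < `min_effect` ≤ |control mean|;
- `retained`: any other significant change;
- otherwise `not_significant`.

`min_effect` defaults to **0.02** on the estimated-skew scale. The choice
follows from the scale compression above: genuine regionalization lands
around 0.04, while the standard error of a null gene's mean skew at six pairs
is ≈0.006; 0.02 therefore sits several null standard errors above noise and
safely below real effects. A floor at 0.05 — natural-looking if one forgets
the adjustment offset — would sit *above* typical genuine effects and
misclassify most flipped genes as lost.

A knockdown that produces zero significant calls is a valid outcome and is
reported as such, not as an error.

## The Fisher overlap test

The RNA-side × protein-compartment association uses a two-sided Fisher exact
test implemented by direct enumeration: all 2×2 tables with the observed
margins, hypergeometric point probabilities via log-gamma (stable for large
counts), p = sum of probabilities ≤ the observed one, with a 1e−7 relative
tolerance absorbing floating-point ties. Any zero margin leaves a single
admissible table and p = 1 by convention. The implementation is verified in
the tests against scipy and against an exhaustive exact-rational-arithmetic
enumeration over every table with total ≤ 30 (agreement to 1e−10). For the
published cross-tabulation, the anterior/posterior comparison [[23,5],[1,0]]
has two admissible tables with probabilities 24/29 and 5/29, both ≤ the
observed, so p is exactly 1; the anterior/membranellar-band comparison
[[23,24],[1,7]] gives p ≈ 0.1191. The 2×2 construction for the second
comparison (rows anterior/posterior RNA, columns anterior/MB protein) is the
reading that reproduces the reported association, and is recorded here as a
modeling choice.

## The synthetic generator

`SimConfig` defaults define the reference scenario: 2000 genes, 15%
regionalized, true skew magnitudes |N(0.4, 0.1)| truncated to (0, 0.95) with
random sign, log-normal baselines (ln-scale mean 3, sd 1.5 — a heavy-tailed
expression profile typical of transcriptomes; absolute scale is irrelevant
after TPM normalization), six control and six knockdown pairs, multiplicative
log-normal noise sd 0.2, bisection-error sd 0.05, and knockdown fractions
0.4 flip / 0.4 loss / 0.2 retention among regionalized genes.

A gene with true skew *s* allocates fractions (1+s)/2 and (1−s)/2 of its
baseline abundance to the anterior and posterior halves. The bisection error
is a *single shared offset* per pair added to every gene's s (an imprecise
cut shifts all genes coherently), noise is i.i.d. per gene and half, and each
half-vector is rescaled to sum to 1e6 exactly as a TPM quantifier would. One
`numpy` Generator seeded from `SimConfig.seed` drives truth and all pairs, so
outputs are byte-reproducible.

What the generator does *not* emulate: read-level sampling (so no
length/GC bias or count overdispersion at low TPM), isoform structure, batch
effects, or correlated gene programs — null genes are independent. Passing
recovery tests therefore demonstrates that the pipeline's statistics behave
as designed under the stated noise model, not that real libraries meet that
model.

## Scenario sizes and degenerate inputs

Monte-Carlo checks use the reference scenario at 10–20 seeded replicates
(2000 genes, 12 pairs), sizes at which every quantity of interest is stable;
the exhaustive Fisher sweep covers all ~46k tables with total ≤ 30.
Degenerate inputs are handled explicitly: all-zero half-samples adjust to
zero (offset 0), constant-and-equal groups give t = 0 and p = 1, zero pooled
sd yields SMD 0 for zero difference (infinite otherwise), and constant
heatmap rows z-score to 0.

## Known limitations

- With very few pairs per condition (the realistic regime), Welch df are
  small and the BH-adjusted screen is conservative; `lost` vs
  `not_significant` for weakly regionalized genes is the least stable call.
- The ground-truth skew parameterizes raw abundance, so only sign and
  rank-order recovery — not numeric equality with estimated skews — are
  meaningful comparisons.
- The dispersion filter on pooled conditions can drop genes whose skew
  changes massively between conditions (the change itself inflates
  variance); with default thresholds this affects none of the simulated
  scenarios' flipped genes, but it is a structural trade-off of filtering
  before testing.
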