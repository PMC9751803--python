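# Methods

This note records the model choices, defaults and numerical conventions
behind `otunet`, and what the synthetic benchmarks do and do not show.

## From counts to similarities

The pipeline's input is an OTU count table with a taxonomy lineage per OTU
and a group label per sample.  Analysis is per group: prevalence is
computed within the sample subset being analysed, and OTUs present in
fewer than half of those samples are removed (prevalence exactly 0.5 is
kept; the cutoff is configurable).  Relative abundances are computed
against the *unfiltered* per-sample totals, so filtering does not change
the compositional denominator.

Zeros must be replaced before the log₁₀ transform.  The default
pseudo-abundance is 0.01 × the smallest nonzero relative abundance in the
matrix — deterministic and scale-respecting.  It is worth knowing its
failure mode: when an abundant taxon has a technical zero, the replacement
value sits several log units below that taxon's typical abundance, and the
resulting outlier can attenuate every correlation involving that profile.
This is a property of the log-pseudocount approach generally, not of this
implementation; a Spearman option (`correlation="spearman"`) is the robust
alternative when dropout is a concern.

Pairwise similarity is the Pearson correlation of log abundances
(zero-variance profiles get r = 0 with a warning).  At least three samples
are required; with ~12 samples per group, only |r| ≳ 0.7 is reliably
distinguishable from noise, which the threshold selection below discovers
by itself.

## RMT threshold selection

For each candidate threshold on a grid (default 0.30–0.99, step 0.01),
entries with |r| below the candidate are zeroed, rows/columns left without
off-diagonal entries are dropped, and the eigenvalues of the result are
examined.  Degenerate eigenvalues (within 1e−8) are collapsed; at least 50
distinct eigenvalues are required, otherwise the scan point is flagged
unusable rather than failing the scan.

Unfolding maps the spectrum so its local mean spacing is 1: a cubic
least-squares spline with ~11 interior knots at eigenvalue quantiles is
fitted to the cumulative spectral function (a degree-5 polynomial is
available via `method="polynomial"`).  The knot count matters: too many
knots track the level fluctuations themselves and whiten the spacings;
around a dozen follows the mean density of both GOE and superposed-block
spectra without touching the fluctuations.  Goodness of fit of the
spacings to the Poisson and Wigner laws uses a Pearson χ² over bins of
width 0.1 up to d = 3 (tail merged; adjacent bins merged until every
expected count is ≥ 5; df = bins − 1).

The selected threshold is the smallest scanned value whose Poisson p-value
exceeds 0.05 *and* whose Poisson χ² is below the GOE χ².  If no point
qualifies, the usable point minimising the Poisson χ² is returned with a
prominent warning.  When several group networks are to be compared, a
single shared threshold (the maximum of the per-group selections, or a
fixed value via `threshold_mode="fixed"`) removes threshold-selection
variance from the comparison; the pipeline supports both per-group and
shared modes.

## Topology and nulls

Average path distance is taken over connected node pairs only (two disjoint
triangles have GD = 1); restriction to the largest component is available
by flag.  Local clustering of degree-<2 nodes is 0 and included in the
average.  Modularity is Newman's Q on unweighted, unsigned edges; module
detection is greedy (Clauset–Newman–Moore) agglomeration, deterministic
for a fixed graph because nodes are inserted in sorted order.  The
"scale-free" statistic is the R² of an ordinary least-squares fit of
log₁₀ frequency against log₁₀ degree over k ≥ 1 — a descriptive fit, not a
maximum-likelihood power-law test, matching how the quantity is reported
in molecular-ecological-network tables.

Null networks are Maslov–Sneppen double-edge swaps (10·L swap attempts,
self-loops and multi-edges rejected), which preserve every node's degree
exactly; consequently N, L, average degree and the degree-distribution fit
are identical across the ensemble and only clustering, path distance and
modularity are summarised (mean, sd, z = (obs − mean)/sd over a default of
100 networks).  Signs are reassigned randomly preserving the empirical
sign ratio; weights are dropped — the null randomizes topology, not
correlation values.

## Node roles and stability

Zi uses the population standard deviation of within-module degree (Zi = 0
when the sd is 0); Pi is the Guimerà–Amaral participation coefficient.
Role thresholds are the conventional Zi ≥ 2.5 / Pi ≥ 0.62, exposed as
parameters; all non-peripheral roles count as potential keystones.

Robustness removes ⌊0.5·N⌋ random nodes (or ⌈0.5·|keystones|⌉ keystones —
ceiling, so "half of one keystone" removes it), then iteratively deletes
any node whose degree has dropped to zero ("isolated ⇒ extinct"), and
reports survivors/N over 100 repetitions.  The cascade is deterministic
and abundance-free; an abundance-weighted variant is out of scope.  Group
comparison is one-way ANOVA over per-repetition values, with a Tukey-HSD
compact letter display for more than two groups.  Repetition counts and
removal fractions are configuration, reported alongside mean ± sd.

## The synthetic generator

`generate_community` draws log abundances from a one-factor-per-module
Gaussian model: OTU *i* in module *b* has
z_i = s_i·a_i·f_b + √(1−a_i²)·ε_i, so the planted correlation of a
within-module pair is s_i·s_j·a_i·a_j and between modules 0.  Design
features, each motivated by a property of real 16S data:

- **Loading gradient.**  Ordinary members get a_i = √ρ·u_i with u_i on a
  deterministic grid (default 0.55–0.9).  Most pairwise correlations then
  sit below the detectable threshold, giving sparse networks (average
  degree ~3–5) with right-skewed degree distributions, as empirical
  microbial networks have.  Setting `loading_range=(1, 1)` recovers
  uniform within-block correlation ρ for block-recovery benchmarks.
- **Hubs.**  One taxon per module carries the factor itself (loading 1)
  and a floor on its mean abundance — keystones are well-sampled, strongly
  coupled taxa.  Its planted correlations (up to ~0.9) exceed every
  member–member correlation (≤ 0.8·0.81), so thresholds inside that gap
  make hubs the top-degree nodes.
- **Signs.**  A fraction of members per module (solving 2q(1−q) = f⁻ for
  the flip rate q, supported for f⁻ < 0.5) has its loading sign flipped,
  interleaved across the loading gradient so the planted sign ratio
  survives threshold-based edge recovery.  Default f⁻ = 0.2 ≈ 80% positive
  associations, the range reported for gut co-occurrence networks.
- **Stable background.**  100 unstructured taxa carry ~65% of the reads
  with small latent variance.  Compositional closure subtracts a common
  log-total term from every profile; if the modules dominate the total,
  that term correlates with the module factors and biases positive pairs
  down and negative pairs up asymmetrically.  A stable background — the
  conserved core of a gut community — damps the closure term and keeps
  recovered sign proportions within a few points of the planted value.
- **Counts.**  Latents are exponentiated, closed to compositions, and
  drawn multinomially at 100k reads/sample (log-normal depth jitter via
  `overdispersion`); module-taxon mean log abundances are clipped at −0.5
  so network taxa are not vanishingly rare.  Bernoulli dropout
  (`zero_inflation`, default 1%) stresses the prevalence filter; because
  of the pseudo-count failure mode above, benchmarks that need clean
  planted structure set it to 0 and say so.
- **Matched margins.**  Per-OTU mean abundances come from a fixed,
  spec-independent generator, so two groups differing only in correlation
  structure have matched composition margins — alpha diversity is then a
  true null between arms while network density differs.

The PSD question does not arise: a factor model is positive semidefinite
by construction, for any sign pattern and loadings.

`generate_two_group_scenario` produces a control arm and a
better-connected arm (default: ρ + 0.2 and an upward-shifted loading
gradient).  The stability benchmark runs it at 24 samples per arm — the
scale of an arm pooled over adjacent timepoints — both because realized
network density at 12 samples fluctuates enough to occasionally invert a
planted density ordering, and because the left-skewed Shannon distribution
(skewness ≈ −0.9) needs groups of that size before the ANOVA F test holds
its nominal level.

## What the benchmarks show — and don't

The synthetic benchmarks validate machinery, not biology: they show the
RMT criterion separates Wigner from Poisson spacing statistics, that
threshold selection lands in the planted gap and module detection recovers
planted blocks (ARI ≥ 0.8), that empirical clustering/modularity exceed
degree-preserving nulls where structure was planted, that sign proportions
are recovered within a few points, and that a denser community is measured
as more robust.  Real 16S data adds abundance-dependent dropout,
taxonomic correlation of technical noise, uneven sequencing depth, and
compositional effects stronger than the generator's — none of which are
modelled here.  Passing these tests therefore certifies the pipeline's
correctness and its statistical behaviour under the stated model, not the
ecological validity of any particular network.

## Problem sizes

Default benchmark sizes — 200 module taxa + 100 background, 12–50 samples,
100-network ensembles, 100 removal repetitions, 20-seed replication — are
desk-scale: the full test suite runs in a few minutes on one CPU, and
`scripts/acceptance.py` in about two.
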