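# Methods

## Site-rate model

Sites of the amino-acid alignment evolve independently on a fixed rooted (or
basally multifurcating) tree under a reversible replacement process. The
default model is JTT: the rate matrix is Q = S·diag(π) with the classic
Jones-Taylor-Thornton exchangeabilities S and frequencies π embedded as
package constants, normalized to one expected substitution per unit branch
length. The `jtt+f` variant replaces π by the observed alignment frequencies
(with a 0.5 pseudo-count so all twenty stay positive). Transition matrices
P(t) = exp(Qt) come from one eigendecomposition of the symmetrized form
diag(√π)·Q·diag(1/√π); tiny negative entries from round-off are clipped at
zero, and t = 0 returns the exact identity so the zero-rate limit is exact.

Among-site rate variation is a discrete gamma prior with K = 16
equal-probability categories (shape = rate = α, so the continuous mean is 1).
Category rates are the conditional means within each quantile bin, which
keeps the mean of the category rates exactly 1 — the reason mean-of-bin was
chosen over median-of-bin.

Column likelihoods use Felsenstein pruning in linear space with per-column
rescaling at every internal node (log-accumulated), which keeps alignments
of hundreds of taxa away from underflow. Gaps and `X` contribute all-ones
leaf vectors (missing data). Columns that are gap/`X` in every taxon are
flagged `no_data`, assigned the prior mean rate, and excluded from Z
standardization.

The reported site rate is the empirical-Bayes posterior mean over the K
categories. α is either user-supplied or maximized over the marginal
log-likelihood with a bounded Brent search on [0.02, 20] (xatol 1e-4); the
returned value is the argmax of {lower bound, interior optimum, upper
bound}, with a warning when it sits on a boundary (e.g. alignments with no
rate signal). Branch lengths are taken from the input tree and never
re-optimized — a deliberate limitation: the pipeline analyses a fixed
alignment/tree pair. Z scores use the population SD (divisor n); a
zero-spread rate vector is an error rather than a silent all-zero output.

Coordinates are 1-based everywhere (residues and alignment columns), and all
reference-coordinate outputs drop columns gapped in the reference.

## Disorder integration and classification

Disorder tracks are per-residue scores in [0,1] with 0.5 as the
order/disorder cutoff; the boundary value counts as disordered (a convention
that had to be fixed; configurable). The heat-map matrix spreads each
taxon's track over its alignment row, masks gap cells, and orders rows by
the ladderized leaf order of the tree (ties between equal-size subtrees
broken by smallest contained label — deterministic). Per-column consensus
is "disordered" when ≥ 50% of the taxa with a residue in the column are at
or above the cutoff; the pipeline can instead use the reference track alone
(`disorder_consensus: reference_only`), since single-protein trace figures
are usually drawn from the reference prediction; the pipeline default is the
consensus call, which is what the synthetic ground truth controls.

Residues split at Z = 0: disordered ∧ Z < 0 is *constrained disorder*,
disordered ∧ Z ≥ 0 *flexible disorder*. The ordered/disordered Z
distributions are compared with a two-sided Mann-Whitney U test:
tie-corrected normal approximation in general, and exact enumeration over
all C(n+m, n) label assignments (midranks, so ties are handled) when both
groups have ≤ 8 observations. The exact two-sided p is the probability that
min(U, nm−U) is at most the observed min.

## Phosphosite conservation

Site calls require score ≥ 0.75 *and* an S/T/Y residue. A column is
conserved when the positive fraction reaches 50%, inclusive, with **all**
sequences of the alignment in the denominator (a gapped sequence counts as
a negative); a non-gap-only denominator is available by config. The
reference-coordinate report by default intersects conserved columns with
reference-positive calls ("conserved human sites"); conserved columns
gapped in the reference are reported separately.

## Variant context

Variants are filtered by a pathogenicity allow-list (default
`{"pathogenic"}`) and by agreement of the stated reference allele with the
reference sequence; failing rows are collected and reported, not fatal.
Context annotation joins domain membership (user-supplied intervals — the
shipped synthetic configs derive them from the generator's ordered blocks
and are labeled non-authoritative), structure/rate category, and the
absolute-distance to the nearest conserved phosphosite (0 = overlap; no
closeness threshold is imposed). Summaries are contingency tables over
(domain, structure, evolution) cells, site-weighted and case-weighted; cell
totals always equal the input counts.

## Phylogenetic profiling

Presence = ortholog-detection flag, or Smith-Waterman score ≥ 150 when
scores are given. Profiles are clustered agglomeratively on Manhattan
distances using Ward's method via the Lance-Williams update applied
directly to the dissimilarities (the `hclust ward.D` convention). "Ward" on
a non-Euclidean dissimilarity is ambiguous, so a `ward_d2` variant (update
on squared dissimilarities, square-root heights) is available by config.
Ties break on the lexicographically smallest cluster-index pair, making the
merge sequence deterministic; tests verify the merge sequence against an
independent oracle that recomputes every cluster-pair distance from scratch
via the error-sum-of-squares closed form, and against R's `hclust`.

The flat cut keeps the last k = 4 clusters (stop after n−k merges).
Cluster labels scan taxonomy groups broadest → narrowest (eukaryotes ⊇
multicellular ⊇ metazoans ⊇ chordates) and assign the first group with mean
presence ≥ 0.5 inside and < 0.25 outside (empty complement counts as 0);
otherwise "unresolved". Both thresholds are configurable — the class
definitions are an operationalization of depth-of-conservation labeling by
inspection, not a published rule.

## Tissue specificity

Per protein over n tissues: μ = mean TPM, s = population SD (divisor n,
as the statistic is defined — not the sample SD, which would shift every
threshold), threshold μ + 1.65·s, flag when TPM strictly exceeds it. 1.65
is the one-sided 90% normal confidence factor, so under a Gaussian null
about 5% of cells are flagged. No log transform is applied by default
(config option available). TPM is used as given; the statistic is
translation-equivariant and its flags are invariant to scaling a protein's
row.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the tests run under:

- **Tree**: Yule topology, 24 taxa, i.i.d. Exponential(0.1) branch lengths
  (substitutions/site) — a depth comparable to a chordate ortholog set.
- **Alignment**: 300 sites under JTT + discrete gamma (α = 0.5, K = 16);
  sites in disordered blocks get a 3x rate multiplier. Generated gap-free
  by default (an i.i.d. gap-masking option exists for gap-handling tests);
  real indel processes are *not* simulated, so tests say nothing about
  alignment quality effects.
- **Disorder**: block architecture (ordered/disordered/ordered/disordered ≈
  20/30/25/25% of sites); scores Beta(2,8) in ordered and Beta(8,2) in
  disordered regimes (means 0.2/0.8, cleanly straddling the 0.5 cutoff),
  independent per taxon and residue. Real disorder predictors produce
  spatially autocorrelated, taxon-correlated scores; this jitter model is
  deliberately simpler.
- **Phosphosites**: 6 sites planted at conservation 0.9 and 4 at 0.3; a
  planted site overwrites the chosen column with `S` in the sampled taxon
  subset (so the substitution process, and hence rate ground truth, is not
  preserved at those few columns) and assigns scores ≥ 0.8; background
  scores are Beta(2,6).
- **Profiles**: 4 planted classes × 15 proteins over 160 species (12
  chordates, 18 other metazoans, 40 other multicellular, 90 unicellular —
  each nesting level well under half of the next, as in real eukaryote
  samplings, which is what makes depth labeling identifiable); 5% i.i.d.
  flip noise.
- **Expression**: 200 proteins × 37 tissues, baseline TPM = exp(N(1,1)),
  nine proteins spiked 50x in the cerebral-cortex column.
- **Variants**: 18 pathogenic missense sites drawn with 4x weight inside
  domains (the generator's domains are its ordered blocks) plus 10 benign
  decoys; case counts 1 + Poisson(2).

One global seed spawns an independent substream per stage
(`numpy SeedSequence`), so bundles are bit-reproducible and stages can be
regenerated independently. Passing tests on these conditions demonstrates
algorithmic correctness and statistical power at this design point — not
robustness to misalignment, predictor bias, or database heterogeneity in
real data.

## Numerical and design notes

- Problem sizes in tests and the acceptance script (24 × 300 alignments,
  5-seed medians, 10⁴-protein nulls, 50 six-profile oracle cases) are chosen
  so the full suite runs in well under a minute of compute per stage while
  keeping the statistical checks sharp.
- Likelihood correctness is established against explicit ancestral-state
  enumeration (≤ 5 leaves) rather than against another pruning
  implementation, and re-rooting invariance is checked separately.
- The exact Mann-Whitney path and the asymptotic path are distinct code
  routes; they are cross-checked against each other and against permutation
  p-values.
- Degenerate inputs fail loudly: all-gap alignments, constant rate vectors,
  empty comparison groups, k > n cluster cuts, < 2 tissues, negative TPM.
- Newick trees with missing branch lengths default them to 0 with a warning;
  an unrooted basal trifurcation is accepted as-is because the likelihood
  under a reversible model is root-invariant.

## Known limitations

- Branch lengths and tree topology are never re-estimated; errors in the
  input tree propagate directly into site rates.
- The consensus disorder call weights all taxa equally (no phylogenetic
  down-weighting of dense clades).
- The four-cluster cut is taken as given (k is configurable but there is no
  automatic model selection for k).
- The specificity statistic assumes an approximately symmetric null per
  protein; on heavy-tailed TPM rows it flags more than the nominal 5%
  (visible in the synthetic log-normal baseline).
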