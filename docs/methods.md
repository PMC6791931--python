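# Methods

`loenet` implements a network-based Lines-of-Evidence (LOE) analysis for
prioritizing candidate genes connected to a curated *anchor set* — genes and
metabolite phenotypes with documented roles in a biological system of
interest (the motivating application is cell wall biosynthesis and
regulation in a *Populus trichocarpa* GWAS population).  This note records
the model, its assumptions, the tunable parameters, the design choices made
where the design was genuinely open, and what the synthetic test worlds do
and do not demonstrate.

## The data layers

Each omics data set is represented as an undirected network over gene and
metabolite nodes.  Metabolite ids are namespaced (`met:`) on ingest so they
can never collide with gene ids.

**Coexpression / comethylation.**  All-pairs Spearman rank correlation
(average ranks for ties) between feature profiles across samples, with an
absolute threshold: 0.85 for expression and 0.95 for methylation by
default.  The stricter methylation threshold reflects its far smaller
sample dimension (10 tissue profiles vs 64 expression conditions), which
inflates the spread of spurious correlations.  Edge weight is the
correlation; the sign records its direction.  Zero-variance features are
excluded (correlation undefined) and logged.

**SNP correlation (CCC).**  Population-level co-segregation between
biallelic SNP dosage vectors u, v ∈ {0,1,2}ⁿ, using the two-way custom
correlation coefficient as defined in the GPU implementation of the
measure.  With allele indicators σ₁(x) = x and σ₀(x) = 2 − x,

    f_i  = Σ_k σ_i(u_k) / (2n)                    (allele frequency)
    f_ij = Σ_k σ_i(u_k) σ_j(v_k) / (4n)           (duo frequency)
    c_ij = (9/2) · f_ij · (1 − ⅔ f_i)(1 − ⅔ f_j)

and CCC(u, v) = max over the four allele pairs (i, j).  The measure lies
in [0, 1] and attains 1 exactly for perfectly co-segregating balanced
homozygous patterns; note that *arbitrary* identical vectors score below 1
when the minor-allele frequency deviates from 0.5 or heterozygotes are
present — the measure rewards informative co-segregation, not mere
equality.  Missing genotypes are excluded pairwise rather than imputed.
Pairs on the same chromosome within 10 kb are discarded (a linkage-
disequilibrium guard); retained pairs (CCC ≥ 0.7) are projected onto the
genes containing the SNPs (position within [start, end], 1-based
inclusive, strand-agnostic), same-gene pairs are dropped, and multiple SNP
pairs hitting one gene pair collapse to a single edge keeping the maximum
CCC (the strongest evidence; order-independent).  The SNP–SNP measure is
pluggable so r² can be swapped in for sensitivity analyses.

**GWAS layers.**  Gene–metabolite edges from association tables
(weight −log10 p).  The pipeline consumes p-values — the mixed-model and
kernel-based association fits themselves are out of scope — and applies
Benjamini–Hochberg FDR control at 0.1 per layer.  SNP-level rows are
assigned to every gene whose interval contains the SNP: strict gene bodies
for the traditional layer (a flank flag is provided; the source procedure
does not state one), ±2 kb flanks for rare-variant gene regions.
Gene-level rows pass through.

**eQTN layer.**  The same association machinery with transcript phenotypes
(gene nodes).  Expression phenotypes are prepared by masking TPM values
more than 5.0 unscaled MADs from the *non-zero* median of the transcript
and retaining transcripts with a non-outlier observed value in more than
20% of samples.  The eQTN multiple-testing correction is hierarchical: BH
across phenotypes at q₁ = 0.1 on a per-phenotype summary p-value, then the
Gavrilov–Benjamini–Sarkar step-down within surviving phenotypes at
q₂ = 5.1e-4 with critical values c_i = i·q₂ / (m + 1 − i·(1 − q₂)).  The
round-1 summary statistic is not fixed by the source description; the
per-phenotype *minimum* p is used, following the hierarchical-correction
literature, and is configurable.  Note the step-down is adaptive, not
uniformly more conservative than BH: for i > 1/(1 − q) its critical values
exceed BH's, so it can reject more hypotheses on some p-vectors.

## Phenotype cleaning and genotype filters

Metabolite phenotypes are screened with an unscaled MAD filter: samples
more than k = 6 MADs from the population median are masked, where
MAD = median(|x − median(x)|) without the 1.4826 consistency constant (the
rule counts MADs from the median directly).  When MAD = 0 the threshold is
undefined; nothing is removed and a warning is logged, rather than
discarding a near-constant phenotype wholesale.  The filter is invariant
to affine transforms of the data.

SNPs are filtered on minor-allele frequency (≥ 0.01) and missingness.  The
source description states two irreconcilable call-rate cutoffs (0.5 in the
genotype preparation, 0.75 in the association testing); the missingness
bound is therefore an explicit parameter (`max_missing`, default 0.5
missing fraction allowed) and both values are noted here.

## LOE scoring, thresholding, tiers

From each layer a 1-hop network is extracted: all edges incident to at
least one anchor node.  For every non-anchor gene,

* **depth per layer** = number of *distinct* anchor partners in that
  layer's 1-hop network (deduplication guards against multi-SNP
  projections; layers are simple graphs so this equals edge multiplicity),
* **breadth** = number of layers with depth > 0,
* **total depth** = Σ depths, and
* **discounted depth** = total depth − comethylation depth.

Anchor genes are excluded from the candidate score table by default (they
are by definition already known actors) but remain network nodes; a flag
restores them for diagnostics.  Coexpression connections are additionally
tallied by sign, since uniformly negative coexpression with anchors hints
at repression.

A gene is **high-LOE** iff breadth ≥ 3 (parameter; chosen where the
breadth distribution typically shows an inflection — the score table lets
users draw their own histogram) *and* it has at least one traditional or
rare-variant metabolite-GWAS connection, the only direct phenotype
readout.  The merged LOE network keeps the 1-hop edges whose endpoints are
both anchors or high-LOE genes, each edge labeled with its source
layer(s).  The phrase "thresholded, then merged" is implemented in exactly
this sense: neighbors failing the threshold drop out of the merged
network, which is why randomized networks (below) can score zero.

High-LOE genes are ranked into tiers on (breadth, discounted depth):
Tier 1 iff breadth ≥ 4, or breadth = 3 with discounted depth ≥ 5;
Tier 2 iff breadth = 3 with discounted depth = 4; Tier 3 otherwise.
Within tiers genes sort by breadth desc, discounted depth desc, then gene
id — the id tie-break makes output deterministic where the source
procedure is silent.  A user-supplied exclusion list (genes with
previously documented roles) is removed last, with per-tier removal counts
reported.

## Validation procedures

**Shuffled-data correlation test.**  Expression (or methylation) values
are permuted within each gene across samples — marginals preserved,
sample-linked structure destroyed.  Correlation values are subsampled from
each shuffled data set (distinct unordered pairs, uniformly, without
replacement up to the number of available pairs; beyond that, with
replacement) and pooled; an equally sized pool is drawn from the observed
matrix.  The pools are compared with the two-sided Wilcoxon rank-sum test
(exact enumeration when min(n, m) ≤ 8 and the pooled values are tie-free,
normal approximation otherwise) and by the fraction of |ρ| above the layer
threshold in each pool.

**GO functional-network intersection.**  From flat GO annotations (no DAG
propagation), genes sharing a term are connected with weight 1/(term gene
count) — inverse size, so rarer terms score higher; any positive
proportionality constant cancels in the observed-vs-null comparison.
Terms above 1000 genes are removed (overly generic), and a pair sharing
several terms keeps only its highest-weight edge (ties broken by term id).
For each of 100 replicates, every input layer's 1-hop network is
randomized by relabeling neighbors with genes drawn uniformly *without
replacement* from the genome minus the anchors — a bijection, so node
count, edge count and per-anchor degrees are exactly preserved
(with-replacement draws would merge nodes and shrink the network).  LOE
scoring, thresholding and merging then run unchanged on the randomized
layers, and the merged network's *intersect score* — the sum of GO edge
weights over gene pairs present in both networks, each shared pair counted
once — is recorded.  The observed score is summarized against the null
distribution with the add-one empirical exceedance
p = (1 + #{null ≥ observed}) / (n + 1).  Anchor–anchor pairs count toward
the score by default (they are held constant across randomizations and
cancel in the comparison); a flag excludes them.

**GO enrichment.**  Upper-tail hypergeometric p-values per term over a
stated gene universe, BH-corrected at 0.1; terms with zero overlap are
skipped.

## The synthetic worlds

The generator (`loenet.simulate`) emulates every input at desk scale:
block-correlated expression (64 samples) and methylation (10 samples)
matrices, genotypes with planted co-segregating SNP pairs and coordinates
exercising the 10-kb rule (including a decoy pair 3 kb apart that the rule
must reject), association tables for both GWAS layers, gene coordinates,
anchor lists, and GO annotations in which each planted candidate shares a
small (weight-0.2) term with one of its anchor partners while anchors and
background genes share one large generic term.

Correlation blocks use a latent one-factor Gaussian model.  The factor
loading is set from the target *Spearman* correlation via the Gaussian
identity ρ_S = (6/π) asin(ρ_P/2); a monotone exponential transform then
maps latents to non-negative TPM-like values without touching rank
structure.  Block factors are drawn mutually orthogonal in sample space:
blocks model independent pathways, and orthogonality removes the shared
spurious cross-block correlation (standard error ≈ 1/√n per factor pair)
that independent draws would induce at these sample sizes.  Default
within-block targets are 0.95 for expression (threshold 0.85) and 0.999
for methylation (threshold 0.95 on 10 samples, where rank flips are
cheap) — wide margins by design.  Planted genotype pairs are balanced
homozygous copies (CCC exactly 1 at zero copy error; a configurable flip
probability models imperfect linkage).  Planted association rows carry
p = 1e-8; background rows draw p ~ U(0, 1) against decoy metabolites,
while background rows that involve an anchor metabolite draw
p ~ U(0.2, 1), which BH at 0.1 can never reject.

Recovery assertions are deterministic, not statistical: after drawing each
matrix the generator rebuilds the corresponding layer with the production
layer builders and compares anchor-incident edges to the planted design,
resampling offending background features (or redrawing a block) until the
realized network matches.  All resampling continues one seeded stream, so
a given seed yields a byte-identical world.  The default world holds
1,000 genes, 20 anchor genes, 10 anchor metabolites and 15 planted
candidates spanning all three tiers plus three decoys that must fail the
merge threshold (one with breadth 3 but no GWAS edge, one with breadth 2,
one with breadth 1).

What passing tests on these worlds show — and do not show.  They show the
pipeline's bookkeeping is exact (scores, thresholds, tiers, network
algebra) and that both validation procedures separate planted signal from
label- and permutation-nulls with wide margins.  They do not show
performance on real data: real expression matrices have pervasive
correlation structure rather than clean orthogonal blocks, real LD decays
continuously rather than vanishing at 10 kb, genotype MAF spectra are
skewed, GO annotations are hierarchical and incomplete, and effect sizes
are not chosen to clear thresholds by 8 standard errors.  Scaled problem
sizes used by the test suite and the acceptance script (worlds of 100–1,000
genes, 10 shuffles × 10,000 subsamples, 50 replicate worlds × 100
randomized networks) are the package's chosen desk-scale study conditions;
the published analysis ran at genome scale (tens of thousands of genes,
10M correlation subsamples).

## Numerical choices and degenerate inputs

* Spearman correlations use average ranks; zero-variance features are
  excluded rather than producing NaN edges.
* CCC is clamped to [0, 1] against ≤ 2·10⁻¹⁶ float overshoot of the
  analytic bound; pairs with fewer than 2 informative samples are skipped
  and logged.
* TPM conversion guards all-zero sample columns (zeros plus a warning).
* BH on an empty p-vector returns an empty result; GBS at q ≥ 1 errors.
* Network edges are stored once under canonical (lexicographic) node
  order; writers sort records, so output is independent of insertion
  order and byte-stable.  Weights are serialized with `repr` for lossless
  round-trips.
* Per-stage seeds derive from the global seed by stable BLAKE2 hashing of
  stage names (kept below 2³¹), so stages are independently reproducible.
* BED gene tables are converted to 1-based inclusive coordinates on read;
  the conversion is logged.

## Known limitations

* The traditional-GWAS SNP→gene assignment defaults to strict gene bodies;
  whether the original analysis used flanks there is not stated.
* GO annotations are taken as a flat file; no ancestor closure or semantic
  similarity.
* The CCC layer is all-pairs over desk-scale SNP panels; genome-scale
  all-pairs scans need the parallel implementations this package's
  definition mirrors.
* Only GT fields of minimal VCFs are read; richer VCF content is out of
  scope.
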