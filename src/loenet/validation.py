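"""Randomization-based validation of the LOE network.

Two complementary null models probe whether the pipeline's networks carry
real biological signal:

1. **Shuffled-data correlation comparison.**  Expression (or methylation)
   values are permuted *within* each gene across samples, preserving every
   gene's marginal distribution while destroying sample-linked structure.
   Correlation values subsampled from shuffled data sets form a null pool
   that is compared to a pool subsampled from the observed data with the
   Wilcoxon rank-sum test, and the fraction of correlations surviving the
   layer threshold is compared between pools.

2. **GO functional-network intersection.**  A weighted gene-gene functional
   network is built from flat GO annotations: genes sharing a term are
   connected with weight 1/(term size) -- rarer terms are more informative
   -- terms above a size cap are removed, and a pair sharing several terms
   keeps only the highest-scoring edge.  Randomized LOE networks are
   produced by relabeling the 1-hop neighbors of each input layer with
   genes drawn uniformly from the genome (anchors and edge structure held
   fixed), re-scoring, re-thresholding and re-merging; the observed merged
   network's intersect score (sum of GO edge weights over shared gene
   pairs) is compared to the null distribution of randomized scores.

Hypergeometric GO term enrichment (BH-corrected) lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .core import OneHopNetwork, compute_loe_scores, threshold_and_merge
from .io import AnchorSet, GoAnnotation, Network, OmicsMatrix, canonical_pair
from .phenotype import bh_fdr

logger = logging.getLogger("loenet")


# ---------------------------------------------------------------------------
# shuffled-data correlation test
# ---------------------------------------------------------------------------


def shuffle_within_rows(m: OmicsMatrix, seed: int) -> OmicsMatrix:
    """Independently permute each row's values across columns.

    Row multisets are preserved exactly; reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    values = m.data.to_numpy(dtype=float, copy=True)
    for i in range(values.shape[0]):
        values[i] = values[i, rng.permutation(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=m.data.index, columns=m.data.columns))


def _pair_from_linear(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Decode linear indices over the strict upper triangle of an n x n grid."""
    # row i owns indices [i*n - i*(i+1)/2, ...) of length n-1-i
    i = (n - 2 - np.floor(
        np.sqrt(-8.0 * k + 4.0 * n * (n - 1) - 7.0) / 2.0 - 0.5
    )).astype(np.int64)
    j = (k + i + 1 - i * n + i * (i + 1) // 2).astype(np.int64)
    return i, j


def subsample_correlations(
    m: OmicsMatrix, n: int, seed: int, replace: bool = False
) -> np.ndarray:
    """Spearman rho values for uniformly sampled distinct unordered gene pairs.

    Zero-variance features are excluded (rho undefined).  Sampling is
    without replacement by default; ``replace=True`` permits n beyond the
    number of available pairs.  ``n`` equal to the number of pairs (without
    replacement) returns the full correlation multiset.
    """
    data = m.data.to_numpy(dtype=float)
    data = data[data.std(axis=1) > 0]
    k = data.shape[0]
    if k < 2:
        raise ValueError("need at least 2 variable features to sample correlations")
    total = k * (k - 1) // 2
    if not replace and n > total:
        raise ValueError(f"cannot draw {n} distinct pairs from {total}")
    rng = np.random.default_rng(seed)
    linear = rng.choice(total, size=n, replace=replace)
    ii, jj = _pair_from_linear(np.asarray(linear, dtype=np.int64), k)
    ranks = rankdata(data, method="average", axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1)
    return np.einsum("ij,ij->i", ranks[ii], ranks[jj]) / (norms[ii] * norms[jj])


def ranksum_compare(observed, null) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum comparison of two pools.

    Exact enumeration when min(n, m) <= 8, normal approximation otherwise.
    Returns (statistic, two-sided p).
    """
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([observed, null])
    ties = np.unique(pooled).size < pooled.size
    if min(observed.size, null.size) <= 8 and not ties:
        res = stats.mannwhitneyu(observed, null, alternative="two-sided", method="exact")
    else:
        res = stats.ranksums(observed, null)
    return float(res.statistic), float(res.pvalue)


def shuffle_validation(
    m: OmicsMatrix,
    threshold: float,
    n_shuffles: int = 100,
    n_subsample: int = 100_000,
    seed: int = 0,
) -> dict:
    """Observed-vs-shuffled correlation comparison for one omics matrix.

    Draws ``n_subsample`` correlation values from each of ``n_shuffles``
    within-row shuffled data sets (pooled null) and the same total number
    from the observed data, compares the pools with the rank-sum test and
    reports the fraction of |rho| >= ``threshold`` in each pool.  When the
    requested observed pool exceeds the number of distinct pairs, observed
    values are drawn with replacement.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_shuffles + 1)
    null_pool = np.concatenate(
        [
            subsample_correlations(
                shuffle_within_rows(m, int(seeds[2 * i])),
                n_subsample,
                int(seeds[2 * i + 1]),
                replace=_needs_replacement(m, n_subsample),
            )
            for i in range(n_shuffles)
        ]
    )
    n_observed = n_shuffles * n_subsample
    observed_pool = subsample_correlations(
        m, n_observed, int(seeds[-1]), replace=_needs_replacement(m, n_observed)
    )
    statistic, pvalue = ranksum_compare(observed_pool, null_pool)
    frac_obs = float(np.mean(np.abs(observed_pool) >= threshold))
    frac_null = float(np.mean(np.abs(null_pool) >= threshold))
    return {
        "statistic": statistic,
        "pvalue": pvalue,
        "threshold": threshold,
        "frac_observed": frac_obs,
        "frac_null": frac_null,
        "n_observed": int(observed_pool.size),
        "n_null": int(null_pool.size),
    }


def _needs_replacement(m: OmicsMatrix, n: int) -> bool:
    k = int((m.data.to_numpy().std(axis=1) > 0).sum())
    return n > k * (k - 1) // 2


# ---------------------------------------------------------------------------
# GO functional network
# ---------------------------------------------------------------------------


@dataclass
class GoNetwork:
    """Weighted gene-gene functional network from shared GO terms.

    ``edges`` maps canonical gene pairs to (weight, winning term).  Edge
    weight is 1 / (term gene count); a pair annotated by several terms
    keeps the maximum-weight (rarest-term) edge, ties broken by term id for
    determinism.
    """

    edges: dict = field(default_factory=dict)

    def weight(self, a: str, b: str) -> float:
        rec = self.edges.get(canonical_pair(a, b))
        return rec[0] if rec else 0.0

    @property
    def total_weight(self) -> float:
        return float(sum(w for w, _ in self.edges.values()))

    def to_network(self) -> Network:
        net = Network("go")
        for (a, b), (w, term) in self.edges.items():
            net.add_edge(a, b, weight=w, sign="n/a", layer=f"go:{term}")
        return net


def build_go_network(ann: GoAnnotation, max_term_size: int = 1000) -> GoNetwork:
    """Connect gene pairs sharing a GO term with weight 1/(term size).

    Terms annotating more than ``max_term_size`` genes are removed before
    pairing (they would produce an overly dense network of generic
    function); single-gene terms contribute no edges.
    """
    go = GoNetwork()
    term_genes = ann.term_genes
    for term in sorted(term_genes):
        genes = sorted(term_genes[term])
        c = len(genes)
        if c < 2 or c > max_term_size:
            continue
        w = 1.0 / c
        for i in range(c):
            for j in range(i + 1, c):
                key = (genes[i], genes[j])
                old = go.edges.get(key)
                if old is None or w > old[0]:
                    go.edges[key] = (w, term)
    return go


def intersect_score(
    net: Network,
    go: GoNetwork,
    include_anchor_pairs: bool = True,
    anchors: AnchorSet | None = None,
) -> float:
    """Sum of GO edge weights over gene pairs present in both networks.

    Each shared pair counts once regardless of how many layers contribute
    it; metabolite nodes are ignored.  ``include_anchor_pairs=False``
    excludes pairs whose endpoints are both anchors.
    """
    pairs = net.gene_edge_pairs()
    if not include_anchor_pairs:
        if anchors is None:
            raise ValueError("anchors required to exclude anchor-anchor pairs")
        nodes = anchors.all_nodes
        pairs = {p for p in pairs if not (p[0] in nodes and p[1] in nodes)}
    return float(sum(go.weight(a, b) for a, b in pairs))


# ---------------------------------------------------------------------------
# randomized LOE networks
# ---------------------------------------------------------------------------


def randomize_one_hop(oh: OneHopNetwork, universe, seed: int) -> OneHopNetwork:
    """Relabel 1-hop neighbors with genes drawn uniformly from the genome.

    Anchor nodes and the edge structure are held constant; each distinct
    neighbor label is replaced by a distinct gene drawn without replacement
    from ``universe`` minus the anchors, so node count, edge count and
    per-anchor degree are all preserved.
    """
    neighbors = sorted(oh.neighbors)
    pool = sorted(set(universe) - set(oh.anchors))
    if len(pool) < len(neighbors):
        raise ValueError(
            f"universe too small: {len(pool)} candidate labels for "
            f"{len(neighbors)} neighbors"
        )
    rng = np.random.default_rng(seed)
    new_labels = rng.choice(len(pool), size=len(neighbors), replace=False)
    relabel = {old: pool[int(i)] for old, i in zip(neighbors, new_labels)}
    out = Network(oh.layer_name)
    for a, b, layer, weight, sign in oh.network.iter_records():
        out.add_edge(relabel.get(a, a), relabel.get(b, b), weight=weight, sign=sign, layer=layer)
    return OneHopNetwork(oh.layer_name, out, oh.anchors)


def randomized_intersect_scores(
    one_hops: list[OneHopNetwork],
    anchors: AnchorSet,
    universe,
    go: GoNetwork,
    n_random: int = 100,
    seed: int = 0,
    min_breadth: int = 3,
    require_gwas: bool = True,
    include_anchor_pairs: bool = True,
) -> np.ndarray:
    """Intersect scores of ``n_random`` randomized, re-scored LOE networks.

    Each replicate randomizes every input layer once, then reruns LOE
    scoring, thresholding and merging unchanged on the randomized layers
    before intersecting with the GO network.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_random * len(one_hops))
    scores_out = np.empty(n_random)
    it = iter(seeds)
    for r in range(n_random):
        random_layers = [randomize_one_hop(oh, universe, int(next(it))) for oh in one_hops]
        # genes scoring zero cannot pass the threshold, so the scoring
        # universe can be restricted to genes actually touching a layer
        scores = compute_loe_scores(random_layers, anchors, universe=())
        merged, _high = threshold_and_merge(
            random_layers, scores, min_breadth=min_breadth, require_gwas=require_gwas
        )
        scores_out[r] = intersect_score(
            merged, go, include_anchor_pairs=include_anchor_pairs, anchors=anchors
        )
    return scores_out


@dataclass
class NullDistribution:
    """Observed statistic plus its randomization null."""

    observed: float
    null_scores: np.ndarray
    seed: int

    @property
    def n_randomizations(self) -> int:
        return int(self.null_scores.size)


def null_validation(observed_score: float, null_scores, n_bins: int = 20) -> dict:
    """Summarize an observed statistic against randomized scores.

    The empirical exceedance p-value uses the add-one permutation
    convention: p = (1 + #{null >= observed}) / (n + 1).  Histogram data for
    a side-by-side plot of the null distribution is included.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("need at least one randomized score")
    n = null_scores.size
    p = (1 + int((null_scores >= observed_score).sum())) / (n + 1)
    counts, edges = np.histogram(null_scores, bins=n_bins)
    return {
        "observed": float(observed_score),
        "null_min": float(null_scores.min()),
        "null_max": float(null_scores.max()),
        "null_mean": float(null_scores.mean()),
        "n_randomizations": n,
        "p_empirical": float(p),
        "histogram_counts": counts.tolist(),
        "histogram_edges": edges.tolist(),
    }


def functional_validation(
    one_hops: list[OneHopNetwork],
    anchors: AnchorSet,
    universe,
    go: GoNetwork,
    n_random: int = 100,
    seed: int = 0,
    min_breadth: int = 3,
    require_gwas: bool = True,
    include_anchor_pairs: bool = True,
) -> dict:
    """Full GO-network intersect validation of an LOE analysis."""
    scores = compute_loe_scores(one_hops, anchors, universe=())
    merged, _ = threshold_and_merge(
        one_hops, scores, min_breadth=min_breadth, require_gwas=require_gwas
    )
    observed = intersect_score(
        merged, go, include_anchor_pairs=include_anchor_pairs, anchors=anchors
    )
    nulls = randomized_intersect_scores(
        one_hops,
        anchors,
        universe,
        go,
        n_random=n_random,
        seed=seed,
        min_breadth=min_breadth,
        require_gwas=require_gwas,
        include_anchor_pairs=include_anchor_pairs,
    )
    return null_validation(observed, nulls)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------


def go_enrichment(
    genes, ann: GoAnnotation, universe, q: float = 0.1
) -> pd.DataFrame:
    """Upper-tail hypergeometric GO-term enrichment with BH correction.

    For each term with non-zero overlap with the query set, the p-value is
    P(X >= k) for X ~ Hypergeometric(N=|universe|, K=|term ∩ universe|,
    n=|query|).  Terms with zero overlap are skipped.  Returns a DataFrame
    sorted by p with BH q-values and rejection flags at level ``q``.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    if not genes:
        return pd.DataFrame(
            columns=["term", "term_size", "overlap", "p_value", "q_value", "significant"]
        ).set_index("term")
    N, n_query = len(universe), len(genes)
    records = []
    for term, term_genes in sorted(ann.term_genes.items()):
        in_universe = term_genes & universe
        overlap = len(term_genes & genes)
        if overlap == 0:
            continue
        K = len(in_universe)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n_query))
        records.append((term, K, overlap, min(p, 1.0)))
    if not records:
        return pd.DataFrame(
            columns=["term", "term_size", "overlap", "p_value", "q_value", "significant"]
        ).set_index("term")
    table = pd.DataFrame(records, columns=["term", "term_size", "overlap", "p_value"])
    mt = bh_fdr(table["p_value"].to_numpy(), q=q)
    table["q_value"] = mt.qvalues
    table["significant"] = mt.reject
    return table.sort_values(["p_value", "term"]).set_index("term")
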