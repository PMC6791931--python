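"""Construction of the LOE input layers.

Each omics data set becomes one :class:`~loenet.io.Network` ("layer"):

* **coexpression / comethylation** -- all-pairs Spearman correlation between
  feature profiles, thresholded on |rho| (0.85 for expression, 0.95 for
  methylation by convention); edge weight is rho and the sign records the
  correlation direction.
* **snp_correlation** -- a co-segregation measure (CCC) between genotype
  dosage vectors; SNP pairs on the same chromosome must be more than 10 kb
  apart (a linkage-disequilibrium guard), pairs are projected onto the genes
  containing the SNPs, and multiple qualifying SNP pairs hitting the same
  gene pair collapse to a single edge keeping the maximum CCC.
* **gwas_traditional / gwas_rare / eqtn** -- significance-filtered
  association tables mapped to gene--phenotype edges weighted by -log10(p).
  SNP-level rows are assigned to every gene whose body (plus an optional
  flank, 2 kb for rare-variant regions) contains the SNP; gene-level rows
  pass through.

The CCC between two dosage vectors u, v in {0,1,2}^n follows the published
two-way definition used by the GPU implementation of the measure: with
allele indicators sigma_1(x) = x and sigma_0(x) = 2 - x,

    f_i   = sum_k sigma_i(u_k) / (2n)          (allele frequency)
    f_ij  = sum_k sigma_i(u_k) sigma_j(v_k) / (4n)   (duo frequency)
    c_ij  = (9/2) * f_ij * (1 - (2/3) f_i) * (1 - (2/3) f_j)

and CCC(u, v) = max over the four allele pairs (i, j).  The measure lies in
[0, 1], is symmetric, and attains 1 exactly for perfectly co-segregating
balanced homozygous patterns.  Missing entries are removed pairwise.  The
SNP-SNP measure is pluggable (``measure=``) so that e.g. r^2 can be swapped
in for sensitivity analyses.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import rankdata

from .io import GenotypeMatrix, Network, OmicsMatrix, met_id
from .phenotype import bh_fdr

logger = logging.getLogger("loenet")

CCC_MULTIPLIER = 9.0 / 2.0
CCC_PARAM = 2.0 / 3.0


# ---------------------------------------------------------------------------
# correlation layers (Spearman)
# ---------------------------------------------------------------------------


def spearman_matrix(m: OmicsMatrix) -> tuple[np.ndarray, list[str]]:
    """All-pairs Spearman rho over sample vectors.

    Zero-variance features are excluded (rho undefined) and logged.  Ties are
    handled by average ranks.  Returns the correlation matrix and the ids of
    the features actually paired, in matrix order.
    """
    data = m.data.to_numpy(dtype=float)
    variable = data.std(axis=1) > 0
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info("excluded %d zero-variance feature(s) from correlation", n_dropped)
    kept = [f for f, v in zip(m.feature_ids, variable) if v]
    if len(kept) < 2:
        return np.zeros((len(kept), len(kept))), kept
    ranks = rankdata(data[variable], method="average", axis=1)
    rho = np.corrcoef(ranks)
    return rho, kept


def build_correlation_layer(
    m: OmicsMatrix, threshold: float, layer_name: str
) -> Network:
    """Spearman correlation network keeping edges with |rho| >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if m.data.shape[1] < 3:
        raise ValueError("need at least 3 samples for a correlation layer")
    rho, kept = spearman_matrix(m)
    net = Network(layer_name)
    for gene in kept:
        net.add_node(gene, kind="gene")
    n = len(kept)
    if n >= 2:
        ii, jj = np.triu_indices(n, k=1)
        strong = np.abs(rho[ii, jj]) >= threshold
        for i, j in zip(ii[strong], jj[strong]):
            r = float(rho[i, j])
            net.add_edge(kept[i], kept[j], weight=r, sign="+" if r >= 0 else "-")
    return net


# ---------------------------------------------------------------------------
# SNP co-segregation (CCC)
# ---------------------------------------------------------------------------


def ccc(u, v) -> float:
    """Custom correlation coefficient between two dosage vectors in {0,1,2}.

    Missing entries (NaN) are removed pairwise; at least 2 informative
    samples are required.  See the module docstring for the definition.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("dosage vectors must have equal length")
    keep = ~(np.isnan(u) | np.isnan(v))
    u, v = u[keep], v[keep]
    n = u.size
    if n < 2:
        raise ValueError("fewer than 2 informative samples")
    best = 0.0
    for su in (u, 2.0 - u):
        fu = su.sum() / (2.0 * n)
        for sv in (v, 2.0 - v):
            fv = sv.sum() / (2.0 * n)
            fuv = float(su @ sv) / (4.0 * n)
            c = CCC_MULTIPLIER * fuv * (1.0 - CCC_PARAM * fu) * (1.0 - CCC_PARAM * fv)
            best = max(best, c)
    return float(min(best, 1.0))  # guard float overshoot of the analytic bound


def _ccc_matrix(dosages: np.ndarray) -> np.ndarray:
    """Vectorized all-pairs CCC for a complete (no-missing) dosage matrix."""
    n = dosages.shape[1]
    alleles = (dosages, 2.0 - dosages)
    freqs = [a.sum(axis=1) / (2.0 * n) for a in alleles]
    best = np.full((dosages.shape[0],) * 2, -np.inf)
    for ai, fi in zip(alleles, freqs):
        wi = 1.0 - CCC_PARAM * fi
        for aj, fj in zip(alleles, freqs):
            wj = 1.0 - CCC_PARAM * fj
            fij = (ai @ aj.T) / (4.0 * n)
            np.maximum(best, CCC_MULTIPLIER * fij * np.outer(wi, wj), out=best)
    return np.minimum(best, 1.0)


def _gene_interval_trees(genes: pd.DataFrame, flank_bp: int = 0) -> dict:
    trees: dict[str, IntervalTree] = {}
    for gene_id, row in genes.iterrows():
        start = max(1, int(row["start"]) - flank_bp)
        end = int(row["end"]) + flank_bp
        trees.setdefault(str(row["chromosome"]), IntervalTree()).addi(
            start, end + 1, gene_id  # half-open tree over 1-based inclusive coords
        )
    return trees


def snps_to_genes(snp_meta: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 0) -> dict:
    """Map each SNP id to the (possibly several) genes containing it.

    A SNP is "in" a gene when its position lies within [start - flank_bp,
    end + flank_bp], both coordinates 1-based inclusive, irrespective of
    strand.  SNPs contained in no gene map to an empty list.
    """
    trees = _gene_interval_trees(genes, flank_bp)
    mapping: dict[str, list[str]] = {}
    for snp_id, row in snp_meta.iterrows():
        tree = trees.get(str(row["chromosome"]))
        hits = sorted(iv.data for iv in tree[int(row["position"])]) if tree else []
        mapping[snp_id] = hits
    return mapping


def build_snp_correlation_layer(
    g: GenotypeMatrix,
    genes: pd.DataFrame,
    ccc_min: float = 0.7,
    min_dist_bp: int = 10_000,
    measure=None,
) -> Network:
    """Gene-gene network from co-segregating SNP pairs.

    All SNP pairs with measure >= ``ccc_min`` and either on different
    chromosomes or more than ``min_dist_bp`` apart are projected to the genes
    containing the SNPs.  Pairs whose SNPs fall in the same gene are
    discarded; multiple SNP pairs hitting the same gene pair collapse to one
    edge keeping the maximum score.
    """
    snp_ids = g.snp_ids
    dosages = g.dosages.to_numpy(dtype=float)
    chrom = g.snp_meta["chromosome"].to_numpy(dtype=str)
    pos = g.snp_meta["position"].to_numpy(dtype=int)
    mapping = snps_to_genes(g.snp_meta, genes, flank_bp=0)

    complete = not np.isnan(dosages).any()
    scores = _ccc_matrix(dosages) if (complete and measure is None) else None
    fn = measure if measure is not None else ccc

    best: dict[tuple[str, str], float] = {}
    n_skipped = 0
    for i, j in itertools.combinations(range(len(snp_ids)), 2):
        if chrom[i] == chrom[j] and abs(int(pos[i]) - int(pos[j])) <= min_dist_bp:
            continue
        genes_i, genes_j = mapping[snp_ids[i]], mapping[snp_ids[j]]
        if not genes_i or not genes_j:
            continue
        if scores is not None:
            score = float(scores[i, j])
        else:
            try:
                score = float(fn(dosages[i], dosages[j]))
            except ValueError:
                n_skipped += 1
                continue
        if score < ccc_min:
            continue
        for ga in genes_i:
            for gb in genes_j:
                if ga == gb:
                    continue  # both SNPs inside one gene: self-pair
                key = (ga, gb) if ga <= gb else (gb, ga)
                if score > best.get(key, -np.inf):
                    best[key] = score
    if n_skipped:
        logger.info("skipped %d SNP pair(s) with <2 informative samples", n_skipped)
    net = Network("snp_correlation")
    for (ga, gb), score in best.items():
        net.add_edge(ga, gb, weight=score, sign="n/a")
    return net


# ---------------------------------------------------------------------------
# association layers (GWAS / eQTN)
# ---------------------------------------------------------------------------


def build_association_layer(
    table: pd.DataFrame,
    genes: pd.DataFrame,
    layer_tag: str,
    snp_meta: pd.DataFrame | None = None,
    flank_bp: int = 0,
    significance_q: float | None = None,
) -> Network:
    """Gene--phenotype network from an association table.

    Rows are restricted to ``layer_tag``.  When ``significance_q`` is given,
    Benjamini-Hochberg FDR control at that level is applied to the p-values
    here; otherwise rows are assumed already significance-filtered.  Rows
    whose unit is a known gene pass through; SNP-level rows (units present
    in ``snp_meta``) are mapped to every gene whose flanked interval contains
    the SNP.  Units mapping to no gene are dropped with a logged count.
    Edge weight is -log10(p); repeated gene--phenotype pairs keep the
    smallest p.
    """
    rows = table[table["layer_tag"] == layer_tag].copy()
    if significance_q is not None and len(rows):
        rows = rows[bh_fdr(rows["p_value"].to_numpy(), q=significance_q).reject]
    mapping = (
        snps_to_genes(snp_meta, genes, flank_bp=flank_bp)
        if snp_meta is not None
        else {}
    )
    best: dict[tuple[str, str], float] = {}
    n_unmapped = 0
    for _, row in rows.iterrows():
        unit = str(row["unit_id"])
        if unit in genes.index:
            targets = [unit]
        elif unit in mapping:
            targets = mapping[unit]
            if not targets:
                n_unmapped += 1
                continue
        else:
            n_unmapped += 1
            continue
        phenotype = str(row["phenotype_id"])
        weight = -np.log10(float(row["p_value"]))
        for gene in targets:
            if gene == phenotype:
                continue  # cis eQTN onto its own transcript: would be a self-edge
            key = (gene, phenotype)
            if weight > best.get(key, -np.inf):
                best[key] = weight
    if n_unmapped:
        logger.info(
            "%s: dropped %d association row(s) mapping to no gene", layer_tag, n_unmapped
        )
    net = Network(layer_tag)
    for (gene, phenotype), weight in best.items():
        net.add_node(gene, kind="gene")
        net.add_edge(gene, phenotype, weight=weight, sign="n/a")
    return net
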