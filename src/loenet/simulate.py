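"""Synthetic multi-omic worlds with planted anchor connectivity.

The generator emulates every input the pipeline consumes at desk scale:
block-correlated expression and methylation matrices, co-segregating
genotype pairs with coordinates that exercise the 10-kb linkage rule,
gene--metabolite association tables for the traditional and rare-variant
GWAS layers, gene coordinates, anchor lists and GO annotations with
controlled term sizes.  A set of *planted candidate genes* is wired to the
anchor set with exact per-layer connection counts, so the expected LOE
breadth, depth and tier of every gene is known by construction
(:class:`GroundTruth`) and pipeline output can be checked for exact
recovery.

Planted-margin determinism
--------------------------
Recovery assertions are meant to be deterministic, not statistical, so the
planted signal is given wide margins and the generator *verifies* its own
output: after drawing each matrix it rebuilds the corresponding layer with
the production layer builders and compares the anchor-incident edge set to
the planted design.  Chance anchor-incident edges from background features
are removed by resampling the offending feature; blocks that fail to clear
the threshold are redrawn.  Background association rows that involve an
anchor metabolite draw p-values from [0.2, 1], which Benjamini-Hochberg
control at 0.1 can never reject, so no spurious anchor GWAS edge can
arise.  All resampling continues a single seeded random stream, keeping
worlds byte-identical for a given seed.

Correlation blocks use a latent-Gaussian one-factor model: members of a
block share a factor with loading chosen so the *Spearman* correlation
concentrates at the configured target (for bivariate Gaussians
rho_S = (6/pi) asin(rho_P / 2), inverted here), followed by a monotone
transform to non-negative TPM-like values that preserves rank structure.
Methylation reuses the same machinery with 10 samples (the dimensionality
asymmetry that motivates the comethylation discount in ranking) and a
higher within-block target.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GWAS_LAYERS, assign_tier
from .io import (
    AnchorSet,
    GenotypeMatrix,
    GoAnnotation,
    OmicsMatrix,
    met_id,
    validate_association_table,
    write_association_table,
    write_gene_table,
    write_genotypes,
    write_go_annotations,
    write_matrix,
)
from .layers import build_correlation_layer, build_snp_correlation_layer
from .phenotype import maf_filter

logger = logging.getLogger("loenet")

GENE_LAYERS = ("coexpression", "comethylation", "snp_correlation")


@dataclass(frozen=True)
class PlantedCandidate:
    """A candidate gene with exact planted anchor-connection counts."""

    name: str
    coexpr: int = 0
    cometh: int = 0
    snp: int = 0
    gwas_traditional: int = 0
    gwas_rare: int = 0

    @property
    def depth_by_layer(self) -> dict:
        return {
            "coexpression": self.coexpr,
            "comethylation": self.cometh,
            "snp_correlation": self.snp,
            "gwas_traditional": self.gwas_traditional,
            "gwas_rare": self.gwas_rare,
        }

    @property
    def breadth(self) -> int:
        return sum(1 for v in self.depth_by_layer.values() if v > 0)

    @property
    def depth_total(self) -> int:
        return sum(self.depth_by_layer.values())

    @property
    def depth_minus_cometh(self) -> int:
        return self.depth_total - self.cometh

    def is_high_loe(self, min_breadth: int = 3, require_gwas: bool = True) -> bool:
        gwas = self.gwas_traditional + self.gwas_rare
        return self.breadth >= min_breadth and (not require_gwas or gwas >= 1)


def default_planted() -> tuple:
    """Fifteen planted candidates spanning all tiers plus three decoys that
    fail the merge threshold (no GWAS edge, or breadth below the cutoff)."""
    P = PlantedCandidate
    return (
        P("CAND01", coexpr=3, cometh=2, snp=1, gwas_traditional=1),          # b4 T1
        P("CAND02", coexpr=2, cometh=2, snp=2, gwas_rare=1),                 # b4 T1
        P("CAND03", coexpr=4, snp=1, gwas_traditional=1),                    # b3 d-c 6 T1
        P("CAND04", coexpr=3, snp=2, gwas_rare=1),                           # b3 d-c 6 T1
        P("CAND05", coexpr=5, gwas_traditional=1, gwas_rare=1),              # b3 d-c 7 T1
        P("CAND06", coexpr=3, cometh=2, gwas_traditional=1),                 # b3 d-c 4 T2
        P("CAND07", coexpr=2, cometh=1, gwas_rare=2),                        # b3 d-c 4 T2
        P("CAND08", cometh=3, snp=3, gwas_traditional=1),                    # b3 d-c 4 T2
        P("CAND09", coexpr=1, cometh=4, gwas_traditional=1),                 # b3 d-c 2 T3
        P("CAND10", coexpr=2, cometh=3, gwas_rare=1),                        # b3 d-c 3 T3
        P("CAND11", cometh=2, snp=1, gwas_traditional=1),                    # b3 d-c 2 T3
        P("CAND12", coexpr=1, cometh=1, gwas_traditional=1),                 # b3 d-c 2 T3
        P("CAND13", coexpr=2, cometh=2, snp=1),                              # no GWAS: excluded
        P("CAND14", coexpr=3, gwas_traditional=1),                           # breadth 2: excluded
        P("CAND15", coexpr=2),                                               # breadth 1: excluded
    )


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic world."""

    n_genes: int = 1000
    n_anchor_genes: int = 20
    n_anchor_metabolites: int = 10
    n_metabolites: int = 30
    n_samples_expr: int = 64
    n_samples_meth: int = 10
    n_samples_geno: int = 200
    n_background_snps: int = 20
    n_background_assoc: int = 200
    planted: tuple = field(default_factory=default_planted)
    target_rho: float = 0.95          # within-block Spearman, expression
    target_rho_meth: float = 0.999    # within-block Spearman, methylation
    ld_flip_prob: float = 0.0         # per-sample genotype copy error
    assoc_p_planted: float = 1e-8
    go_small_term_size: int = 5
    go_big_term_size: int = 400
    coexpr_threshold: float = 0.85
    cometh_threshold: float = 0.95
    ccc_min: float = 0.7
    min_dist_bp: int = 10_000
    min_maf: float = 0.01
    max_missing: float = 0.5
    significance_q: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_rho < 1 or not 0 < self.target_rho_meth < 1:
            raise ValueError("target correlations must lie in (0, 1)")
        if self.n_samples_geno % 2:
            raise ValueError("n_samples_geno must be even (balanced planted genotypes)")
        names = [p.name for p in self.planted]
        if len(set(names)) != len(names):
            raise ValueError("planted candidate names must be unique")
        n_bg = self.n_genes - self.n_anchor_genes - len(self.planted)
        if n_bg < max(self.go_big_term_size, 10):
            raise ValueError("n_genes too small for the configured anchors/candidates/terms")


@dataclass
class GroundTruth:
    """Expected pipeline output implied by the planted design."""

    depth_by_layer: dict          # gene -> {layer: depth}
    breadth: dict                 # gene -> int
    depth_total: dict
    depth_minus_cometh: dict
    high_loe: list
    tiers: dict                   # high-LOE gene -> tier
    go_pairs: list                # (candidate, anchor) pairs shared in GO and LOE
    anchor_genes: list
    anchor_metabolites: list

    def to_json(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class World:
    """One fully generated synthetic study."""

    config: SimulationConfig
    expression: OmicsMatrix
    methylation: OmicsMatrix
    genotypes: GenotypeMatrix
    genes: pd.DataFrame
    associations: pd.DataFrame
    anchors: AnchorSet
    go: GoAnnotation
    truth: GroundTruth
    universe: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# deterministic layout of ids, coordinates and block memberships
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    anchors: list
    members: list  # candidate genes

    @property
    def genes(self) -> list:
        return self.members + self.anchors


class _Layout:
    """Names, coordinates and planted block structure for one world."""

    def __init__(self, cfg: SimulationConfig):
        self.cfg = cfg
        self.anchor_genes = [f"ANC{i:02d}" for i in range(1, cfg.n_anchor_genes + 1)]
        self.candidates = [p.name for p in cfg.planted]
        n_bg = cfg.n_genes - cfg.n_anchor_genes - len(cfg.planted)
        self.background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
        self.genes = self.anchor_genes + self.candidates + self.background
        self.anchor_mets = [f"AM{i:02d}" for i in range(1, cfg.n_anchor_metabolites + 1)]
        n_decoy = cfg.n_metabolites - cfg.n_anchor_metabolites
        self.decoy_mets = [f"DM{i:02d}" for i in range(1, n_decoy + 1)]
        # the last two background genes sit 3 kb apart on their own
        # chromosome so a perfectly co-segregating decoy SNP pair is
        # excluded by the 10-kb rule
        self.decoy_pair_genes = self.background[-2:]
        self.coords = self._gene_coordinates()
        self.expr_blocks = self._blocks("coexpr")
        self.meth_blocks = self._blocks("cometh")
        self.snp_blocks = self._blocks("snp")

    def _gene_coordinates(self) -> pd.DataFrame:
        chroms, starts = [], []
        regular = [g for g in self.genes if g not in self.decoy_pair_genes]
        per_chrom = math.ceil(len(regular) / 5)
        for idx, _gene in enumerate(regular):
            chroms.append(f"Chr{idx // per_chrom + 1:02d}")
            starts.append(1 + (idx % per_chrom) * 50_000)
        rows = {g: (c, s) for g, c, s in zip(regular, chroms, starts)}
        rows[self.decoy_pair_genes[0]] = ("ChrD", 1)
        rows[self.decoy_pair_genes[1]] = ("ChrD", 3001)
        table = pd.DataFrame(
            {
                "chromosome": [rows[g][0] for g in self.genes],
                "start": [rows[g][1] for g in self.genes],
                "strand": "+",
            },
            index=pd.Index(self.genes, name="gene_id"),
        )
        table["end"] = table["start"] + 1999
        return table[["chromosome", "start", "end", "strand"]]

    def _blocks(self, attr: str) -> list:
        """One block per distinct planted edge count; candidates with the
        same count share the block's anchors (their mutual correlation is
        harmless: candidate-candidate edges never touch an anchor)."""
        by_count: dict[int, list] = {}
        for p in self.cfg.planted:
            k = getattr(p, attr)
            if k > 0:
                by_count.setdefault(k, []).append(p.name)
        blocks, cursor = [], 0
        for k in sorted(by_count):
            if cursor + k > len(self.anchor_genes):
                raise ValueError(
                    f"not enough anchor genes for the planted {attr} design"
                )
            blocks.append(_Block(self.anchor_genes[cursor : cursor + k], by_count[k]))
            cursor += k
        return blocks

    def gene_layer_partner(self, cand: PlantedCandidate) -> str | None:
        """First planted anchor partner of a candidate in any gene-gene layer
        (used to seed a shared GO term)."""
        for attr, blocks in (
            ("coexpr", self.expr_blocks),
            ("cometh", self.meth_blocks),
            ("snp", self.snp_blocks),
        ):
            if getattr(cand, attr) > 0:
                for block in blocks:
                    if cand.name in block.members:
                        return block.anchors[0]
        return None


# ---------------------------------------------------------------------------
# correlated matrices with verification
# ---------------------------------------------------------------------------


def _loading(target_spearman: float) -> float:
    """Factor loading giving the requested Spearman rho between block
    members of a Gaussian one-factor model (rho_S = (6/pi) asin(rho_P/2))."""
    pearson = 2.0 * math.sin(math.pi * target_spearman / 6.0)
    return math.sqrt(pearson)


def _orthogonal_factor(rng, n: int, others: list) -> np.ndarray:
    """A random factor orthogonalized against the other blocks' factors.

    Block factors model independent pathways; enforcing orthogonality in
    sample space keeps cross-block gene pairs free of the shared spurious
    correlation that independent factor draws would induce at small n.
    """
    if len(others) >= n:
        raise ValueError("more correlation blocks than samples")
    for _ in range(50):
        f = rng.standard_normal(n)
        for o in others:
            u = o / np.linalg.norm(o)
            f -= (f @ u) * u
        norm = np.linalg.norm(f)
        if norm > 1e-8:
            return f * (math.sqrt(n) / norm)
    raise RuntimeError("could not draw an orthogonal block factor")


def _draw_block(latent: np.ndarray, rows: list, a: float, rng, factor: np.ndarray) -> None:
    n = latent.shape[1]
    b = math.sqrt(1.0 - a * a)
    for r in rows:
        latent[r] = a * factor + b * rng.standard_normal(n)


def _simulate_correlated(
    feature_ids: list,
    blocks: list,
    anchor_genes: set,
    n_samples: int,
    target_rho: float,
    threshold: float,
    layer_name: str,
    rng,
    max_iter: int = 100,
) -> OmicsMatrix:
    index = {g: i for i, g in enumerate(feature_ids)}
    a = _loading(target_rho)
    latent = rng.standard_normal((len(feature_ids), n_samples))
    block_of: dict[str, _Block] = {}
    factors: dict[int, np.ndarray] = {}

    def redraw(block: _Block) -> None:
        others = [f for bid, f in factors.items() if bid != id(block)]
        factors[id(block)] = _orthogonal_factor(rng, n_samples, others)
        _draw_block(latent, [index[g] for g in block.genes], a, rng, factors[id(block)])

    for block in blocks:
        redraw(block)
        for g in block.genes:
            block_of[g] = block
    expected = {
        _pair(m, anc) for b in blocks for m in b.members for anc in b.anchors
    }
    for _ in range(max_iter):
        matrix = OmicsMatrix(
            pd.DataFrame(
                100.0 * np.exp(latent), index=feature_ids, columns=_samples(n_samples)
            )
        )
        net = build_correlation_layer(matrix, threshold, layer_name)
        actual = {
            _pair(x, y)
            for x, y in net.edge_pairs()
            if (x in anchor_genes) != (y in anchor_genes)
        }
        extra, missing = actual - expected, expected - actual
        if not extra and not missing:
            return matrix
        redraw_blocks = set()
        for x, y in extra:
            gene = y if x in anchor_genes else x
            if gene in block_of:
                redraw_blocks.add(id(block_of[gene]))
            else:
                latent[index[gene]] = rng.standard_normal(n_samples)
        for x, y in missing:
            gene = y if x in anchor_genes else x
            redraw_blocks.add(id(block_of[gene]))
        for block in blocks:
            if id(block) in redraw_blocks:
                redraw(block)
    raise RuntimeError(f"{layer_name}: could not realize the planted design")


def _pair(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


def _samples(n: int, prefix: str = "S") -> list:
    return [f"{prefix}{i:03d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# public per-data-type generators
# ---------------------------------------------------------------------------


def _rng_for(cfg: SimulationConfig, stream: str):
    children = {
        "expression": 0,
        "methylation": 1,
        "genotypes": 2,
        "associations": 3,
    }
    seq = np.random.SeedSequence(cfg.seed).spawn(4)[children[stream]]
    return np.random.default_rng(seq)


def simulate_expression(cfg: SimulationConfig) -> OmicsMatrix:
    layout = _Layout(cfg)
    return _simulate_correlated(
        layout.genes,
        layout.expr_blocks,
        set(layout.anchor_genes),
        cfg.n_samples_expr,
        cfg.target_rho,
        cfg.coexpr_threshold,
        "coexpression",
        _rng_for(cfg, "expression"),
    )


def simulate_methylation(cfg: SimulationConfig) -> OmicsMatrix:
    layout = _Layout(cfg)
    return _simulate_correlated(
        layout.genes,
        layout.meth_blocks,
        set(layout.anchor_genes),
        cfg.n_samples_meth,
        cfg.target_rho_meth,
        cfg.cometh_threshold,
        "comethylation",
        _rng_for(cfg, "methylation"),
    )


def _balanced_vector(n: int, rng) -> np.ndarray:
    v = np.repeat([0.0, 2.0], n // 2)
    return v[rng.permutation(n)]


def _flip(v: np.ndarray, p: float, rng) -> np.ndarray:
    out = v.copy()
    if p > 0:
        mask = rng.random(v.size) < p
        out[mask] = 2.0 - out[mask]
    return out


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeMatrix:
    """Genotypes with planted co-segregating SNP pairs (see module notes)."""
    layout = _Layout(cfg)
    rng = _rng_for(cfg, "genotypes")
    genes = layout.coords
    for _ in range(100):
        geno = _draw_genotypes(cfg, layout, rng)
        filtered = maf_filter(geno, min_maf=cfg.min_maf, max_missing=cfg.max_missing)
        net = build_snp_correlation_layer(
            filtered, genes, ccc_min=cfg.ccc_min, min_dist_bp=cfg.min_dist_bp
        )
        anchor_genes = set(layout.anchor_genes)
        actual = {
            _pair(x, y)
            for x, y in net.edge_pairs()
            if (x in anchor_genes) != (y in anchor_genes)
        }
        expected = {
            _pair(m, anc)
            for b in layout.snp_blocks
            for m in b.members
            for anc in b.anchors
        }
        if actual == expected:
            return geno
    raise RuntimeError("could not realize the planted genotype design")


def _draw_genotypes(cfg: SimulationConfig, layout: _Layout, rng) -> GenotypeMatrix:
    n = cfg.n_samples_geno
    ids, chroms, positions, rows = [], [], [], []

    def place(snp_id: str, gene: str, offset: int, dosage: np.ndarray) -> None:
        ids.append(snp_id)
        chroms.append(layout.coords.at[gene, "chromosome"])
        positions.append(int(layout.coords.at[gene, "start"]) + offset)
        rows.append(dosage)

    for block in layout.snp_blocks:
        template = _balanced_vector(n, rng)
        for anchor in block.anchors:
            place(f"SNP_{anchor}", anchor, 100, _flip(template, cfg.ld_flip_prob, rng))
        for member in block.members:
            place(f"SNP_{member}", member, 100, _flip(template, cfg.ld_flip_prob, rng))
    decoy_template = _balanced_vector(n, rng)
    for gene in layout.decoy_pair_genes:
        place(f"SNP_{gene}", gene, 100, decoy_template.copy())
    for p in cfg.planted:
        if p.gwas_traditional > 0:
            place(f"ASNP_{p.name}", p.name, 300, _balanced_vector(n, rng))
    per_chrom = math.ceil(
        (cfg.n_genes - len(layout.decoy_pair_genes)) / 5
    )
    for i in range(cfg.n_background_snps):
        ids.append(f"BSNP{i:03d}")
        chroms.append("Chr01")
        positions.append(25_000 + (i % max(1, per_chrom - 1)) * 50_000)  # intergenic
        maf = rng.uniform(0.2, 0.5)
        rows.append(rng.binomial(2, maf, size=n).astype(float))
    meta = pd.DataFrame(
        {"chromosome": chroms, "position": positions},
        index=pd.Index(ids, name="snp_id"),
    )
    dosages = pd.DataFrame(
        np.vstack(rows), index=meta.index, columns=_samples(n, "P")
    )
    return GenotypeMatrix(dosages, meta)


def simulate_associations(cfg: SimulationConfig) -> pd.DataFrame:
    """Association table with planted anchor-metabolite rows (p ~ 1e-8).

    Background rows draw p ~ U(0,1) against decoy metabolites; background
    rows that do involve an anchor metabolite draw p ~ U(0.2, 1), which BH
    at 0.1 can never reject, so planted edges are the only anchor GWAS
    edges after FDR control.
    """
    layout = _Layout(cfg)
    rng = _rng_for(cfg, "associations")
    rows = []
    for p in cfg.planted:
        for met in layout.anchor_mets[: p.gwas_traditional]:
            rows.append((f"ASNP_{p.name}", met, cfg.assoc_p_planted, "gwas_traditional"))
        for met in layout.anchor_mets[: p.gwas_rare]:
            rows.append((p.name, met, cfg.assoc_p_planted, "gwas_rare"))
    n_bg_genes = len(layout.background)
    for i in range(cfg.n_background_assoc):
        tag = "gwas_traditional" if i % 2 else "gwas_rare"
        if i % 4 == 0:
            unit = f"BSNP{i % max(1, cfg.n_background_snps):03d}"  # maps to no gene
        else:
            unit = layout.background[int(rng.integers(n_bg_genes))]
        if i % 3 == 0 and layout.anchor_mets:
            met, pval = layout.anchor_mets[i % len(layout.anchor_mets)], rng.uniform(0.2, 1.0)
        else:
            met, pval = layout.decoy_mets[i % len(layout.decoy_mets)], rng.uniform(0.0, 1.0)
        rows.append((unit, met, float(pval), tag))
    table = pd.DataFrame(rows, columns=["unit_id", "phenotype_id", "p_value", "layer_tag"])
    return validate_association_table(table)


def simulate_go(cfg: SimulationConfig, layout: _Layout | None = None) -> GoAnnotation:
    """GO annotations: each planted candidate shares one small (heavy) term
    with a planted anchor partner; anchors and many background genes share
    one large (light) generic term."""
    layout = layout or _Layout(cfg)
    gene_terms: dict[str, set] = {}

    def annotate(gene: str, term: str) -> None:
        gene_terms.setdefault(gene, set()).add(term)

    filler_cursor = 0
    fillers = [g for g in layout.background if g not in layout.decoy_pair_genes]
    for i, cand in enumerate(cfg.planted):
        partner = layout.gene_layer_partner(cand)
        if partner is None:
            continue
        term = f"GO:S{i + 1:03d}"
        annotate(cand.name, term)
        annotate(partner, term)
        for _ in range(cfg.go_small_term_size - 2):
            annotate(fillers[filler_cursor % len(fillers)], term)
            filler_cursor += 1
    big = "GO:BIG01"
    for gene in layout.anchor_genes:
        annotate(gene, big)
    n_big_bg = cfg.go_big_term_size - len(layout.anchor_genes)
    for gene in reversed(fillers[-n_big_bg:] if n_big_bg > 0 else []):
        annotate(gene, big)
    return GoAnnotation(gene_terms)


# ---------------------------------------------------------------------------
# ground truth and the full world
# ---------------------------------------------------------------------------


def _ground_truth(cfg: SimulationConfig, layout: _Layout) -> GroundTruth:
    depth_by_layer, breadth, depth_total, dmc = {}, {}, {}, {}
    for p in cfg.planted:
        depth_by_layer[p.name] = dict(p.depth_by_layer)
        breadth[p.name] = p.breadth
        depth_total[p.name] = p.depth_total
        dmc[p.name] = p.depth_minus_cometh
    high = sorted(p.name for p in cfg.planted if p.is_high_loe())
    tiers = {
        p.name: assign_tier(p.breadth, p.depth_minus_cometh)
        for p in cfg.planted
        if p.name in high
    }
    go_pairs = []
    for p in cfg.planted:
        if p.name not in high:
            continue
        partner = layout.gene_layer_partner(p)
        if partner is not None:
            go_pairs.append(_pair(p.name, partner))
    return GroundTruth(
        depth_by_layer=depth_by_layer,
        breadth=breadth,
        depth_total=depth_total,
        depth_minus_cometh=dmc,
        high_loe=high,
        tiers=tiers,
        go_pairs=sorted(go_pairs),
        anchor_genes=list(layout.anchor_genes),
        anchor_metabolites=[met_id(m) for m in layout.anchor_mets],
    )


def generate_world(cfg: SimulationConfig) -> World:
    """Generate every pipeline input plus the implied ground truth."""
    layout = _Layout(cfg)
    world = World(
        config=cfg,
        expression=simulate_expression(cfg),
        methylation=simulate_methylation(cfg),
        genotypes=simulate_genotypes(cfg),
        genes=layout.coords,
        associations=simulate_associations(cfg),
        anchors=AnchorSet(
            anchor_genes=frozenset(layout.anchor_genes),
            anchor_metabolites=frozenset(layout.anchor_mets),
        ),
        go=simulate_go(cfg, layout),
        truth=_ground_truth(cfg, layout),
        universe=list(layout.genes),
    )
    return world


def emit_world(cfg: SimulationConfig, out_dir) -> World:
    """Write a generated world in every format the readers consume.

    Emits expression.tsv, methylation.tsv, genotypes.tsv, genes.tsv,
    associations.tsv, anchor_genes.txt, anchor_metabolites.txt,
    go_annotations.tsv and manifest.json (the ground-truth manifest).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = generate_world(cfg)
    write_matrix(world.expression, out / "expression.tsv")
    write_matrix(world.methylation, out / "methylation.tsv")
    write_genotypes(world.genotypes, out / "genotypes.tsv")
    write_gene_table(world.genes, out / "genes.tsv")
    write_association_table(world.associations, out / "associations.tsv")
    (out / "anchor_genes.txt").write_text(
        "".join(f"{g}\n" for g in sorted(world.anchors.anchor_genes))
    )
    (out / "anchor_metabolites.txt").write_text(
        "".join(f"{m}\n" for m in sorted(world.anchors.anchor_metabolites))
    )
    write_go_annotations(world.go, out / "go_annotations.tsv")
    manifest = {
        "config": dataclasses.asdict(cfg),
        "truth": world.truth.to_json(),
        "universe": world.universe,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return world
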