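import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from loenet import (
    AnchorSet,
    Network,
    OmicsMatrix,
    SimulationConfig,
    build_layers,
    extract_one_hop,
    generate_world,
)

settings.register_profile(
    "loenet",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("loenet")


@pytest.fixture(scope="session")
def tiny_world():
    """A small synthetic study reused across end-to-end tests."""
    cfg = SimulationConfig(seed=11, n_genes=250, go_big_term_size=120)
    return generate_world(cfg)


@pytest.fixture(scope="session")
def tiny_layers(tiny_world):
    w = tiny_world
    cfg = w.config
    return build_layers(
        w.expression,
        w.methylation,
        w.genotypes,
        w.genes,
        w.associations,
        coexpr_threshold=cfg.coexpr_threshold,
        cometh_threshold=cfg.cometh_threshold,
        ccc_min=cfg.ccc_min,
        min_dist_bp=cfg.min_dist_bp,
        min_maf=cfg.min_maf,
        max_missing=cfg.max_missing,
        fdr_q=cfg.significance_q,
    )


@pytest.fixture(scope="session")
def tiny_one_hops(tiny_world, tiny_layers):
    return [extract_one_hop(net, tiny_world.anchors) for net in tiny_layers.values()]


def random_matrix(rng, n_features=8, n_samples=10, prefix="G") -> OmicsMatrix:
    data = rng.gamma(2.0, 50.0, size=(n_features, n_samples))
    return OmicsMatrix(
        pd.DataFrame(
            data,
            index=[f"{prefix}{i:03d}" for i in range(n_features)],
            columns=[f"S{j:03d}" for j in range(n_samples)],
        )
    )


def random_multilayer(rng, n_genes=60, n_anchor_genes=6, n_anchor_mets=3, n_layers=6,
                      edge_prob=0.05):
    """A random multilayer instance: (networks, anchors, universe).

    Layer names cover coexpression/comethylation/both GWAS layers so the
    breadth, GWAS-requirement and comethylation-discount paths are all
    exercised.
    """
    layer_names = [
        "coexpression",
        "comethylation",
        "snp_correlation",
        "gwas_traditional",
        "gwas_rare",
        "eqtn",
    ][:n_layers]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    anchor_genes = genes[:n_anchor_genes]
    mets = [f"met:M{i:02d}" for i in range(n_anchor_mets)]
    anchors = AnchorSet(frozenset(anchor_genes), frozenset(mets))
    nets = []
    for name in layer_names:
        net = Network(name)
        gwas = name in ("gwas_traditional", "gwas_rare")
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if not gwas and rng.random() < edge_prob:
                    r = float(rng.uniform(-1, 1))
                    net.add_edge(genes[i], genes[j], weight=r,
                                 sign="+" if r >= 0 else "-")
        if gwas:
            for g in genes:
                for met in mets:
                    if rng.random() < edge_prob * 2:
                        net.add_edge(g, met, weight=float(rng.uniform(1, 9)), sign="n/a")
        nets.append(net)
    return nets, anchors, genes
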