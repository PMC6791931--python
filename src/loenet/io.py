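"""Containers and file formats for the LOE pipeline.

Every external representation the pipeline touches is read and written here:
feature x sample omics matrices (expression / methylation TPM), genotype
dosage matrices with SNP coordinates (TSV or a minimal GT-only VCF dialect),
gene coordinate tables (GFF-lite TSV or BED), association tables, anchor
lists, GO annotations, and layer networks (Cytoscape-loadable TSV / SIF).

Conventions
-----------
* Gene coordinates are 1-based inclusive (GFF convention).  BED input is
  converted on read (0-based half-open -> 1-based inclusive) and the
  conversion is logged.
* Metabolite node ids are namespaced with ``met:`` on ingest so a metabolite
  can never collide with a gene id.
* Missing genotypes stay missing (NaN); downstream correlation computations
  exclude them pairwise rather than imputing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("loenet")

MET_PREFIX = "met:"

#: closed vocabulary of association-table layer tags
ASSOCIATION_TAGS = frozenset({"gwas_traditional", "gwas_rare", "eqtn"})

#: layer names understood by the scoring stage
LAYER_NAMES = (
    "coexpression",
    "comethylation",
    "snp_correlation",
    "gwas_traditional",
    "gwas_rare",
    "eqtn",
)

_MISSING_GT_TOKENS = {".", "./.", ".|.", "NA", "nan", ""}


def met_id(metabolite: str) -> str:
    """Namespace a metabolite identifier (idempotent)."""
    return metabolite if metabolite.startswith(MET_PREFIX) else MET_PREFIX + metabolite


def is_metabolite(node: str) -> bool:
    return node.startswith(MET_PREFIX)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


class OmicsMatrix:
    """Feature x sample numeric matrix (expression or methylation TPM).

    Wraps a :class:`pandas.DataFrame` whose index holds feature (gene) ids and
    whose columns hold sample ids.  Values must be finite and non-negative.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at feature {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at feature {data.index[i]!r}, sample {data.columns[j]!r}"
            )
        self.data = data.astype(float)
        self.data.index = self.data.index.rename("feature_id")
        self.data.columns = self.data.columns.rename(None)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, OmicsMatrix) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"OmicsMatrix({self.shape[0]} features x {self.shape[1]} samples)"


class GenotypeMatrix:
    """SNP x sample dosage matrix over {0, 1, 2, missing} plus SNP metadata.

    ``snp_meta`` is indexed by SNP id with columns ``chromosome``, ``position``
    (1-based int) and optionally ``maf``.  Missing dosages are NaN.
    """

    def __init__(self, dosages: pd.DataFrame, snp_meta: pd.DataFrame):
        if dosages.index.has_duplicates:
            dup = dosages.index[dosages.index.duplicated()][0]
            raise ValueError(f"duplicate SNP id: {dup!r}")
        if dosages.columns.has_duplicates:
            dup = dosages.columns[dosages.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if not dosages.index.equals(snp_meta.index):
            raise ValueError("dosages and snp_meta must share an identical SNP index")
        values = dosages.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid dosage {values[i, j]!r} at SNP {dosages.index[i]!r}, "
                f"sample {dosages.columns[j]!r}"
            )
        if (snp_meta["position"] < 1).any():
            bad = snp_meta.index[snp_meta["position"] < 1][0]
            raise ValueError(f"position < 1 for SNP {bad!r}")
        self.dosages = dosages.astype(float)
        self.snp_meta = snp_meta

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def maf(self) -> pd.Series:
        """Minor-allele frequency per SNP, computed from dosages.

        Uses metadata MAF where present, otherwise the allele frequency of
        the non-missing dosages folded onto [0, 0.5].
        """
        values = self.dosages.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(values, axis=1) / 2.0
        computed = np.minimum(freq, 1.0 - freq)
        computed = np.where(np.isnan(computed), 0.0, computed)
        if "maf" in self.snp_meta.columns:
            meta = self.snp_meta["maf"].to_numpy(dtype=float)
            computed = np.where(np.isnan(meta), computed, meta)
        return pd.Series(computed, index=self.dosages.index, name="maf")

    def missingness(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1).rename("missingness")

    def subset(self, snp_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(snp_ids)
        return GenotypeMatrix(self.dosages.loc[ids], self.snp_meta.loc[ids])

    def __repr__(self) -> str:
        return f"GenotypeMatrix({len(self.snp_ids)} SNPs x {len(self.sample_ids)} samples)"


# ---------------------------------------------------------------------------
# anchors and GO annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchorSet:
    """The curated seed set: anchor genes plus (namespaced) anchor metabolites."""

    anchor_genes: frozenset
    anchor_metabolites: frozenset

    def __post_init__(self):
        mets = frozenset(met_id(m) for m in self.anchor_metabolites)
        object.__setattr__(self, "anchor_metabolites", mets)
        object.__setattr__(self, "anchor_genes", frozenset(self.anchor_genes))
        if self.anchor_genes & self.anchor_metabolites:
            raise ValueError("anchor gene and metabolite sets must be disjoint")
        if not (self.anchor_genes | self.anchor_metabolites):
            raise ValueError("anchor set is empty")

    @property
    def all_nodes(self) -> frozenset:
        return self.anchor_genes | self.anchor_metabolites


@dataclass
class GoAnnotation:
    """Flat gene -> GO-term annotation (no DAG propagation)."""

    gene_terms: dict

    def __post_init__(self):
        self.gene_terms = {g: frozenset(t) for g, t in self.gene_terms.items() if t}

    @property
    def term_genes(self) -> dict:
        out: dict[str, set] = {}
        for gene, terms in self.gene_terms.items():
            for term in terms:
                out.setdefault(term, set()).add(gene)
        return out

    @property
    def term_sizes(self) -> dict:
        return {t: len(g) for t, g in self.term_genes.items()}


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) node ordering for an undirected edge."""
    return (a, b) if a <= b else (b, a)


class Network:
    """Undirected, typed, weighted, signed network over gene/metabolite nodes.

    One :class:`Network` represents either a single omics layer
    (``layer_name`` set, one provenance entry per edge) or a merged LOE
    network (edges carry per-layer provenance).  Backed by a
    :class:`networkx.Graph`; each edge stores ``by_layer``, a mapping
    ``layer -> (weight, sign)``.  Self-edges are rejected and node kinds
    (gene vs metabolite) must be consistent.
    """

    def __init__(self, layer_name: str | None = None):
        self.layer_name = layer_name
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, node: str, kind: str | None = None) -> None:
        if kind is None:
            kind = "metabolite" if is_metabolite(node) else "gene"
        existing = self.graph.nodes.get(node, {}).get("kind")
        if existing is not None and existing != kind:
            raise ValueError(f"node {node!r} typed both {existing} and {kind}")
        self.graph.add_node(node, kind=kind)

    def add_edge(
        self,
        a: str,
        b: str,
        weight: float,
        sign: str = "n/a",
        layer: str | None = None,
    ) -> None:
        if a == b:
            raise ValueError(f"self-edge on node {a!r}")
        if sign not in ("+", "-", "n/a"):
            raise ValueError(f"invalid sign {sign!r}")
        layer = layer if layer is not None else self.layer_name
        if layer is None:
            raise ValueError("edge needs a layer label")
        self.add_node(a)
        self.add_node(b)
        data = self.graph.get_edge_data(a, b)
        if data is None:
            self.graph.add_edge(a, b, by_layer={layer: (float(weight), sign)})
        else:
            data["by_layer"][layer] = (float(weight), sign)

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def node_kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_pairs(self) -> set:
        """Canonical unordered node pairs with at least one edge."""
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def gene_edge_pairs(self) -> set:
        """Canonical pairs where both endpoints are genes."""
        return {
            canonical_pair(a, b)
            for a, b in self.graph.edges
            if self.node_kind(a) == "gene" and self.node_kind(b) == "gene"
        }

    def iter_records(self) -> Iterator[tuple[str, str, str, float, str]]:
        """Yield (node_a, node_b, layer, weight, sign) in canonical sorted order."""
        records = []
        for a, b, data in self.graph.edges(data=True):
            a, b = canonical_pair(a, b)
            for layer, (weight, sign) in data["by_layer"].items():
                records.append((a, b, layer, weight, sign))
        records.sort(key=lambda r: (r[0], r[1], r[2]))
        yield from records

    def edge_layers(self, a: str, b: str) -> dict:
        return dict(self.graph.get_edge_data(a, b)["by_layer"])

    def copy(self) -> "Network":
        out = Network(self.layer_name)
        out.graph = self.graph.copy()
        for a, b in out.graph.edges:
            out.graph.edges[a, b]["by_layer"] = dict(self.graph.edges[a, b]["by_layer"])
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            list(self.iter_records()) == list(other.iter_records())
            and dict(self.graph.nodes(data="kind")) == dict(other.graph.nodes(data="kind"))
        )

    def __repr__(self) -> str:
        name = self.layer_name or "merged"
        return f"Network({name}: {len(self.nodes)} nodes, {self.n_edges} edges)"


NETWORK_HEADER = ("node_a", "node_b", "layer_name", "weight", "sign")


def write_network(net: Network, path, dialect: str = "tsv") -> None:
    """Write a network as edge-list TSV or Cytoscape SIF.

    The TSV dialect writes one row per (edge, source layer) in canonical node
    order, so output is independent of edge insertion order and round-trips
    losslessly (byte-identically) through :func:`read_network`.
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(NETWORK_HEADER) + "\n")
            for a, b, layer, weight, sign in net.iter_records():
                fh.write(f"{a}\t{b}\t{layer}\t{weight!r}\t{sign}\n")
        else:
            for a, b, layer, _weight, _sign in net.iter_records():
                fh.write(f"{a}\t{layer}\t{b}\n")


def read_network(path) -> Network:
    """Read a network from the TSV dialect written by :func:`write_network`."""
    net = Network()
    layers_seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != NETWORK_HEADER:
            raise ValueError(f"unexpected network header {header!r} in {path}")
        for line in fh:
            a, b, layer, weight, sign = line.rstrip("\n").split("\t")
            net.add_edge(a, b, float(weight), sign, layer=layer)
            layers_seen.add(layer)
    if len(layers_seen) == 1:
        net.layer_name = next(iter(layers_seen))
    return net


# ---------------------------------------------------------------------------
# matrix readers / writers
# ---------------------------------------------------------------------------


def _check_header_duplicates(path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    seen = set()
    for s in samples:
        if s in seen:
            raise ValueError(f"duplicate sample id: {s!r}")
        seen.add(s)
    return samples


def read_matrix(path, kind: str):
    """Read an omics or genotype matrix.

    ``kind`` is ``expression``, ``methylation`` or ``genotype``.  The first
    two expect a TSV with a header row of sample ids and the feature id in
    the first column.  Genotype input is either a TSV whose first three
    columns are ``snp_id``, ``chromosome``, ``position`` followed by per
    sample dosages (missing tokens ``.``, ``./.``, ``NA`` map to missing),
    or a minimal VCF (GT field only) when the filename ends in ``.vcf``.
    """
    if kind in ("expression", "methylation"):
        samples = _check_header_duplicates(path)
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        raw.columns = samples
        if raw.index.has_duplicates:
            dup = raw.index[raw.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        try:
            data = raw.astype(float)
        except ValueError:
            for gene, row in raw.iterrows():
                for sample, cell in row.items():
                    try:
                        float(cell)
                    except (TypeError, ValueError):
                        raise ValueError(
                            f"non-numeric value {cell!r} at feature {gene!r}, "
                            f"sample {sample!r}"
                        ) from None
            raise
        return OmicsMatrix(data)
    if kind == "genotype":
        if str(path).endswith((".vcf", ".vcf.gz")):
            return _read_vcf(path)
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown matrix kind {kind!r}")


def _read_genotype_tsv(path) -> GenotypeMatrix:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["snp_id", "chromosome", "position"]
    if list(raw.columns[:3]) != expected:
        raise ValueError(f"genotype TSV must start with columns {expected}")
    if raw["snp_id"].duplicated().any():
        dup = raw["snp_id"][raw["snp_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate SNP id: {dup!r}")
    meta = pd.DataFrame(
        {"chromosome": raw["chromosome"].values,
         "position": raw["position"].astype(int).values},
        index=pd.Index(raw["snp_id"], name="snp_id"),
    )
    body = raw.iloc[:, 3:].copy()
    body.index = meta.index
    body = body.map(lambda x: np.nan if str(x).strip() in _MISSING_GT_TOKENS else x)
    dosages = body.astype(float)
    return GenotypeMatrix(dosages, meta)


def _read_vcf(path) -> GenotypeMatrix:
    """Minimal VCF dialect: biallelic sites, GT only, via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    snp_ids, chroms, positions, rows = [], [], [], []
    for variant in vcf:
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snp_ids.append(snp_id)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
        gt = variant.gt_types.astype(float)  # 0/1/2 = dosage, 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    index = pd.Index(snp_ids, name="snp_id")
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate SNP id: {dup!r}")
    dosages = pd.DataFrame(rows, index=index, columns=samples)
    meta = pd.DataFrame({"chromosome": chroms, "position": positions}, index=index)
    return GenotypeMatrix(dosages, meta)


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    out = geno.snp_meta[["chromosome", "position"]].copy()
    body = geno.dosages.copy()

    def _fmt(x):
        return "." if (isinstance(x, float) and math.isnan(x)) else str(int(x))

    body = body.map(_fmt)
    pd.concat([out, body], axis=1).to_csv(path, sep="\t", index_label="snp_id")


# ---------------------------------------------------------------------------
# gene tables, association tables, anchors, GO
# ---------------------------------------------------------------------------


def read_gene_table(path, fmt: str | None = None) -> pd.DataFrame:
    """Read gene coordinates as a DataFrame indexed by gene id.

    ``fmt`` is ``"tsv"`` (GFF-lite: gene_id, chromosome, start, end[, strand];
    1-based inclusive) or ``"bed"`` (0-based half-open, converted on read).
    Inferred from the file extension when omitted.
    """
    if fmt is None:
        fmt = "bed" if str(path).endswith(".bed") else "tsv"
    if fmt == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
        if raw.shape[1] < 4:
            raise ValueError("BED gene table needs at least chrom,start,end,name")
        table = pd.DataFrame(
            {
                "chromosome": raw[0].astype(str).values,
                "start": raw[1].astype(int).values + 1,  # 0-based half-open -> 1-based
                "end": raw[2].astype(int).values,
                "strand": raw[5].astype(str).values if raw.shape[1] >= 6 else "unknown",
            },
            index=pd.Index(raw[3].astype(str), name="gene_id"),
        )
        logger.info("converted BED coordinates (0-based half-open) to 1-based inclusive")
    elif fmt == "tsv":
        raw = pd.read_csv(path, sep="\t", dtype=str)
        if "gene_id" not in raw.columns:
            raise ValueError("GFF-lite gene table needs a gene_id column")
        table = pd.DataFrame(
            {
                "chromosome": raw["chromosome"].values,
                "start": raw["start"].astype(int).values,
                "end": raw["end"].astype(int).values,
                "strand": raw["strand"].values if "strand" in raw.columns else "unknown",
            },
            index=pd.Index(raw["gene_id"], name="gene_id"),
        )
    else:
        raise ValueError(f"unknown gene-table format {fmt!r}")
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    if (table["start"] > table["end"]).any():
        bad = table.index[table["start"] > table["end"]][0]
        raise ValueError(f"start > end for gene {bad!r}")
    return table


def write_gene_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


def validate_association_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"unit_id", "phenotype_id", "p_value", "layer_tag"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"association table missing columns {sorted(missing)}")
    table = table.copy()
    table["p_value"] = table["p_value"].astype(float)
    if ((table["p_value"] <= 0) | (table["p_value"] > 1)).any():
        raise ValueError("association p-values must lie in (0, 1]")
    bad_tags = set(table["layer_tag"]) - ASSOCIATION_TAGS
    if bad_tags:
        raise ValueError(f"unknown layer_tag values {sorted(bad_tags)}")
    if "q_value" not in table.columns:
        table["q_value"] = np.nan
    # metabolite phenotypes are namespaced; eQTN phenotypes are transcripts
    gwas = table["layer_tag"].isin(("gwas_traditional", "gwas_rare"))
    table.loc[gwas, "phenotype_id"] = table.loc[gwas, "phenotype_id"].map(met_id)
    return table


def read_association_table(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"unit_id": str, "phenotype_id": str})
    return validate_association_table(raw)


def write_association_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def read_anchor_sets(gene_path, metabolite_path) -> AnchorSet:
    return AnchorSet(
        anchor_genes=frozenset(read_id_list(gene_path)),
        anchor_metabolites=frozenset(read_id_list(metabolite_path)),
    )


def read_go_annotations(path) -> GoAnnotation:
    """Two-column TSV: gene <TAB> GO term, one annotation per line."""
    gene_terms: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene_terms.setdefault(gene, set()).add(term)
    return GoAnnotation(gene_terms)


def write_go_annotations(ann: GoAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.gene_terms):
            for term in sorted(ann.gene_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# TPM normalization
# ---------------------------------------------------------------------------


def tpm_from_counts(counts: OmicsMatrix, lengths: Mapping[str, float]) -> OmicsMatrix:
    """Convert read counts to TPM (transcripts per million).

    Per sample: TPM_i = 1e6 * (c_i / l_i) / sum_j (c_j / l_j), where l_i is
    the feature length in bp.  Columns of the result sum to 1e6 unless a
    sample has zero counts everywhere, in which case the column is zero and
    a warning is logged.
    """
    missing = [f for f in counts.feature_ids if f not in lengths]
    if missing:
        raise ValueError(f"no length for feature {missing[0]!r}")
    length = np.array([float(lengths[f]) for f in counts.feature_ids])
    if (length <= 0).any():
        bad = counts.feature_ids[int(np.argmax(length <= 0))]
        raise ValueError(f"non-positive length for feature {bad!r}")
    rates = counts.data.to_numpy(dtype=float) / length[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        names = [s for s, z in zip(counts.sample_ids, zero) if z]
        logger.warning("all-zero count column(s) %s: TPM left at zero", names)
    safe = np.where(zero, 1.0, totals)
    tpm = 1e6 * rates / safe[None, :]
    return OmicsMatrix(pd.DataFrame(tpm, index=counts.data.index, columns=counts.data.columns))
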