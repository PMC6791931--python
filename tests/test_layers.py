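"""Correlation layers, the CCC co-segregation measure, SNP/association mapping.

The CCC brute-force oracle below is an independent transcription of the
two-way allele-pair definition (duo frequency times rarity weights, maximum
over the four allele pairs); the implementation must match it to 1e-12.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from loenet import (
    OmicsMatrix,
    build_association_layer,
    build_correlation_layer,
    build_snp_correlation_layer,
    ccc,
    snps_to_genes,
)
from loenet.io import GenotypeMatrix, validate_association_table

from conftest import random_matrix


def ccc_oracle(u, v) -> float:
    """Brute-force reference transcription: explicit loop over samples and
    the four allele pairs, no vectorization shared with the implementation."""
    pairs = [
        (float(a), float(b))
        for a, b in zip(u, v)
        if not (np.isnan(a) or np.isnan(b))
    ]
    n = len(pairs)
    best = 0.0
    for i in (0, 1):
        for j in (0, 1):
            duo = 0.0
            fi = 0.0
            fj = 0.0
            for a, b in pairs:
                ca = a if i == 1 else 2 - a
                cb = b if j == 1 else 2 - b
                duo += ca * cb
                fi += ca
                fj += cb
            duo /= 4 * n
            fi /= 2 * n
            fj /= 2 * n
            best = max(best, 4.5 * duo * (1 - 2 * fi / 3) * (1 - 2 * fj / 3))
    return best


def _geno(rows, chroms=None, positions=None):
    dosages = pd.DataFrame(rows).T.astype(float)
    dosages.columns = [f"P{i}" for i in range(dosages.shape[1])]
    n = len(rows)
    meta = pd.DataFrame(
        {
            "chromosome": chroms if chroms is not None else ["c"] * n,
            "position": positions if positions is not None else range(100, 100 + n),
        },
        index=dosages.index,
    )
    return GenotypeMatrix(dosages, meta)


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end"], index=pd.Index(list(rows.keys()))
    ) if isinstance(rows, dict) else rows


class TestCorrelationLayer:
    def test_identical_profiles_give_rho_one(self):
        m = OmicsMatrix(pd.DataFrame([[1, 5, 2, 9]] * 2, index=["a", "b"]).astype(float))
        net = build_correlation_layer(m, 1.0, "coexpression")
        assert net.edge_layers("a", "b")["coexpression"] == (1.0, "+")

    def test_anti_monotone_gives_negative_edge(self):
        m = OmicsMatrix(
            pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]], index=["x", "y"]).astype(float)
        )
        net = build_correlation_layer(m, 0.9, "coexpression")
        assert net.edge_layers("x", "y")["coexpression"] == (-1.0, "-")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for n_genes, n_samples in [(5, 10), (20, 8), (50, 20)]:
            m = random_matrix(rng, n_genes, n_samples)
            threshold = 0.5
            net = build_correlation_layer(m, threshold, "coexpression")
            ids = m.feature_ids
            data = m.data.to_numpy()
            expected = set()
            for i, j in itertools.combinations(range(n_genes), 2):
                rho = spearmanr(data[i], data[j]).statistic
                if abs(rho) >= threshold:
                    expected.add(tuple(sorted((ids[i], ids[j]))))
                    got = net.edge_layers(ids[i], ids[j])["coexpression"]
                    assert got[0] == pytest.approx(rho, abs=1e-12)
            assert net.edge_pairs() == expected

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 30, 10)
        counts = [
            build_correlation_layer(m, t, "coexpression").n_edges
            for t in (0.2, 0.4, 0.6, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_variance_feature_excluded(self, caplog):
        m = OmicsMatrix(
            pd.DataFrame(
                [[1, 2, 3, 4], [5, 5, 5, 5], [2, 4, 6, 8]],
                index=["a", "flat", "c"],
            ).astype(float)
        )
        with caplog.at_level("INFO", logger="loenet"):
            net = build_correlation_layer(m, 0.5, "coexpression")
        assert "flat" not in net.nodes
        assert net.has_edge("a", "c")

    def test_too_few_samples_rejected(self):
        m = OmicsMatrix(pd.DataFrame([[1, 2]] * 2, index=["a", "b"]).astype(float))
        with pytest.raises(ValueError):
            build_correlation_layer(m, 0.85, "coexpression")


class TestCCC:
    def test_perfect_cosegregation_is_one(self):
        v = np.array([0, 2, 0, 2, 0, 2], dtype=float)
        assert ccc(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            u = rng.integers(0, 3, size=8).astype(float)
            v = rng.integers(0, 3, size=8).astype(float)
            if u.std() == 0 and v.std() == 0:
                continue
            assert ccc(u, v) == pytest.approx(ccc(v, u), abs=1e-12)

    def test_matches_brute_force_oracle_on_toys(self):
        toys = [
            ([0, 0, 1, 1, 2, 2], [0, 0, 1, 1, 2, 2]),
            ([0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]),
            ([0, 2, 0, 2, 1, 1], [0, 2, 2, 0, 1, 1]),
            ([1, 1, 1, 1, 1, 1], [0, 2, 0, 2, 0, 2]),
            ([0, 0, 0, 0, 0, 2], [2, 0, 0, 0, 0, 0]),
        ]
        for u, v in toys:
            u, v = np.asarray(u, float), np.asarray(v, float)
            assert ccc(u, v) == pytest.approx(ccc_oracle(u, v), abs=1e-12)

    def test_matches_oracle_on_random_and_missing(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            n = int(rng.integers(4, 12))
            u = rng.integers(0, 3, size=n).astype(float)
            v = rng.integers(0, 3, size=n).astype(float)
            if rng.random() < 0.5:
                u[rng.integers(n)] = np.nan
                v[rng.integers(n)] = np.nan
            try:
                got = ccc(u, v)
            except ValueError:
                continue
            assert got == pytest.approx(min(ccc_oracle(u, v), 1.0), abs=1e-12)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            u = rng.integers(0, 3, size=10).astype(float)
            v = rng.integers(0, 3, size=10).astype(float)
            assert 0.0 <= ccc(u, v) <= 1.0

    def test_too_few_informative_samples(self):
        with pytest.raises(ValueError):
            ccc([0, np.nan], [np.nan, 2])


class TestSnpCorrelationLayer:
    def test_nearby_perfect_pair_excluded_by_distance_rule(self):
        v = [0, 2, 0, 2, 0, 2]
        g = _geno({"s1": v, "s2": v}, chroms=["c", "c"], positions=[1000, 6000])
        genes = pd.DataFrame(
            {"chromosome": ["c", "c"], "start": [900, 5900], "end": [1100, 6100]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        net = build_snp_correlation_layer(g, genes, ccc_min=0.7, min_dist_bp=10_000)
        assert net.n_edges == 0

    def test_cross_chromosome_pair_always_passes(self):
        v = [0, 2, 0, 2, 0, 2]
        g = _geno({"s1": v, "s2": v}, chroms=["c1", "c2"], positions=[1000, 1000])
        genes = pd.DataFrame(
            {"chromosome": ["c1", "c2"], "start": [900, 900], "end": [1100, 1100]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        net = build_snp_correlation_layer(g, genes, ccc_min=0.7, min_dist_bp=10_000)
        assert net.edge_layers("gA", "gB")["snp_correlation"] == (1.0, "n/a")

    def test_gene_pair_collapse_keeps_maximum(self):
        # three qualifying SNP pairs hit the same gene pair; a pluggable
        # measure assigns them CCC 0.72, 0.8, 0.9 -> single edge, weight 0.9
        genes = pd.DataFrame(
            {"chromosome": ["c1", "c2"], "start": [900, 900], "end": [1100, 1100]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )
        planted = {("a0", "b0"): 0.72, ("a1", "b1"): 0.8, ("a2", "b2"): 0.9}
        # distinct dosage patterns let the measure identify each SNP
        patterns = {  # six distinct vectors so the measure can identify SNPs;
            # insertion order matches the chromosome assignment below
            "a0": [0, 2, 0, 2, 0, 2], "a1": [2, 0, 2, 0, 2, 0],
            "a2": [0, 0, 2, 2, 0, 2], "b0": [2, 0, 0, 2, 0, 2],
            "b1": [0, 2, 2, 0, 2, 0], "b2": [2, 2, 0, 0, 2, 0],
        }
        g = _geno(
            patterns,
            chroms=["c1"] * 3 + ["c2"] * 3,
            positions=[1000, 1010, 1020, 1000, 1010, 1020],
        )
        key = {tuple(v): s for s, v in patterns.items()}

        def measure(u, v):
            a, b = key[tuple(int(x) for x in u)], key[tuple(int(x) for x in v)]
            return planted.get((a, b), planted.get((b, a), 0.1))

        net = build_snp_correlation_layer(
            g, genes, ccc_min=0.7, min_dist_bp=10_000, measure=measure
        )
        assert net.n_edges == 1
        assert net.edge_layers("gA", "gB")["snp_correlation"][0] == pytest.approx(0.9)

    def test_invariant_to_row_and_sample_order(self):
        rng = np.random.default_rng(12)
        rows = {f"s{i}": rng.integers(0, 3, size=12).astype(float) for i in range(6)}
        chroms = [f"c{i % 3}" for i in range(6)]
        positions = [1000 + 40_000 * i for i in range(6)]
        genes = pd.DataFrame(
            {
                "chromosome": chroms,
                "start": [p - 50 for p in positions],
                "end": [p + 50 for p in positions],
            },
            index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
        )
        g1 = _geno(rows, chroms=chroms, positions=positions)
        order = list(reversed(list(rows)))
        g2 = GenotypeMatrix(
            g1.dosages.loc[order, ::-1], g1.snp_meta.loc[order]
        )
        n1 = build_snp_correlation_layer(g1, genes, ccc_min=0.3)
        n2 = build_snp_correlation_layer(g2, genes, ccc_min=0.3)
        assert n1 == n2

    def test_snps_in_same_gene_discarded(self):
        v = [0, 2, 0, 2, 0, 2]
        g = _geno({"s1": v, "s2": v}, chroms=["c", "c"], positions=[1000, 90_000])
        genes = pd.DataFrame(
            {"chromosome": ["c"], "start": [1], "end": [100_000]},
            index=pd.Index(["big"], name="gene_id"),
        )
        net = build_snp_correlation_layer(g, genes)
        assert net.n_edges == 0


class TestAssociationLayer:
    def _table(self, rows):
        return validate_association_table(
            pd.DataFrame(rows, columns=["unit_id", "phenotype_id", "p_value", "layer_tag"])
        )

    def _genes(self):
        return pd.DataFrame(
            {"chromosome": ["c", "c"], "start": [2000, 50_000], "end": [3000, 52_000]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )

    def test_gene_level_passthrough(self):
        t = self._table([("gA", "M1", 1e-6, "gwas_rare")])
        net = build_association_layer(t, self._genes(), "gwas_rare")
        assert net.edge_layers("gA", "met:M1")["gwas_rare"][0] == pytest.approx(6.0)
        assert net.node_kind("met:M1") == "metabolite"

    def test_snp_flank_interval_arithmetic(self):
        # SNP at 1,500 with gene body [2,000-3,000] and 2-kb flank: the
        # flanked interval [1-5,000] contains it
        snp_meta = pd.DataFrame(
            {"chromosome": ["c"], "position": [1500]}, index=pd.Index(["snp1"])
        )
        t = self._table([("snp1", "M1", 1e-4, "gwas_rare")])
        net = build_association_layer(
            t, self._genes(), "gwas_rare", snp_meta=snp_meta, flank_bp=2000
        )
        assert net.has_edge("gA", "met:M1")
        strict = build_association_layer(
            t, self._genes(), "gwas_rare", snp_meta=snp_meta, flank_bp=0
        )
        assert strict.n_edges == 0

    def test_insignificant_rows_filtered_by_bh(self):
        t = self._table(
            [("gA", "M1", 1e-8, "gwas_traditional"), ("gB", "M2", 0.9, "gwas_traditional")]
        )
        net = build_association_layer(
            t, self._genes(), "gwas_traditional", significance_q=0.1
        )
        assert net.has_edge("gA", "met:M1") and not net.has_edge("gB", "met:M2")

    def test_snp_in_overlapping_genes_maps_to_all(self):
        genes = pd.DataFrame(
            {"chromosome": ["c", "c"], "start": [1000, 1500], "end": [2000, 2500]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        )
        snp_meta = pd.DataFrame(
            {"chromosome": ["c"], "position": [1700]}, index=pd.Index(["snp1"])
        )
        t = self._table([("snp1", "M1", 1e-5, "gwas_traditional")])
        net = build_association_layer(
            t, genes, "gwas_traditional", snp_meta=snp_meta
        )
        assert net.has_edge("g1", "met:M1") and net.has_edge("g2", "met:M1")

    def test_eqtn_layer_connects_genes_to_transcripts(self):
        # eQTN phenotypes are transcripts (gene nodes), not metabolites
        snp_meta = pd.DataFrame(
            {"chromosome": ["c", "c"], "position": [2500, 51_000]},
            index=pd.Index(["snpA", "snpB"]),
        )
        t = self._table(
            [
                ("snpA", "gB", 1e-6, "eqtn"),  # trans: SNP in gA, transcript gB
                ("snpB", "gB", 1e-7, "eqtn"),  # cis: SNP in gB onto its own transcript
            ]
        )
        net = build_association_layer(t, self._genes(), "eqtn", snp_meta=snp_meta)
        assert net.edge_pairs() == {("gA", "gB")}
        assert net.node_kind("gB") == "gene"

    def test_unmapped_units_dropped(self, caplog):
        t = self._table([("nowhere", "M1", 1e-5, "gwas_traditional")])
        with caplog.at_level("INFO", logger="loenet"):
            net = build_association_layer(t, self._genes(), "gwas_traditional")
        assert net.n_edges == 0


def test_snps_to_genes_inclusive_bounds():
    genes = pd.DataFrame(
        {"chromosome": ["c"], "start": [100], "end": [200]},
        index=pd.Index(["g"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {"chromosome": ["c"] * 4, "position": [99, 100, 200, 201]},
        index=pd.Index(["a", "b", "c_", "d"]),
    )
    mapping = snps_to_genes(meta, genes)
    assert mapping == {"a": [], "b": ["g"], "c_": ["g"], "d": []}
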