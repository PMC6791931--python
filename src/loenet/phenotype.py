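"""Phenotype cleaning and multiple-testing procedures.

Association edges enter the LOE pipeline only after the phenotypes behind
them have been screened for outliers and the association p-values corrected
for multiple testing.  This module provides:

* a robust MAD outlier filter for metabolite phenotypes (samples more than
  ``k`` median absolute deviations from the population median are masked;
  the MAD here is *unscaled*, i.e. no 1.4826 consistency constant, because
  the rule counts MADs from the median directly);
* outlier masking of expression phenotypes relative to the non-zero median
  (used before eQTN association testing), with a retention rule requiring a
  non-outlier observed value in more than a given fraction of samples;
* Benjamini-Hochberg step-up FDR control;
* the Gavrilov-Benjamini-Sarkar (GBS) step-down procedure, with critical
  values c_i = i*q / (m + 1 - i*(1 - q));
* a two-round hierarchical correction (BH across phenotypes at ``q1``,
  then GBS within surviving phenotypes at ``q2``);
* a genotype MAF / missingness filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix, OmicsMatrix

logger = logging.getLogger("loenet")


@dataclass
class PhenotypeVector:
    """Per-sample phenotype values with a retained/removed mask."""

    phenotype_id: str
    values: pd.Series
    mask: pd.Series | None = None  # True = retained

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.Series(True, index=self.values.index)
        if len(self.mask) != len(self.values):
            raise ValueError("mask length must equal value length")

    @property
    def retained(self) -> pd.Series:
        return self.values[self.mask]


@dataclass
class MultipleTestingResult:
    """Outcome of a multiple-testing procedure over one p-value vector."""

    pvalues: np.ndarray
    reject: np.ndarray
    procedure: str
    levels: tuple
    qvalues: np.ndarray | None = None

    @property
    def n_rejected(self) -> int:
        return int(self.reject.sum())


def mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def mad_outlier_filter(x: PhenotypeVector, k: float = 6.0) -> PhenotypeVector:
    """Mask samples more than ``k`` MADs from the population median.

    When MAD = 0 (near-constant phenotype) the threshold is undefined; no
    sample is removed and a warning is logged rather than discarding the
    whole phenotype.
    """
    vals = x.retained.to_numpy(dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 non-missing values")
    med = float(np.median(vals))
    spread = mad(vals)
    mask = x.mask.copy()
    if spread == 0.0:
        logger.warning("MAD = 0 for phenotype %s: no outliers removed", x.phenotype_id)
        return PhenotypeVector(x.phenotype_id, x.values, mask)
    outlier = (x.values - med).abs() > k * spread
    mask &= ~outlier
    return PhenotypeVector(x.phenotype_id, x.values, mask)


def mask_expression_phenotypes(
    tpm: OmicsMatrix,
    mad_threshold: float = 5.0,
    retain_frac: float = 0.2,
) -> tuple[pd.DataFrame, list[str]]:
    """Outlier-mask transcript phenotypes and apply the retention rule.

    Per transcript, values whose absolute deviation from the median of the
    non-zero values exceeds ``mad_threshold`` times the (unscaled) MAD of the
    non-zero values are masked (set to NaN).  Transcripts with a non-outlier
    observed (non-zero) value in more than ``retain_frac`` of samples are
    retained.  All-zero transcripts are dropped and counted in the log.

    Returns the masked matrix (NaN at masked cells) and the retained
    transcript ids.
    """
    data = tpm.data.copy()
    retained: list[str] = []
    n_samples = data.shape[1]
    n_all_zero = 0
    for gene in data.index:
        row = data.loc[gene].to_numpy(dtype=float)
        nonzero = row[row > 0]
        if nonzero.size == 0:
            n_all_zero += 1
            continue
        med = float(np.median(nonzero))
        spread = mad(nonzero)
        if spread > 0:
            outlier = np.abs(row - med) > mad_threshold * spread
        else:
            outlier = np.zeros_like(row, dtype=bool)
        masked = row.astype(float)
        masked[outlier] = np.nan
        data.loc[gene] = masked
        n_observed = int(((row > 0) & ~outlier).sum())
        if n_observed > retain_frac * n_samples:
            retained.append(gene)
    if n_all_zero:
        logger.info("dropped %d all-zero transcript(s) from phenotype masking", n_all_zero)
    return data, retained


def bh_fdr(p, q: float = 0.1) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Rejects H_(i) for all i <= k* where k* = max{i : p_(i) <= i*q/m}.  Also
    returns BH-adjusted q-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return MultipleTestingResult(p, np.zeros(0, dtype=bool), "BH", (q,), p.copy())
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, qvalues, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return MultipleTestingResult(p, reject, "BH", (q,), qvalues)


def gbs_stepdown(p, q: float) -> MultipleTestingResult:
    """Gavrilov-Benjamini-Sarkar step-down procedure at level ``q``.

    Critical values c_i = i*q / (m + 1 - i*(1 - q)) for the ordered
    p-values; step-down rejects H_(1..k) for the largest k such that
    p_(i) <= c_i for every i <= k.
    """
    if not 0 < q < 1:
        raise ValueError("GBS level must lie in (0, 1)")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return MultipleTestingResult(p, np.zeros(0, dtype=bool), "GBS_stepdown", (q,))
    m = p.size
    order = np.argsort(p, kind="stable")
    i = np.arange(1, m + 1)
    crit = i * q / (m + 1 - i * (1 - q))
    passed = p[order] <= crit
    k = int(np.argmin(passed)) if not passed.all() else m
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return MultipleTestingResult(p, reject, "GBS_stepdown", (q,))


def hierarchical_correction(
    p_by_phenotype,
    q1: float = 0.1,
    q2: float = 5.1e-4,
    summary: str = "min",
) -> dict:
    """Two-round hierarchical FDR correction across many phenotypes.

    Round 1 applies BH at ``q1`` to one summary p-value per phenotype (the
    per-phenotype minimum by default; the choice of summary statistic is
    configurable).  Round 2 applies the GBS step-down at ``q2`` within each
    phenotype that survived round 1.  An association is significant iff it
    passes both rounds; phenotypes rejected in round 1 contribute no
    significant associations.

    Returns ``{phenotype: MultipleTestingResult}`` (the per-association
    round-2 result, all-False where round 1 failed).
    """
    if q2 >= 1:
        raise ValueError("q2 must be < 1")
    if summary != "min":
        raise ValueError(f"unknown round-1 summary {summary!r}")
    phenos = list(p_by_phenotype)
    summaries = np.array([np.min(np.asarray(p_by_phenotype[ph], dtype=float)) for ph in phenos])
    round1 = bh_fdr(summaries, q=q1)
    out: dict[str, MultipleTestingResult] = {}
    for ph, keep in zip(phenos, round1.reject):
        p = np.asarray(p_by_phenotype[ph], dtype=float)
        if keep:
            out[ph] = gbs_stepdown(p, q=q2)
        else:
            out[ph] = MultipleTestingResult(
                p, np.zeros(p.size, dtype=bool), "hierarchical", (q1, q2)
            )
    return out


def maf_filter(
    g: GenotypeMatrix, min_maf: float = 0.01, max_missing: float = 0.5
) -> GenotypeMatrix:
    """Drop SNPs with MAF < ``min_maf`` or missingness > ``max_missing``."""
    maf = g.maf()
    miss = g.missingness()
    keep = (maf >= min_maf) & (miss <= max_missing)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("maf_filter removed %d of %d SNPs", dropped, len(keep))
    return g.subset(list(g.dosages.index[keep]))
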