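"""Differential expression and signature extraction from count matrices.

The chain follows the standard bulk RNA-seq workflow for a two-group
genotype contrast: CPM-based expression filtering (a gene is expressed if
it reaches 1 count-per-million in at least one condition), a per-gene
negative-binomial Wald test, Benjamini-Hochberg adjustment with the
padj < 0.05 significance convention, ortholog mapping into a target
(human symbol) namespace, and extraction of the top-k up/down signature
sorted by Wald statistic (k = 50 by default).

The Wald test here is a desk-scale surrogate for a full NB GLM framework:
median-of-ratios library-size factors, per-gene method-of-moments
dispersion (variance = mu + alpha mu^2, floor 1e-8, no shrinkage), and a
delta-method standard error for the log fold change. p-values come from a
t reference with the residual degrees of freedom (n_a + n_b - 2), which
keeps the null type-I error calibrated at quadruplicate sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "cpm",
    "filter_expressed",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "count_deg",
    "map_orthologs",
    "select_signature",
]

DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class Signature:
    """Disjoint ordered up/down gene lists, at most k per side."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    k: int = 50

    def __post_init__(self):
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets must be disjoint")
        if len(self.up) > self.k or len(self.down) > self.k:
            raise ValueError("signature sides must not exceed k genes")


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size x 1e6 per sample."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0].tolist()
        raise ValueError(f"zero library size for samples {bad}")
    return counts / lib * 1e6


def filter_expressed(
    counts: pd.DataFrame, design: dict[str, str], threshold_cpm: float = 1.0
) -> pd.DataFrame:
    """Keep genes whose mean CPM reaches the threshold in >= 1 condition."""
    c = cpm(counts)
    groups = pd.Series(design)
    keep = pd.Series(False, index=counts.index)
    for g in groups.unique():
        samples = groups.index[groups == g]
        keep |= c[samples].mean(axis=1) >= threshold_cpm
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_expressed: dropped %d genes below %g CPM", dropped, threshold_cpm)
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    Computed on genes with all-positive counts against their geometric
    mean; falls back to total-count scaling (normalized to mean 1) when no
    such gene exists.
    """
    arr = counts.to_numpy(float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        logc = np.log(arr[positive])
        log_gm = logc.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logc - log_gm, axis=0))
    else:
        lib = arr.sum(axis=0)
        sf = lib / lib.mean()
    return pd.Series(sf, index=counts.columns)


# ---------------------------------------------------------------------------
# NB Wald surrogate test
# ---------------------------------------------------------------------------

def _group_moments(q: np.ndarray, inv_s: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean, sample variance, and mean reciprocal size factor per group of
    normalized counts q (genes x samples)."""
    mu = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    return mu, v, float(np.mean(inv_s))


def nb_wald_test(
    counts: pd.DataFrame, design: dict[str, str], contrast: tuple[str, str]
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``contrast = (group_b, group_a)``:
    log2 fold change of group_b over reference group_a.

    Returns a DataFrame with columns ``gene_id, log2fc, fold_change, wald,
    pvalue, padj`` (BH-adjusted); genes with all-zero counts in both
    contrast groups are excluded with a log notice.
    """
    group_b, group_a = contrast
    groups = pd.Series(design)
    cols_a = [s for s in counts.columns if groups.get(s) == group_a]
    cols_b = [s for s in counts.columns if groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each contrast group needs >= 2 replicates")

    sub = counts[cols_a + cols_b]
    sf = size_factors(sub)
    q = sub.to_numpy(float) / sf.to_numpy()
    n_a, n_b = len(cols_a), len(cols_b)
    qa, qb = q[:, :n_a], q[:, n_a:]

    nonzero = (qa.sum(axis=1) + qb.sum(axis=1)) > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("nb_wald_test: excluded %d genes with all-zero counts", n_excluded)
    qa, qb = qa[nonzero], qb[nonzero]
    genes = counts.index[nonzero]

    inv_sa = 1.0 / sf.to_numpy()[:n_a]
    inv_sb = 1.0 / sf.to_numpy()[n_a:]
    mu_a, v_a, mean_inv_sa = _group_moments(qa, inv_sa)
    mu_b, v_b, mean_inv_sb = _group_moments(qb, inv_sb)

    # method-of-moments dispersion pooled across the two groups:
    # Var(q) ~= mu * mean(1/s) + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (v_a - mu_a * mean_inv_sa) / np.square(mu_a)
        alpha_b = (v_b - mu_b * mean_inv_sb) / np.square(mu_b)
    alpha_a = np.where(np.isfinite(alpha_a), alpha_a, 0.0)
    alpha_b = np.where(np.isfinite(alpha_b), alpha_b, 0.0)
    w_a, w_b = n_a - 1, n_b - 1
    alpha = np.maximum((w_a * alpha_a + w_b * alpha_b) / (w_a + w_b), DISPERSION_FLOOR)

    # continuity correction only where a group mean is zero, keeping the
    # log fold change finite; identical groups still give exactly zero.
    pseudo = np.where((mu_a == 0) | (mu_b == 0), 0.5, 0.0)
    ma, mb = mu_a + pseudo, mu_b + pseudo

    # delta-method SE of log mu per group under Var(q_j) = mu/s_j + alpha mu^2
    var_mean_a = (ma * mean_inv_sa + alpha * ma**2) / n_a
    var_mean_b = (mb * mean_inv_sb + alpha * mb**2) / n_b
    se_log = np.sqrt(var_mean_a / ma**2 + var_mean_b / mb**2)

    log_ratio = np.log(mb) - np.log(ma)
    log2fc = log_ratio / np.log(2.0)
    wald = np.where(log_ratio == 0, 0.0, log_ratio / se_log)
    df = n_a + n_b - 2
    pvalue = 2.0 * sst.t.sf(np.abs(wald), df)
    pvalue = np.clip(pvalue, np.finfo(float).tiny, 1.0)

    res = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": log2fc,
            "fold_change": 2.0**log2fc,
            "wald": wald,
            "pvalue": pvalue,
            "padj": bh_adjust(pvalue),
        }
    ).reset_index(drop=True)
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DEG counting, ortholog mapping, signature selection
# ---------------------------------------------------------------------------

def count_deg(
    results: pd.DataFrame, alpha: float = 0.05, min_abs_fc: float | None = None
) -> tuple[int, int, int]:
    """Count significant genes (padj < alpha): total, up (FC > 1), down.

    With ``min_abs_fc`` given, genes must additionally satisfy
    fold_change >= min_abs_fc (up) or <= 1/min_abs_fc (down); the total is
    the sum of the two sides in every case.
    """
    if len(results) == 0:
        return 0, 0, 0
    sig = results["padj"] < alpha
    up = sig & (results["fold_change"] > 1)
    down = sig & (results["fold_change"] <= 1)
    if min_abs_fc is not None:
        up &= results["fold_change"] >= min_abs_fc
        down &= results["fold_change"] <= 1.0 / min_abs_fc
    return int(up.sum() + down.sum()), int(up.sum()), int(down.sum())


def map_orthologs(results: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Rename DE results into the target (ortholog) namespace.

    Unmapped source genes are dropped (count logged). A source mapping to
    several targets contributes its statistics to each target once; when
    several sources map to one target, the entry with the largest |Wald|
    wins (ties: smaller p, then lexicographic source id).
    """
    if len(table) == 0:
        raise ValueError("empty ortholog mapping table")
    merged = results.merge(table, left_on="gene_id", right_on="source_id", how="inner")
    n_unmapped = results["gene_id"].nunique() - merged["gene_id"].nunique()
    if n_unmapped > 0:
        logger.info("map_orthologs: dropped %d unmapped genes", n_unmapped)
    merged = merged.assign(_abs_wald=merged["wald"].abs())
    merged = merged.sort_values(
        ["target_symbol", "_abs_wald", "pvalue", "gene_id"],
        ascending=[True, False, True, True],
    )
    out = merged.drop_duplicates("target_symbol", keep="first").copy()
    out["gene_id"] = out["target_symbol"]
    return out[["gene_id", "log2fc", "fold_change", "wald", "pvalue", "padj"]].reset_index(
        drop=True
    )


def select_signature(results: pd.DataFrame, k: int = 50) -> Signature:
    """Top-k up- and down-regulated genes sorted by Wald statistic.

    Up = the k genes with the largest positive Wald statistic (descending);
    down = the k most-negative (ascending). Ties break by smaller raw p,
    then lexicographic gene id, making the output invariant to row order.
    """
    res = results.copy()
    pos = res[res["wald"] > 0].sort_values(
        ["wald", "pvalue", "gene_id"], ascending=[False, True, True]
    )
    neg = res[res["wald"] < 0].sort_values(
        ["wald", "pvalue", "gene_id"], ascending=[True, True, True]
    )
    if len(pos) < k or len(neg) < k:
        logger.info(
            "select_signature: only %d up / %d down genes available for k=%d",
            len(pos), len(neg), k,
        )
    return Signature(
        up=tuple(pos["gene_id"].head(k)), down=tuple(neg["gene_id"].head(k)), k=k
    )
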