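"""Tumor-vs-normal differential expression of the panel genes.

Per cancer type with at least ``min_normals`` normal samples, each
panel gene is tested by the two-sided Wilcoxon rank-sum test, p-values
are Benjamini-Hochberg adjusted within the cancer type across panel
genes, and a gene is a DEG when the adjusted p is below 0.01 and the
fold change is at least two-fold in either direction.  Expression
values arrive on the log2(norm+1) scale; the default fold change is
therefore computed on linearized values ``2**x - 1`` (a
difference-of-log2-means variant is config-selectable).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .errors import AnalysisError
from .panel import GenePanel

logger = logging.getLogger(__name__)

#: largest combined sample size for the exact rank-sum path
EXACT_MAX_N = 12


def rank_sum_test(tumor: np.ndarray, normal: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when the combined sample size is at most 12 and
    there are no ties; otherwise the normal approximation with midrank
    tie correction and continuity correction.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size == 0 or normal.size == 0:
        raise AnalysisError("rank-sum test requires two non-empty groups")
    pooled = np.concatenate([tumor, normal])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(tumor, normal, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(res.pvalue)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AnalysisError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fold_change(tumor: np.ndarray, normal: np.ndarray, scale: str) -> float:
    """Linear-scale fold change tumor/normal from log2(norm+1) values."""
    if scale == "log2":
        return float(2.0 ** (tumor.mean() - normal.mean()))
    t = np.mean(2.0 ** tumor - 1.0)
    n = np.mean(2.0 ** normal - 1.0)
    if n == 0:
        return np.inf if t > 0 else 1.0
    return float(t / n)


def call_degs(expression: pd.DataFrame, sample_meta: pd.DataFrame,
              panel: GenePanel, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Differential-expression calls per panel gene per cancer type.

    Cancer types with fewer than ``config.min_normals`` normal samples
    are skipped entirely (the expression feature is missing for them,
    not zero).  BH adjustment is within one cancer type across the
    tested panel genes.  "At least two-fold" is inclusive: fold change
    >= 2 or <= 1/2 (linear scale).

    Returns
    -------
    pandas.DataFrame
        Columns gene, cancer_type, n_tumor, n_normal, fold_change,
        log2_fold_change, p, p_adjusted, is_deg.  ``.attrs["skipped"]``
        lists the cancer types skipped for lack of normals.
    """
    config = config or PipelineConfig()
    meta = sample_meta.set_index("sample")
    shared = [s for s in expression.columns if s in meta.index]
    meta = meta.loc[shared]
    genes = [g for g in panel.symbols if g in expression.index]
    results, skipped = [], []
    for ctype, grp in meta.groupby("cancer_type"):
        tumor_ids = grp.index[grp["sample_type"] == "tumor"]
        normal_ids = grp.index[grp["sample_type"] == "normal"]
        if len(normal_ids) < config.min_normals:
            skipped.append(ctype)
            logger.info("DEG stage: skipping %s (%d < %d normal samples)",
                        ctype, len(normal_ids), config.min_normals)
            continue
        if len(tumor_ids) == 0:
            skipped.append(ctype)
            continue
        tmat = expression.loc[genes, tumor_ids].to_numpy(dtype=float)
        nmat = expression.loc[genes, normal_ids].to_numpy(dtype=float)
        block = []
        for i, gene in enumerate(genes):
            t, n = tmat[i], nmat[i]
            fc = _fold_change(t, n, config.fold_change_scale)
            block.append(dict(
                gene=gene, cancer_type=ctype,
                n_tumor=len(tumor_ids), n_normal=len(normal_ids),
                fold_change=fc,
                log2_fold_change=float(np.log2(fc)) if fc > 0 else -np.inf,
                p=rank_sum_test(t, n),
            ))
        block = pd.DataFrame(block)
        block["p_adjusted"] = bh_adjust(block["p"].to_numpy())
        fc = block["fold_change"]
        big = (fc >= config.deg_fold_change) | (fc <= 1.0 / config.deg_fold_change)
        block["is_deg"] = (block["p_adjusted"] < config.deg_adjusted_p) & big
        results.append(block)
    out = (pd.concat(results, ignore_index=True) if results
           else pd.DataFrame(columns=["gene", "cancer_type", "n_tumor", "n_normal",
                                      "fold_change", "log2_fold_change", "p",
                                      "p_adjusted", "is_deg"]))
    out.attrs["skipped"] = skipped
    return out


def deg_counts(deg_results: pd.DataFrame, panel: GenePanel) -> pd.Series:
    """Number of differentially expressed BRCAness (non-reference) genes
    per tested cancer type.  Skipped cancer types are absent."""
    non_ref = set(panel.brcaness_genes)
    sub = deg_results.loc[deg_results["gene"].isin(non_ref)]
    counts = sub.groupby("cancer_type")["is_deg"].sum().astype(int)
    counts = counts.reindex(sorted(deg_results["cancer_type"].unique()), fill_value=0)
    return counts
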