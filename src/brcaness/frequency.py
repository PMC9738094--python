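"""Gene x cancer-type frequency matrices and correlation against BRCA1/2.

Both the pathogenic-variant stage and the homozygous-deletion stage
reduce to the same two objects: a carrier-frequency matrix (per gene,
per cancer type: carriers / samples) and a list of Pearson correlations
of each BRCAness gene's frequency profile across cancer types against
each of the two reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .panel import GenePanel


@dataclass
class FrequencyMatrix:
    """Carrier frequencies per gene per cancer type.

    Attributes
    ----------
    freq : pandas.DataFrame
        genes x cancer types, each cell ``numerator / denominator``;
        NaN where the denominator is zero (a missing cell, never 0).
    numerator : pandas.DataFrame
        Distinct carrier samples per gene per cancer type.
    denominator : pandas.Series
        Samples per cancer type.
    """

    freq: pd.DataFrame
    numerator: pd.DataFrame
    denominator: pd.Series

    def __post_init__(self) -> None:
        if self.freq.size == 0:
            return
        defined = self.freq.notna()
        vals = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise AnalysisError("frequencies must lie in [0, 1]")
        recomputed = self.numerator.div(self.denominator, axis=1)
        if not np.allclose(
            self.freq.to_numpy(dtype=float)[defined.to_numpy()],
            recomputed.to_numpy(dtype=float)[defined.to_numpy()],
        ):
            raise AnalysisError("freq != numerator / denominator")

    @property
    def cancer_types(self) -> list[str]:
        return list(self.freq.columns)

    def pooled(self) -> pd.Series:
        """Pan-cancer pooled fraction per gene: sum(num) / sum(denom)."""
        total = float(self.denominator.sum())
        if total == 0:
            raise AnalysisError("no samples in any cancer type")
        return self.numerator.sum(axis=1) / total


def frequency_matrix(
    carriers: pd.DataFrame, sample_map: pd.Series, genes: list[str]
) -> FrequencyMatrix:
    """Build a :class:`FrequencyMatrix` from a (sample, gene) carrier table.

    Parameters
    ----------
    carriers : pandas.DataFrame
        Columns ``sample`` and ``gene``; one row per (sample, gene) event,
        duplicates allowed (a sample carrying several events in one gene
        is still one carrier).
    sample_map : pandas.Series
        sample -> cancer-type label for every sample of the cohort; the
        denominator for a type is its number of mapped samples.
    genes : list of str
        Row universe; genes without carriers get frequency 0.
    """
    denom = sample_map.value_counts()
    types = sorted(denom.index)
    distinct = carriers.drop_duplicates(["sample", "gene"]).copy()
    distinct["cancer_type"] = distinct["sample"].map(sample_map)
    if distinct["cancer_type"].isna().any():
        bad = sorted(distinct.loc[distinct["cancer_type"].isna(), "sample"].unique())
        raise AnalysisError(f"carrier samples missing from sample map: {bad[:10]}")
    num = (
        distinct.groupby(["gene", "cancer_type"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(index=genes, columns=types, fill_value=0)
        .astype(int)
    )
    denom = denom.reindex(types)
    freq = num.div(denom, axis=1)
    return FrequencyMatrix(freq=freq, numerator=num, denominator=denom.astype(int))


def correlate_with_references(
    freq: FrequencyMatrix,
    panel: GenePanel,
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each BRCAness gene's frequencies vs BRCA1/2.

    For every non-reference panel gene and each of the two reference
    genes, computes Pearson r over the cancer types where both genes
    have a defined frequency (pairwise-complete), with the two-sided
    p-value from the t transform on n - 2 degrees of freedom.  A pair
    is ``significant`` iff p < alpha and \\|r\\| > threshold.  Pairs with
    fewer than 3 complete cancer types or zero variance in either
    vector are returned with ``undefined = True`` and are never
    significant.

    Returns
    -------
    pandas.DataFrame
        Columns gene, reference, r, p, n, significant, undefined.
    """
    rows = []
    f = freq.freq
    for ref in panel.reference_genes:
        if ref not in f.index:
            raise AnalysisError(f"reference gene {ref} absent from frequency matrix")
        for gene in panel.brcaness_genes:
            if gene not in f.index:
                continue
            pair = f.loc[[gene, ref]].T.dropna()
            n = len(pair)
            r = p = np.nan
            undefined = True
            if n >= 3:
                x = pair[gene].to_numpy(dtype=float)
                y = pair[ref].to_numpy(dtype=float)
                if np.ptp(x) > 0 and np.ptp(y) > 0:
                    r, p = stats.pearsonr(x, y)
                    undefined = False
            significant = bool(
                not undefined and p < alpha and abs(r) > threshold
            )
            rows.append(
                dict(gene=gene, reference=ref, r=r, p=p, n=n,
                     significant=significant, undefined=undefined)
            )
    return pd.DataFrame(rows)
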