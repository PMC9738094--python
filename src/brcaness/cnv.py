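"""Homozygous-deletion analysis from GISTIC-coded gene-level copy number.

Code -2 (deep/homozygous deletion) is the event of interest; codes -1
through 2 never count.  Frequencies are computed per gene per cancer
type, pooled pan-cancer per gene, correlated with BRCA1/2 (|r| > 0.4
significance rule), and each BRCAness gene's pooled frequency is
classified as strictly lower / not lower than each reference gene's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .frequency import FrequencyMatrix, correlate_with_references, frequency_matrix
from .panel import GenePanel

HOMDEL_CODE = -2


def homdel_frequency(cnv: pd.DataFrame, sample_map: pd.Series) -> FrequencyMatrix:
    """Fraction of samples at GISTIC code -2, per gene per cancer type."""
    if not np.isin(cnv.to_numpy(), [-2, -1, 0, 1, 2]).all():
        raise AnalysisError("CNV codes outside {-2..2}")
    missing = sorted(set(cnv.columns) - set(sample_map.index))
    if missing:
        raise AnalysisError(f"CNV samples missing from sample map: {missing[:10]}")
    hom = cnv.eq(HOMDEL_CODE)
    gene_idx, sample_idx = np.nonzero(hom.to_numpy())
    carriers = pd.DataFrame({
        "sample": cnv.columns.to_numpy()[sample_idx],
        "gene": cnv.index.to_numpy()[gene_idx],
    })
    return frequency_matrix(carriers, sample_map.loc[list(cnv.columns)], list(cnv.index))


def correlate_homdel(freq: FrequencyMatrix, panel: GenePanel,
                     threshold: float = 0.4, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of homozygous-deletion frequencies vs BRCA1/2."""
    return correlate_with_references(freq, panel, threshold=threshold, alpha=alpha)


def classify_vs_references(freq: FrequencyMatrix, panel: GenePanel) -> pd.DataFrame:
    """Compare each gene's pan-cancer pooled frequency to the references.

    "Lower" is a strict ``<`` against each reference gene's pooled
    frequency; ties are "not lower".  The pooled fraction (all samples
    pooled) is used because the comparison is a single per-gene number.

    Returns
    -------
    pandas.DataFrame
        Indexed by non-reference gene: pooled frequency, one boolean
        ``lower_than_<ref>`` column per reference, with per-reference
        totals in ``.attrs["counts"]``.
    """
    pooled = freq.pooled()
    refs = panel.reference_genes
    for ref in refs:
        if ref not in pooled.index:
            raise AnalysisError(f"reference gene {ref} absent from frequency matrix")
    genes = [g for g in panel.brcaness_genes if g in pooled.index]
    out = pd.DataFrame({"pooled_freq": pooled.loc[genes]})
    counts = {}
    for ref in refs:
        col = f"lower_than_{ref}"
        out[col] = out["pooled_freq"] < pooled.loc[ref]
        counts[ref] = int(out[col].sum())
    out.attrs["counts"] = counts
    return out


def cancer_type_homdel_burden(freq: FrequencyMatrix, panel: GenePanel) -> pd.DataFrame:
    """Per-cancer-type homozygous-deletion burden over BRCAness genes.

    The aggregation over genes is not uniquely determined by a single
    per-type number, so both the sum and the mean of per-gene
    frequencies (non-reference genes) are reported, clearly labeled.
    """
    genes = [g for g in panel.brcaness_genes if g in freq.freq.index]
    sub = freq.freq.loc[genes]
    return pd.DataFrame({"sum_freq": sub.sum(axis=0, skipna=True),
                         "mean_freq": sub.mean(axis=0, skipna=True)})
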