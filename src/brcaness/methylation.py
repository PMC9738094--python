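"""Promoter methylation: probe assignment, beta aggregation, silencing calls.

A gene's promoter is the window TSS +/- 10 kb (boundary inclusive) on
the same chromosome; a 450k-style probe may fall in several genes'
windows and is then assigned to all of them.  Hypermethylation is a
strict mean-beta > 0.3 call.  The per-cancer methylation load is the
sum of per-gene mean promoter betas over the non-reference genes, with
the BRCA1/2 reference genes reported separately.  Methylation-
expression association correlates per-sample promoter mean beta with
per-sample expression; r <= -0.5 is a silencing call, r >= +0.5
enhancing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .panel import GenePanel

logger = logging.getLogger(__name__)


def _norm_chrom(c: str) -> str:
    c = str(c).strip()
    return c[3:] if c.lower().startswith("chr") else c


def assign_promoter_probes(manifest: pd.DataFrame, panel: GenePanel,
                           window: int = 10_000) -> pd.DataFrame:
    """Map probes to the panel genes whose promoter window contains them.

    A probe maps to gene g iff ``|pos - TSS_g| <= window`` and the
    chromosomes agree after normalizing "chr1" vs "1" naming (logged
    when applied).  Returns a long-format table (probe, gene, distance);
    a probe may appear once per gene it hits.
    """
    tss = panel.tss()
    man_chr = manifest["chrom"].map(_norm_chrom)
    pan_chr = tss["tss_chrom"].map(_norm_chrom)
    if len(manifest) and not manifest["chrom"].equals(man_chr.astype(manifest["chrom"].dtype)):
        logger.info("normalized 'chr' prefixes between manifest and panel")
    rows = []
    for gene, (chrom, pos) in zip(tss.index, zip(pan_chr, tss["tss_pos"])):
        on_chrom = manifest.loc[man_chr == chrom]
        dist = (on_chrom["pos"] - pos).abs()
        hits = dist[dist <= window]
        for probe, d in hits.items():
            rows.append((probe, gene, int(d)))
    return pd.DataFrame(rows, columns=["probe", "gene", "distance"])


@dataclass
class PromoterProfile:
    """Per-gene, per-cancer promoter methylation summary.

    ``mean_beta`` is NaN for a (gene, cancer) without probes in the
    window — missing, never zero.  ``hypermethylated`` is the strict
    ``mean_beta > cutoff`` call.
    """

    mean_beta: pd.DataFrame
    probe_counts: pd.Series
    hypermethylated: pd.DataFrame
    cutoff: float


def promoter_sample_means(methylation: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Per-sample promoter mean beta per gene (genes x samples)."""
    if not len(probe_map):
        raise AnalysisError("empty probe map")
    present = probe_map.loc[probe_map["probe"].isin(methylation.index)]
    out = {}
    for gene, grp in present.groupby("gene"):
        out[gene] = methylation.loc[grp["probe"]].mean(axis=0)
    return pd.DataFrame(out).T


def promoter_means(methylation: pd.DataFrame, probe_map: pd.DataFrame,
                   sample_map: pd.Series, cutoff: float = 0.3) -> PromoterProfile:
    """Mean promoter beta per gene per cancer type, with hypermethylation calls.

    The mean is over all (window probe, sample-of-type) beta values.
    Genes with no probes in the window are absent from the profile.
    """
    if not len(probe_map):
        raise AnalysisError("empty probe map")
    samples = [s for s in methylation.columns if s in sample_map.index]
    if len(samples) < len(methylation.columns):
        raise AnalysisError("methylation samples missing from sample map")
    types = sample_map.loc[samples]
    present = probe_map.loc[probe_map["probe"].isin(methylation.index)]
    rows, counts = {}, {}
    for gene, grp in present.groupby("gene"):
        block = methylation.loc[grp["probe"], samples]
        counts[gene] = len(grp)
        # mean over probes x samples within each cancer type
        rows[gene] = block.T.groupby(types).mean().mean(axis=1)
    mean_beta = pd.DataFrame(rows).T
    probe_counts = pd.Series(counts, name="n_probes")
    # strict > with a guard for floating-point representation of the cutoff:
    # a mean that equals the cutoff up to 1e-12 is not hypermethylated
    hyper = (mean_beta > cutoff) & ~np.isclose(mean_beta, cutoff, rtol=0.0, atol=1e-12)
    return PromoterProfile(
        mean_beta=mean_beta,
        probe_counts=probe_counts,
        hypermethylated=hyper,
        cutoff=cutoff,
    )


def methylation_load(profile: PromoterProfile, panel: GenePanel) -> pd.DataFrame:
    """Total promoter methylation level per cancer type.

    ``load`` sums the per-gene mean betas over non-reference genes with
    a defined cell; ``n_genes`` counts the genes included; the two
    reference genes' means are reported in their own columns.
    """
    genes = [g for g in panel.brcaness_genes if g in profile.mean_beta.index]
    sub = profile.mean_beta.loc[genes]
    out = pd.DataFrame({
        "load": sub.sum(axis=0, skipna=True),
        "n_genes": sub.notna().sum(axis=0),
    })
    for ref in panel.reference_genes:
        out[f"{ref}_mean_beta"] = (
            profile.mean_beta.loc[ref] if ref in profile.mean_beta.index else np.nan
        )
    return out


def methylation_expression_association(
    methylation: pd.DataFrame, probe_map: pd.DataFrame, expression: pd.DataFrame,
    sample_map: pd.Series, threshold: float = 0.5,
) -> pd.DataFrame:
    """Silencing/enhancing calls per gene per cancer type.

    Correlates per-sample promoter mean beta against per-sample
    expression over the samples shared between the two assays within
    each cancer type.  ``call`` is "silencing" when r <= -threshold,
    "enhancing" when r >= +threshold, otherwise "none"; pairs with
    fewer than 3 shared samples or zero variance are undefined.
    """
    sample_beta = promoter_sample_means(methylation, probe_map)
    shared = [s for s in sample_beta.columns if s in expression.columns and s in sample_map.index]
    rows = []
    genes = [g for g in sample_beta.index if g in expression.index]
    types = sample_map.loc[shared]
    for ctype in sorted(types.unique()):
        cols = [s for s in shared if types[s] == ctype]
        for gene in genes:
            b = sample_beta.loc[gene, cols].to_numpy(dtype=float)
            e = expression.loc[gene, cols].to_numpy(dtype=float)
            ok = np.isfinite(b) & np.isfinite(e)
            r, call, undefined = np.nan, "none", True
            if ok.sum() >= 3 and np.ptp(b[ok]) > 0 and np.ptp(e[ok]) > 0:
                r, _ = stats.pearsonr(b[ok], e[ok])
                undefined = False
                if r <= -threshold:
                    call = "silencing"
                elif r >= threshold:
                    call = "enhancing"
            rows.append(dict(gene=gene, cancer_type=ctype, r=r,
                             n=int(ok.sum()), call=call, undefined=undefined))
    return pd.DataFrame(rows)


def classify_hypermethylated_genes(profile: PromoterProfile, panel: GenePanel,
                                   cutoff_gene: str = "BRCA2") -> pd.DataFrame:
    """Per-gene pan-cancer mean beta vs a reference gene's pan-cancer mean.

    Flags each non-reference gene as hypermethylated when its pan-cancer
    mean (over cancer types) exceeds the cutoff gene's.
    """
    if cutoff_gene not in profile.mean_beta.index:
        raise AnalysisError(f"cutoff gene {cutoff_gene} absent from profile")
    pan = profile.mean_beta.mean(axis=1, skipna=True)
    cut = pan.loc[cutoff_gene]
    genes = [g for g in panel.brcaness_genes if g in pan.index]
    return pd.DataFrame({
        "pan_mean_beta": pan.loc[genes],
        "hypermethylated_vs_cutoff": pan.loc[genes] > cut,
    })
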