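"""Pathogenic/likely-pathogenic (PLP) variant analysis.

The stage mirrors how PLP burden is established in pan-cancer catalogs:
variant calls are filtered to passing, non-silent rows; matched by
normalized genomic key against a ClinVar/COSMIC-style pathogenicity
catalog; reduced to per-gene, per-cancer-type carrier frequencies
(distinct carrier samples over samples of the type); and each BRCAness
gene's frequency profile across cancer types is correlated with
BRCA1/2 by Pearson's r.

Indel keys are normalized reference-free by parsimony trimming (shared
allele suffix, then shared prefix with a position shift), which
canonicalizes the common padded MAF/catalog representations; full
left-alignment against a reference genome is out of scope.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import KNOWN_SILENT, PipelineConfig
from .errors import AnalysisError
from .frequency import FrequencyMatrix, correlate_with_references, frequency_matrix
from .panel import GenePanel

logger = logging.getLogger(__name__)

#: FILTER values accepted as passing.
PASSING_FILTERS = {"PASS", "pass", "."}


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Parsimony-normalize an allele pair: trim shared suffix, then prefix.

    Positions are 1-based; trimming a shared prefix advances the
    position accordingly.  At least one base is kept on each allele.
    """
    ref, alt = str(ref), str(alt)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return str(chrom), int(pos), ref, alt


def _normalized_keys(df: pd.DataFrame, chrom: str, pos: str, ref: str, alt: str) -> pd.Series:
    if not len(df):
        return pd.Series(dtype=object)
    return pd.Series(
        [normalize_key(c, p, r, a)
         for c, p, r, a in zip(df[chrom], df[pos], df[ref], df[alt])],
        index=df.index,
    )


def filter_variants(variants: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Keep passing-filter, non-silent variant rows.

    Rows whose ``Variant_Classification`` is neither in the configured
    non-silent set nor a recognized silent class are flagged as unknown,
    excluded, and logged.
    """
    config = config or PipelineConfig()
    if not len(variants):
        return variants.copy()
    non_silent = set(config.non_silent_classifications)
    known = non_silent | set(KNOWN_SILENT)
    cls = variants["Variant_Classification"]
    unknown = ~cls.isin(known)
    if unknown.any():
        logger.warning(
            "excluding %d variant rows with unknown classification(s): %s",
            int(unknown.sum()), sorted(cls[unknown].unique()),
        )
    passing = variants["FILTER"].isin(PASSING_FILTERS)
    keep = passing & cls.isin(non_silent)
    logger.info("variant filter: %d of %d rows retained", int(keep.sum()), len(variants))
    return variants.loc[keep].copy()


def match_plp(variants: pd.DataFrame, catalog: pd.DataFrame,
              config: PipelineConfig | None = None) -> pd.DataFrame:
    """Keep variants whose normalized genomic key occurs in the PLP catalog.

    A key present in both catalog sources matches once (set semantics);
    a sample's row duplicated across sources is deduplicated.  With
    ``match_level = "protein"`` matching is on (gene, HGVSp) instead,
    requiring an ``HGVSp`` column in both tables.
    """
    config = config or PipelineConfig()
    if not len(variants) or not len(catalog):
        return variants.iloc[0:0].copy()
    if config.match_level == "protein":
        for df, name in ((variants, "variants"), (catalog, "catalog")):
            if "HGVSp" not in df.columns:
                raise AnalysisError(f"protein-level matching requires HGVSp in {name}")
        keys = set(zip(catalog["gene"].str.upper(), catalog["HGVSp"]))
        hit = [
            (g.upper(), p) in keys
            for g, p in zip(variants["Hugo_Symbol"], variants["HGVSp"])
        ]
    else:
        keys = set(_normalized_keys(catalog, "chrom", "pos", "ref", "alt"))
        var_keys = _normalized_keys(
            variants, "Chromosome", "Start_Position",
            "Reference_Allele", "Tumor_Seq_Allele2",
        )
        hit = var_keys.isin(keys)
    matched = variants.loc[hit].drop_duplicates(
        ["Tumor_Sample_Barcode", "Chromosome", "Start_Position",
         "Reference_Allele", "Tumor_Seq_Allele2", "origin"]
    )
    logger.info("PLP matching: %d of %d filtered rows matched", len(matched), len(variants))
    return matched.copy()


def plp_frequency(matched: pd.DataFrame, sample_map: pd.Series,
                  genes: list[str], origin: str | None = None) -> FrequencyMatrix:
    """Carrier frequency per gene per cancer type.

    frequency = (# distinct samples with >=1 PLP in the gene) /
    (# samples of the cancer type).  Cancer types with zero samples are
    missing (NaN), never zero.
    """
    sub = matched
    if origin is not None:
        if origin not in ("somatic", "germline"):
            raise AnalysisError(f"origin must be somatic/germline, got {origin!r}")
        sub = matched.loc[matched["origin"] == origin]
    carriers = pd.DataFrame({
        "sample": sub["Tumor_Sample_Barcode"].to_numpy() if len(sub) else [],
        "gene": sub["Hugo_Symbol"].to_numpy() if len(sub) else [],
    })
    return frequency_matrix(carriers, sample_map, genes)


def summarize_plp(somatic: pd.DataFrame, germline: pd.DataFrame, n_types: int) -> dict:
    """Totals and per-cancer-type means of matched PLP mutations.

    Means are reported raw and rounded to the nearest integer
    (round-half-to-even, Python's ``round``).
    """
    if n_types <= 0:
        raise AnalysisError("n_types must be positive")
    out = {}
    for name, table in (("somatic", somatic), ("germline", germline)):
        total = int(len(table))
        mean = total / n_types
        out[f"{name}_total"] = total
        out[f"{name}_mean"] = mean
        out[f"{name}_mean_rounded"] = round(mean)
    out["n_types"] = n_types
    return out


def correlate_plp(freq: FrequencyMatrix, panel: GenePanel,
                  threshold: float = 0.5, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of PLP frequencies vs BRCA1/2 (|r| > 0.5 rule)."""
    return correlate_with_references(freq, panel, threshold=threshold, alpha=alpha)
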