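"""Composite BRCAness score: six features, reference-normalized, ranked.

Each cancer type gets six raw features:

somatic / germline — sum over BRCAness genes of per-gene PLP carrier
frequency; homozygotic — same for GISTIC -2 frequency; methylation —
total promoter methylation load; expression — number of differentially
expressed BRCAness genes (missing for cancer types without enough
normals); prognosis — number of prognostic BRCAness genes.

Every feature is divided by its value in each of the two reference
cancer types (BRCA-like and OV-like), giving 12 normalized columns in
which the references are exactly 1.0.  The Sum of the 12 columns
(missing cells contribute 0) ranks the cancer types; a type qualifies
as a BRCAness candidate when its Sum strictly exceeds the reference Sum
(12.0 when all six features are defined).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AnalysisError, NormalizationError
from .frequency import FrequencyMatrix
from .panel import GenePanel

FEATURES = ("somatic", "germline", "homozygotic", "methylation",
            "expression", "prognosis")


def _frequency_feature(freq: FrequencyMatrix, panel: GenePanel) -> pd.Series:
    genes = [g for g in panel.brcaness_genes if g in freq.freq.index]
    return freq.freq.loc[genes].sum(axis=0, skipna=True)


def assemble_features(
    somatic: FrequencyMatrix,
    germline: FrequencyMatrix,
    homdel: FrequencyMatrix,
    meth_load: pd.DataFrame,
    deg_counts: pd.Series,
    risky_counts: pd.Series,
    panel: GenePanel,
) -> pd.DataFrame:
    """Cancer type x six raw BRCAness features.

    Cells are missing (NaN) only where the producing stage declared
    them missing — e.g. the expression feature for cancer types skipped
    for lack of normal samples.
    """
    types = sorted(
        set(somatic.cancer_types) | set(germline.cancer_types)
        | set(homdel.cancer_types) | set(meth_load.index)
    )
    if not types:
        raise AnalysisError("empty cohort: no cancer types in any stage output")
    out = pd.DataFrame(index=pd.Index(types, name="cancer_type"))
    out["somatic"] = _frequency_feature(somatic, panel).reindex(types)
    out["germline"] = _frequency_feature(germline, panel).reindex(types)
    out["homozygotic"] = _frequency_feature(homdel, panel).reindex(types)
    out["methylation"] = meth_load["load"].reindex(types)
    out["expression"] = deg_counts.reindex(types).astype(float)
    out["prognosis"] = risky_counts.reindex(types).fillna(0).astype(float)
    return out


def normalize(features: pd.DataFrame, ref1: str, ref2: str) -> pd.DataFrame:
    """Divide every feature by its value in each reference cancer type.

    Produces 12 columns named ``<feature>_by_<ref>``; reference rows are
    exactly 1.0 in every defined column, missing cells stay missing.
    Both references must be present with all six features defined and
    non-zero.
    """
    for ref in (ref1, ref2):
        if ref not in features.index:
            raise NormalizationError(f"reference cancer type {ref!r} absent from features")
        row = features.loc[ref]
        for feat in FEATURES:
            v = row[feat]
            if pd.isna(v):
                raise NormalizationError(f"reference {ref!r} feature {feat!r} is missing")
            if v == 0:
                raise NormalizationError(
                    f"reference {ref!r} feature {feat!r} is zero; normalization undefined"
                )
    cols = {}
    for ref in (ref1, ref2):
        for feat in FEATURES:
            cols[f"{feat}_by_{ref}"] = features[feat] / features.loc[ref, feat]
    out = pd.DataFrame(cols, index=features.index)
    out.attrs["reference_types"] = (ref1, ref2)
    return out


def score_and_rank(normalized: pd.DataFrame,
                   reference: str | float | None = None) -> pd.DataFrame:
    """Add Sum, rank, and the candidate qualification flag.

    Sum is over all normalized columns with missing treated as 0; rank
    is descending by Sum (1 = highest).  A type qualifies iff its Sum
    strictly exceeds the reference Sum: 2 x the number of features
    defined for the references (12.0 when all six are defined), i.e.
    the Sum a reference scores when every normalized cell is exactly 1.
    ``reference`` may name a merged all-ones reference row (whose
    defined cells then set the cutoff) or give the cutoff directly;
    when omitted the reference types recorded by :func:`normalize` are
    used.
    """
    value_cols = [c for c in normalized.columns
                  if c not in ("Sum", "rank", "qualifies")]
    out = normalized[value_cols].copy()
    out["Sum"] = out[value_cols].fillna(0).sum(axis=1)
    if reference is None:
        refs = normalized.attrs.get("reference_types")
        if refs is None:
            raise AnalysisError(
                "no reference recorded in the table; pass reference= explicitly")
        # each defined reference cell contributes its ideal value, 1.0
        ref_sum = float(normalized.loc[refs[0], value_cols].notna().sum())
    elif isinstance(reference, str):
        if reference not in out.index:
            raise AnalysisError(f"reference row {reference!r} absent from table")
        ref_sum = float(normalized.loc[reference, value_cols].notna().sum())
    else:
        ref_sum = float(reference)
    order = out["Sum"].sort_values(ascending=False, kind="mergesort")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    out["rank"] = ranks.reindex(out.index).astype(int)
    out["qualifies"] = out["Sum"] > ref_sum
    out.attrs["reference_sum"] = ref_sum
    out.attrs["reference_types"] = normalized.attrs.get("reference_types")
    return out


def candidate_report(scored: pd.DataFrame) -> pd.DataFrame:
    """Qualifying cancer types in descending Sum order."""
    return scored.loc[scored["qualifies"]].sort_values("Sum", ascending=False)
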