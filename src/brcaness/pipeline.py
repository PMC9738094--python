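"""End-to-end driver: cohort bundle in, ranked candidate table out."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cnv as cnv_mod
from . import expression as expr_mod
from . import methylation as meth_mod
from . import score as score_mod
from . import survival as surv_mod
from . import variants as var_mod
from .cohort import CohortBundle
from .config import PipelineConfig
from .frequency import FrequencyMatrix


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    somatic_freq: FrequencyMatrix
    germline_freq: FrequencyMatrix
    plp_correlations: pd.DataFrame
    plp_summary: dict
    homdel_freq: FrequencyMatrix
    homdel_correlations: pd.DataFrame
    homdel_classification: pd.DataFrame
    probe_map: pd.DataFrame
    promoter_profile: meth_mod.PromoterProfile
    methylation_load: pd.DataFrame
    meth_expr_association: pd.DataFrame
    deg_results: pd.DataFrame
    deg_counts: pd.Series
    forest: pd.DataFrame
    risky_counts: pd.Series
    features: pd.DataFrame
    normalized: pd.DataFrame
    scored: pd.DataFrame
    candidates: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(bundle: CohortBundle, reference_types: tuple[str, str],
                 config: PipelineConfig | None = None,
                 with_association: bool = True) -> PipelineResult:
    """Run every stage on one cohort and score the cancer types.

    ``reference_types`` are the two cancer-type labels playing the role
    of the BRCA-like and OV-like references.
    """
    config = config or PipelineConfig()
    panel = bundle.panel
    tumors = bundle.tumor_samples()

    # --- pathogenic variants -------------------------------------------------
    filtered = var_mod.filter_variants(bundle.variants, config)
    matched = var_mod.match_plp(filtered, bundle.catalog, config)
    somatic = matched.loc[matched["origin"] == "somatic"]
    germline = matched.loc[matched["origin"] == "germline"]
    somatic_freq = var_mod.plp_frequency(somatic, tumors, panel.symbols)
    germline_freq = var_mod.plp_frequency(germline, tumors, panel.symbols)
    plp_corr = pd.concat([
        var_mod.correlate_plp(somatic_freq, panel,
                              threshold=config.plp_correlation_threshold).assign(origin="somatic"),
        var_mod.correlate_plp(germline_freq, panel,
                              threshold=config.plp_correlation_threshold).assign(origin="germline"),
    ], ignore_index=True)
    plp_summary = var_mod.summarize_plp(somatic, germline, n_types=tumors.nunique())

    # --- homozygous deletions ------------------------------------------------
    homdel_freq = cnv_mod.homdel_frequency(bundle.cnv, bundle.samples)
    homdel_corr = cnv_mod.correlate_homdel(
        homdel_freq, panel, threshold=config.homdel_correlation_threshold)
    homdel_cls = cnv_mod.classify_vs_references(homdel_freq, panel)

    # --- promoter methylation ------------------------------------------------
    probe_map = meth_mod.assign_promoter_probes(
        bundle.manifest, panel, window=config.tss_window)
    profile = meth_mod.promoter_means(
        bundle.methylation, probe_map, bundle.samples,
        cutoff=config.beta_hyper_cutoff)
    load = meth_mod.methylation_load(profile, panel)
    assoc = (meth_mod.methylation_expression_association(
                bundle.methylation, probe_map, bundle.expression, bundle.samples,
                threshold=config.meth_expr_correlation_threshold)
             if with_association else pd.DataFrame())

    # --- differential expression --------------------------------------------
    degs = expr_mod.call_degs(bundle.expression, bundle.sample_meta, panel, config)
    counts = expr_mod.deg_counts(degs, panel) if len(degs) else pd.Series(dtype=int)

    # --- survival ------------------------------------------------------------
    forest, risky = surv_mod.prognostic_screen(
        bundle.expression, bundle.clinical, panel, config)

    # --- composite score -----------------------------------------------------
    features = score_mod.assemble_features(
        somatic_freq, germline_freq, homdel_freq, load, counts, risky, panel)
    normalized = score_mod.normalize(features, *reference_types)
    scored = score_mod.score_and_rank(normalized)
    candidates = score_mod.candidate_report(scored)

    return PipelineResult(
        somatic_freq=somatic_freq, germline_freq=germline_freq,
        plp_correlations=plp_corr, plp_summary=plp_summary,
        homdel_freq=homdel_freq, homdel_correlations=homdel_corr,
        homdel_classification=homdel_cls, probe_map=probe_map,
        promoter_profile=profile, methylation_load=load,
        meth_expr_association=assoc, deg_results=degs, deg_counts=counts,
        forest=forest, risky_counts=risky, features=features,
        normalized=normalized, scored=scored, candidates=candidates,
    )
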