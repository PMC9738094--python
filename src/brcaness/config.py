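"""Run configuration: every threshold the pipeline applies, with defaults.

All thresholds live in one place so a run is fully described by a single
YAML file.  Defaults follow the published analysis choices: promoter
hypermethylation at mean beta > 0.3, differential expression at
BH-adjusted p < 0.01 with at least a two-fold change, survival screening
at log-rank p < 0.05, Pearson correlation cutoffs of 0.5 (pathogenic
variant frequencies, methylation-expression association) and 0.4
(homozygous-deletion frequencies), a promoter window of TSS +/- 10 kb,
and a minimum of 5 normal samples for a tumor-vs-normal comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import BrcanessError

#: MAF Variant_Classification values treated as non-silent (protein-affecting).
DEFAULT_NON_SILENT = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Splice_Site",
    "Translation_Start_Site",
)

#: Classifications recognized as silent/non-coding (excluded, not flagged).
KNOWN_SILENT = (
    "Silent",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "RNA",
    "IGR",
    "Splice_Region",
)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the BRCAness pipeline.

    Attributes
    ----------
    beta_hyper_cutoff : float
        Promoter hypermethylation call: mean promoter beta strictly
        greater than this value.
    deg_adjusted_p : float
        BH-adjusted p-value cutoff for a differentially expressed gene.
    deg_fold_change : float
        Minimum fold change (inclusive, linear scale) for a DEG.
    fold_change_scale : str
        ``"linear"`` computes fold change on linearized values
        ``2**x - 1``; ``"log2"`` uses the difference of log2 means.
    survival_alpha : float
        Two-sided log-rank significance level for the prognostic screen.
    plp_correlation_threshold : float
        |Pearson r| above which a pathogenic-variant frequency
        correlation with BRCA1/2 counts as significant.
    homdel_correlation_threshold : float
        Same for homozygous-deletion frequency correlations.
    meth_expr_correlation_threshold : float
        |Pearson r| at which promoter methylation is called silencing
        (r <= -t) or enhancing (r >= +t) for expression.
    tss_window : int
        Promoter half-width in bp: a probe belongs to a gene's promoter
        iff |pos - TSS| <= tss_window on the same chromosome.
    min_normals : int
        Minimum normal samples for a cancer type to enter the
        tumor-vs-normal expression comparison.
    risky_mode : str
        ``"any_significant"`` counts every gene with log-rank
        p < survival_alpha toward the prognosis feature;
        ``"hr_gt_1"`` counts only hazard ratios above 1.
    match_level : str
        ``"genomic"`` matches variants to the pathogenicity catalog on
        normalized (chrom, pos, ref, alt); ``"protein"`` matches on
        (gene, protein change) when both tables carry an ``HGVSp`` column.
    non_silent_classifications : tuple of str
        MAF classifications retained by the variant filter.
    stratify_linkage, stratify_metric : str
        Hierarchical-clustering parameters for 2-group patient
        stratification on panel expression.
    """

    beta_hyper_cutoff: float = 0.3
    deg_adjusted_p: float = 0.01
    deg_fold_change: float = 2.0
    fold_change_scale: str = "linear"
    survival_alpha: float = 0.05
    plp_correlation_threshold: float = 0.5
    homdel_correlation_threshold: float = 0.4
    meth_expr_correlation_threshold: float = 0.5
    tss_window: int = 10_000
    min_normals: int = 5
    risky_mode: str = "any_significant"
    match_level: str = "genomic"
    non_silent_classifications: tuple = field(default_factory=lambda: DEFAULT_NON_SILENT)
    stratify_linkage: str = "average"
    stratify_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.fold_change_scale not in ("linear", "log2"):
            raise BrcanessError(f"unknown fold_change_scale: {self.fold_change_scale!r}")
        if self.risky_mode not in ("any_significant", "hr_gt_1"):
            raise BrcanessError(f"unknown risky_mode: {self.risky_mode!r}")
        if self.match_level not in ("genomic", "protein"):
            raise BrcanessError(f"unknown match_level: {self.match_level!r}")
        self.non_silent_classifications = tuple(self.non_silent_classifications)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise BrcanessError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["non_silent_classifications"] = list(self.non_silent_classifications)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
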