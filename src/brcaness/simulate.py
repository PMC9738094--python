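"""Seeded synthetic pan-cancer cohorts with planted BRCAness structure.

The generator emulates the statistical shape of a TCGA-style
multi-omics cohort at toy scale so that every pipeline stage has a
known ground truth:

* PLP carriers drawn per gene and cancer type as independent Bernoulli
  draws at the planted carrier probability, each carrier receiving one
  catalog-matching variant; background non-PLP variants (silent and
  non-silent, some failing FILTER) exercise the filter logic;
* GISTIC codes with -2 at the planted homozygous-deletion probability
  and the remaining codes from a fixed background distribution;
* 450k-style promoter probes — at least 3 inside each gene's TSS window
  and one outside — with Gaussian jitter around the planted mean beta,
  clipped to [0.01, 0.99];
* tumor expression = per-gene normal baseline + planted log2 shift +
  noise; genes planted as methylation-silenced get an anti-correlated
  per-sample coupling between promoter beta and expression;
* overall survival exponential, with each tumor's rate multiplied by
  the planted hazard ratio of every gene whose expression in that
  sample exceeds the gene's within-type median, under independent
  uniform censoring (the true high-vs-low HR equals the rate ratio).

Identical design + seed gives byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortBundle, _build_sample_map
from .errors import DesignError
from .panel import GenePanel, load_default_panel

#: background distribution of non-(-2) GISTIC codes (-1, 0, 1, 2)
_CNV_BACKGROUND = np.array([0.05, 0.85, 0.07, 0.03])
#: promoter-probe offsets from the TSS: 4 inside a +/-10 kb window, 1 outside
_PROBE_OFFSETS = (-8000, -2500, 1500, 6000, 25000)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationDesign:
    """Planted per-gene, per-cancer-type parameters of a toy cohort.

    All planted matrices are gene x cancer-type DataFrames sharing the
    same index (panel symbols) and columns (cancer-type labels).
    """

    cancer_types: dict[str, int]            # label -> tumor sample count
    reference_types: tuple[str, str]
    n_normals: dict[str, int]
    plp_somatic: pd.DataFrame               # carrier probability
    plp_germline: pd.DataFrame              # carrier probability
    homdel: pd.DataFrame                    # probability of code -2
    meth_beta: pd.DataFrame                 # planted mean promoter beta
    expr_shift: pd.DataFrame                # log2 tumor-vs-normal shift
    hazard: pd.DataFrame                    # HR of high- vs low-expression
    seed: int
    probe_noise_sd: float = 0.05
    expr_noise_sd: float = 0.5
    background_variant_rate: float = 0.8    # Poisson mean per tumor sample
    baseline_hazard: float = 1.0 / 1000.0   # events per day in the low group
    censor_max_days: float = 2000.0
    silencing_beta_coupling: float = 0.08
    silencing_expr_coupling: float = 0.6
    meth_background: float = 0.15

    def __post_init__(self) -> None:
        for label, n in self.cancer_types.items():
            if n < 2:
                raise DesignError(f"cancer type {label!r} needs >= 2 samples, got {n}")
        for ref in self.reference_types:
            if ref not in self.cancer_types:
                raise DesignError(f"reference type {ref!r} not among cancer types")
        for name in ("plp_somatic", "plp_germline", "homdel"):
            m = getattr(self, name)
            if ((m < 0) | (m > 1)).any().any():
                raise DesignError(f"{name} probabilities must lie in [0, 1]")
        if ((self.meth_beta < 0) | (self.meth_beta > 1)).any().any():
            raise DesignError("planted betas must lie in [0, 1]")
        if (self.hazard <= 0).any().any():
            raise DesignError("planted hazards must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.plp_somatic.index)


@dataclass
class TruthRecord:
    """Ground truth of one generated cohort: the planted design plus the
    realized carrier counts per gene and cancer type."""

    design: SimulationDesign
    somatic_carriers: pd.DataFrame
    germline_carriers: pd.DataFrame
    homdel_carriers: pd.DataFrame
    silenced_pairs: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (gene, cancer_type, planted parameters)."""
        d = self.design
        rows = []
        for gene in d.genes:
            for ctype in d.cancer_types:
                rows.append(dict(
                    gene=gene, cancer_type=ctype,
                    plp_somatic=d.plp_somatic.loc[gene, ctype],
                    plp_germline=d.plp_germline.loc[gene, ctype],
                    homdel=d.homdel.loc[gene, ctype],
                    meth_beta=d.meth_beta.loc[gene, ctype],
                    expr_shift=d.expr_shift.loc[gene, ctype],
                    hazard=d.hazard.loc[gene, ctype],
                    somatic_carriers=self.somatic_carriers.loc[gene, ctype],
                    germline_carriers=self.germline_carriers.loc[gene, ctype],
                    homdel_carriers=self.homdel_carriers.loc[gene, ctype],
                ))
        return pd.DataFrame(rows)


def _matrix(genes: list[str], types: list[str], value: float) -> pd.DataFrame:
    return pd.DataFrame(value, index=pd.Index(genes, name="gene"), columns=list(types))


def null_design(n_types: int, n_per_type: int, seed: int,
                panel: GenePanel | None = None) -> SimulationDesign:
    """All-null design for calibration: uniform PLP background, no
    methylation or expression shifts, hazard 1 everywhere."""
    if n_per_type < 10:
        raise DesignError("null design requires n_per_type >= 10")
    if n_types < 2:
        raise DesignError("need at least 2 cancer types (for the references)")
    panel = panel or load_default_panel()
    genes = panel.symbols
    types = [f"T{i + 1:02d}" for i in range(n_types)]
    return SimulationDesign(
        cancer_types={t: n_per_type for t in types},
        reference_types=(types[0], types[1]),
        n_normals={t: 10 for t in types},
        plp_somatic=_matrix(genes, types, 0.02),
        plp_germline=_matrix(genes, types, 0.01),
        homdel=_matrix(genes, types, 0.005),
        meth_beta=_matrix(genes, types, 0.15),
        expr_shift=_matrix(genes, types, 0.0),
        hazard=_matrix(genes, types, 1.0),
        seed=seed,
    )


def default_design(seed: int, n_per_type: int = 120, n_normals: int = 12,
                   panel: GenePanel | None = None) -> SimulationDesign:
    """The stated world: 8 cancer types with planted BRCAness structure.

    Two reference types (BRCA-like, OV-like) carry moderate signal on a
    handful of genes; two "BRCAness-high" types carry stronger, broader
    signal; four background types carry weak signal.  Effect sizes are
    chosen so that each stage's estimator sees a realistic magnitude:
    carrier probabilities of a few percent up to 15%, hypermethylation
    betas of 0.4-0.5 against a 0.15 background, roughly two- to
    four-fold expression silencing, and hazard ratios of 2-2.5.
    """
    panel = panel or load_default_panel()
    genes = panel.symbols
    non_ref = panel.brcaness_genes
    types = ["BRCA_REF", "OV_REF", "HIGH1", "HIGH2", "BG1", "BG2", "BG3", "BG4"]
    plp_s = _matrix(genes, types, 0.005)
    plp_g = _matrix(genes, types, 0.002)
    homdel = _matrix(genes, types, 0.002)
    meth = _matrix(genes, types, 0.15)
    shift = _matrix(genes, types, 0.0)
    hazard = _matrix(genes, types, 1.0)
    for ref in ("BRCA_REF", "OV_REF"):
        plp_s.loc[non_ref[:6], ref] = 0.08
        plp_g.loc[non_ref[:4], ref] = 0.04
        plp_s.loc[["BRCA1", "BRCA2"], ref] = 0.10
        plp_g.loc[["BRCA1", "BRCA2"], ref] = 0.06
        homdel.loc[non_ref[:4], ref] = 0.01
        meth.loc[non_ref[:5], ref] = 0.40
        shift.loc[non_ref[:5], ref] = -1.5
        hazard.loc[non_ref[:4], ref] = 2.0
    for high in ("HIGH1", "HIGH2"):
        plp_s.loc[non_ref[:10], high] = 0.15
        plp_g.loc[non_ref[:8], high] = 0.08
        homdel.loc[non_ref[:6], high] = 0.02
        meth.loc[non_ref[:8], high] = 0.50
        shift.loc[non_ref[:8], high] = -2.0
        hazard.loc[non_ref[:8], high] = 2.5
    for bg in ("BG1", "BG2", "BG3", "BG4"):
        plp_s.loc[non_ref[:3], bg] = 0.02
        plp_g.loc[non_ref[:2], bg] = 0.01
    return SimulationDesign(
        cancer_types={t: n_per_type for t in types},
        reference_types=("BRCA_REF", "OV_REF"),
        n_normals={t: n_normals for t in types},
        plp_somatic=plp_s, plp_germline=plp_g, homdel=homdel,
        meth_beta=meth, expr_shift=shift, hazard=hazard, seed=seed,
    )


def _make_catalog(panel: GenePanel, rng: np.random.Generator) -> pd.DataFrame:
    """Three PLP catalog entries per panel gene, near its TSS."""
    tss = panel.tss()
    rows = []
    for i, gene in enumerate(panel.symbols):
        chrom, pos = tss.loc[gene, "tss_chrom"], int(tss.loc[gene, "tss_pos"])
        for k in range(3):
            ref_i = rng.integers(4)
            alt_i = (ref_i + 1 + rng.integers(3)) % 4
            source = "clinvar" if k < 2 else "cosmic"
            sig = ("Pathogenic" if k % 2 == 0 else "Likely pathogenic")
            if source == "cosmic":
                sig = "Pathogenic"
            rows.append(dict(
                chrom=chrom, pos=pos + 101 + 10 * k, ref=_BASES[ref_i],
                alt=_BASES[alt_i], gene=gene, clinical_significance=sig,
                source=source,
            ))
    return pd.DataFrame(rows)


def _draw_variants(design: SimulationDesign, panel: GenePanel,
                   catalog: pd.DataFrame, tumors: dict[str, list[str]],
                   rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """PLP carrier variants plus background non-PLP variants."""
    tss = panel.tss()
    cat_by_gene = {g: grp.reset_index(drop=True) for g, grp in catalog.groupby("gene")}
    rows = []
    carriers = {
        "somatic": _matrix(design.genes, list(design.cancer_types), 0).astype(int),
        "germline": _matrix(design.genes, list(design.cancer_types), 0).astype(int),
    }
    for origin, planted in (("somatic", design.plp_somatic),
                            ("germline", design.plp_germline)):
        for ctype, ids in tumors.items():
            for gene in design.genes:
                p = float(planted.loc[gene, ctype])
                hits = np.nonzero(rng.random(len(ids)) < p)[0]
                carriers[origin].loc[gene, ctype] = len(hits)
                entries = cat_by_gene[gene]
                for s in hits:
                    e = entries.iloc[int(rng.integers(len(entries)))]
                    rows.append((ids[s], gene, e["chrom"], int(e["pos"]),
                                 e["ref"], e["alt"], "Missense_Mutation",
                                 "PASS", origin))
    # background non-PLP variants: positions outside the catalog range,
    # classifications spanning silent and non-silent, some failing FILTER
    bg_classes = np.array(["Silent", "Missense_Mutation", "Intron",
                           "Nonsense_Mutation", "3'UTR"])
    for ctype, ids in tumors.items():
        counts = rng.poisson(design.background_variant_rate, len(ids))
        for sample, c in zip(ids, counts):
            for _ in range(int(c)):
                gene = design.genes[int(rng.integers(len(design.genes)))]
                chrom = tss.loc[gene, "tss_chrom"]
                pos = int(tss.loc[gene, "tss_pos"]) + 1000 + int(rng.integers(4000))
                ref_i = int(rng.integers(4))
                alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
                cls = bg_classes[int(rng.integers(len(bg_classes)))]
                filt = "PASS" if rng.random() > 0.1 else "artifact"
                rows.append((sample, gene, chrom, pos, _BASES[ref_i],
                             _BASES[alt_i], cls, filt, "somatic"))
    variants = pd.DataFrame(rows, columns=[
        "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
        "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
        "FILTER", "origin"])
    return variants, carriers["somatic"], carriers["germline"]


def generate(design: SimulationDesign,
             panel: GenePanel | None = None) -> tuple[CohortBundle, TruthRecord]:
    """Generate one cohort bundle plus its ground-truth record."""
    panel = panel or load_default_panel()
    if list(design.plp_somatic.index) != panel.symbols:
        raise DesignError("design gene index must equal the panel symbols")
    rng = np.random.default_rng(design.seed)
    types = list(design.cancer_types)
    tumors = {t: [f"{t}-T{i + 1:03d}" for i in range(design.cancer_types[t])]
              for t in types}
    normals = {t: [f"{t}-N{i + 1:03d}" for i in range(design.n_normals.get(t, 0))]
               for t in types}
    all_tumor_ids = [s for t in types for s in tumors[t]]

    catalog = _make_catalog(panel, rng)
    variants, som_car, germ_car = _draw_variants(design, panel, catalog, tumors, rng)

    # --- CNV ----------------------------------------------------------------
    cnv_cols = {}
    hom_car = _matrix(design.genes, types, 0).astype(int)
    other_codes = np.array([-1, 0, 1, 2])
    for ctype in types:
        n = len(tumors[ctype])
        p_hom = design.homdel[ctype].to_numpy()[:, None]
        is_hom = rng.random((len(design.genes), n)) < p_hom
        backgrounds = other_codes[rng.choice(4, size=(len(design.genes), n),
                                             p=_CNV_BACKGROUND)]
        codes = np.where(is_hom, -2, backgrounds)
        hom_car[ctype] = is_hom.sum(axis=1)
        for j, s in enumerate(tumors[ctype]):
            cnv_cols[s] = codes[:, j]
    cnv = pd.DataFrame(cnv_cols, index=pd.Index(design.genes, name="gene"))

    # --- methylation + expression (coupled for silenced genes) --------------
    tss = panel.tss()
    probe_ids, man_rows = [], []
    for gene in design.genes:
        for k, off in enumerate(_PROBE_OFFSETS):
            pid = f"cg_{gene}_{k}"
            probe_ids.append(pid)
            man_rows.append((pid, tss.loc[gene, "tss_chrom"],
                             int(tss.loc[gene, "tss_pos"]) + off))
    manifest = pd.DataFrame(man_rows, columns=["probe", "chrom", "pos"]).set_index("probe")

    baseline = pd.Series(6.0 + 4.0 * rng.random(len(design.genes)),
                         index=design.genes)
    probe_jitter = pd.Series(rng.normal(0.0, 0.02, len(probe_ids)), index=probe_ids)

    meth = pd.DataFrame(index=pd.Index(probe_ids, name="probe"),
                        columns=all_tumor_ids, dtype=float)
    expr_cols: dict[str, np.ndarray] = {}
    silenced_pairs = []
    for ctype in types:
        t_ids, n_ids = tumors[ctype], normals[ctype]
        n_t = len(t_ids)
        expr_t = (baseline.to_numpy()[:, None]
                  + design.expr_shift[ctype].to_numpy()[:, None]
                  + rng.normal(0.0, design.expr_noise_sd, (len(design.genes), n_t)))
        beta_block = np.empty((len(probe_ids), n_t))
        for gi, gene in enumerate(design.genes):
            base = float(design.meth_beta.loc[gene, ctype])
            silenced = (base > design.meth_background + 0.05
                        and design.expr_shift.loc[gene, ctype] < 0)
            u = rng.normal(0.0, 1.0, n_t) if silenced else np.zeros(n_t)
            if silenced:
                silenced_pairs.append((gene, ctype))
                expr_t[gi] -= design.silencing_expr_coupling * u
            for k in range(len(_PROBE_OFFSETS)):
                pid = f"cg_{gene}_{k}"
                pi = gi * len(_PROBE_OFFSETS) + k
                level = 0.5 if k == len(_PROBE_OFFSETS) - 1 else base
                beta_block[pi] = (level + probe_jitter[pid]
                                  + design.silencing_beta_coupling * u
                                  + rng.normal(0.0, design.probe_noise_sd, n_t))
        meth.loc[:, t_ids] = np.clip(beta_block, 0.01, 0.99)
        expr_cols.update({s: expr_t[:, j] for j, s in enumerate(t_ids)})
        if n_ids:
            expr_n = (baseline.to_numpy()[:, None]
                      + rng.normal(0.0, design.expr_noise_sd,
                                   (len(design.genes), len(n_ids))))
            expr_cols.update({s: expr_n[:, j] for j, s in enumerate(n_ids)})
    expression = pd.DataFrame(expr_cols, index=pd.Index(design.genes, name="gene"))

    # --- survival ------------------------------------------------------------
    clin_rows = []
    for ctype in types:
        t_ids = tumors[ctype]
        block = expression[t_ids]
        medians = block.median(axis=1)
        log_mult = np.zeros(len(t_ids))
        hz = design.hazard[ctype]
        for gene in design.genes:
            h = float(hz.loc[gene])
            if h != 1.0:
                above = (block.loc[gene] > medians.loc[gene]).to_numpy()
                log_mult = log_mult + np.log(h) * above
        rate = design.baseline_hazard * np.exp(log_mult)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.uniform(0.0, design.censor_max_days, len(t_ids))
        os_days = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        for s, d, e in zip(t_ids, os_days, event):
            clin_rows.append((s, ctype, round(float(d), 2), int(e)))
    clinical = pd.DataFrame(clin_rows, columns=["sample", "cancer_type",
                                                "os_days", "os_event"])

    meta_rows = ([(s, t, "tumor") for t in types for s in tumors[t]]
                 + [(s, t, "normal") for t in types for s in normals[t]])
    sample_meta = pd.DataFrame(meta_rows, columns=["sample", "cancer_type",
                                                   "sample_type"])

    variants = variants.copy()
    panel_upper = {s.upper() for s in panel.symbols}
    variants["in_panel"] = variants["Hugo_Symbol"].str.upper().isin(panel_upper)

    bundle = CohortBundle(
        variants=variants, catalog=catalog, cnv=cnv, methylation=meth,
        manifest=manifest, expression=expression, sample_meta=sample_meta,
        clinical=clinical, samples=_build_sample_map(clinical, sample_meta),
        panel=panel,
    )
    bundle.validate()
    truth = TruthRecord(design=design, somatic_carriers=som_car,
                        germline_carriers=germ_car, homdel_carriers=hom_car,
                        silenced_pairs=silenced_pairs)
    return bundle, truth


def with_seed(design: SimulationDesign, seed: int) -> SimulationDesign:
    """Copy of a design with a different seed."""
    return replace(design, seed=seed)
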