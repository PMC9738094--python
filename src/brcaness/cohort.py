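"""Cohort I/O: strict readers/writers for every table the pipeline touches.

All on-disk formats are plain tab-delimited text:

* variants — MAF-dialect TSV with at least ``Hugo_Symbol``, ``Chromosome``,
  ``Start_Position`` (1-based, fully closed, as in MAF),
  ``Reference_Allele``, ``Tumor_Seq_Allele2``, ``Variant_Classification``,
  ``FILTER``, ``Tumor_Sample_Barcode`` and an ``origin`` column
  (``somatic``/``germline``);
* catalog — pathogenicity catalog with ``chrom``, ``pos`` (1-based),
  ``ref``, ``alt``, ``gene``, ``clinical_significance``, ``source``;
* cnv — gene x sample integer GISTIC codes in {-2..2};
* methylation — probe x sample beta matrix plus a probe manifest
  (``probe``, ``chrom``, ``pos``, 1-based);
* expression — gene x sample log2(norm+1) matrix plus a sample-metadata
  table (``sample``, ``cancer_type``, ``sample_type`` tumor/normal);
* clinical — ``sample``, ``cancer_type``, ``os_days``, ``os_event``.

Loaders never silently drop rows: rows for genes outside the panel are
retained and flagged (``in_panel``), and accepted/flagged counts are
logged.  Cancer-type labels are free strings; nothing in the pipeline
hard-codes a particular cohort's label set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortFormatError, CohortValidationError
from .panel import GenePanel

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = (
    "Tumor_Sample_Barcode", "Hugo_Symbol", "Chromosome", "Start_Position",
    "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Classification",
    "FILTER", "origin",
)
CATALOG_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "clinical_significance", "source")
CLINICAL_COLUMNS = ("sample", "cancer_type", "os_days", "os_event")
SAMPLE_META_COLUMNS = ("sample", "cancer_type", "sample_type")
MANIFEST_COLUMNS = ("probe", "chrom", "pos")

#: catalog entries allowed per source (ClinVar-style P/LP, COSMIC Pathogenic)
CATALOG_ALLOWED = {
    "clinvar": {"Pathogenic", "Likely pathogenic"},
    "cosmic": {"Pathogenic"},
}


def _read_tsv(path: str | Path, required: tuple[str, ...], name: str) -> pd.DataFrame:
    try:
        # round_trip float parsing: write/read must be an exact identity
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                         dtype={c: str for c in ("chrom", "Chromosome")})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise CohortFormatError(f"{path}: cannot parse {name} table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: {name} table missing column(s) {missing}")
    return df


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a MAF-dialect variant table (coordinates 1-based, closed)."""
    df = _read_tsv(path, VARIANT_COLUMNS, "variant")
    if len(df):
        df["Start_Position"] = df["Start_Position"].astype(int)
        bad = df["origin"].loc[~df["origin"].isin(["somatic", "germline"])]
        if len(bad):
            raise CohortValidationError(
                f"{path}: origin must be somatic/germline, got {sorted(bad.unique())}"
            )
        same = df["Reference_Allele"] == df["Tumor_Seq_Allele2"]
        if same.any():
            raise CohortValidationError(
                f"{path}: {int(same.sum())} rows with ref == alt allele"
            )
    return df


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a pathogenicity catalog; entries restricted to P/LP labels."""
    df = _read_tsv(path, CATALOG_COLUMNS, "catalog")
    if len(df):
        df["pos"] = df["pos"].astype(int)
        for source, allowed in CATALOG_ALLOWED.items():
            sub = df.loc[df["source"] == source, "clinical_significance"]
            bad = sorted(set(sub) - allowed)
            if bad:
                raise CohortValidationError(
                    f"{path}: {source} catalog entries with disallowed significance {bad}"
                )
        unknown = sorted(set(df["source"]) - set(CATALOG_ALLOWED))
        if unknown:
            raise CohortValidationError(f"{path}: unknown catalog source(s) {unknown}")
        dup = df.duplicated(["source", "chrom", "pos", "ref", "alt"])
        if dup.any():
            raise CohortValidationError(
                f"{path}: {int(dup.sum())} duplicate (source, chrom, pos, ref, alt) keys"
            )
    return df


def _read_matrix(path: str | Path, index_name: str, name: str) -> pd.DataFrame:
    df = _read_tsv(path, (index_name,), name)
    df = df.set_index(index_name)
    df.columns = [str(c) for c in df.columns]
    return df


def read_cnv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample GISTIC-coded copy-number matrix."""
    df = _read_matrix(path, "gene", "cnv")
    vals = df.to_numpy()
    if len(df) and not np.isin(vals, [-2, -1, 0, 1, 2]).all():
        raise CohortValidationError(f"{path}: CNV codes outside {{-2..2}}")
    return df.astype(int)


def read_methylation(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample beta matrix (values in [0, 1])."""
    df = _read_matrix(path, "probe", "methylation").astype(float)
    if len(df):
        vals = df.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise CohortValidationError(f"{path}: beta values outside [0, 1]")
    return df

def read_manifest(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, MANIFEST_COLUMNS, "manifest")
    if len(df):
        df["pos"] = df["pos"].astype(int)
    return df.set_index("probe")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample log2(norm+1) expression matrix."""
    df = _read_matrix(path, "gene", "expression").astype(float)
    if len(df) and not np.isfinite(df.to_numpy()).all():
        raise CohortValidationError(f"{path}: non-finite expression values")
    return df


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, SAMPLE_META_COLUMNS, "sample metadata")
    bad = sorted(set(df["sample_type"]) - {"tumor", "normal"})
    if bad:
        raise CohortValidationError(f"{path}: sample_type must be tumor/normal, got {bad}")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, CLINICAL_COLUMNS, "clinical")
    if len(df):
        df["os_days"] = df["os_days"].astype(float)
        df["os_event"] = df["os_event"].astype(int)
        if (df["os_days"] < 0).any():
            raise CohortValidationError(f"{path}: negative os_days")
        if not df["os_event"].isin([0, 1]).all():
            raise CohortValidationError(f"{path}: os_event must be 0/1")
    return df


@dataclass
class CohortPaths:
    """File locations of one cohort on disk."""

    variants: Path
    catalog: Path
    cnv: Path
    methylation: Path
    manifest: Path
    expression: Path
    sample_meta: Path
    clinical: Path

    @classmethod
    def in_dir(cls, directory: str | Path) -> "CohortPaths":
        d = Path(directory)
        return cls(**{f.name: d / f"{f.name}.tsv" for f in fields(cls)})


@dataclass
class CohortBundle:
    """All per-sample omics and clinical tables of one cohort.

    ``samples`` maps every sample ID to its cancer-type label and is the
    union of the clinical table and the expression sample metadata; every
    sample referenced by an omics table must appear in it.
    """

    variants: pd.DataFrame
    catalog: pd.DataFrame
    cnv: pd.DataFrame
    methylation: pd.DataFrame
    manifest: pd.DataFrame
    expression: pd.DataFrame
    sample_meta: pd.DataFrame
    clinical: pd.DataFrame
    samples: pd.Series
    panel: GenePanel

    def validate(self) -> None:
        """Check referential integrity across all tables."""
        known = set(self.samples.index)
        checks = {
            "variants": set(self.variants["Tumor_Sample_Barcode"]) if len(self.variants) else set(),
            "cnv": set(self.cnv.columns),
            "methylation": set(self.methylation.columns),
            "expression": set(self.expression.columns),
            "clinical": set(self.clinical["sample"]) if len(self.clinical) else set(),
        }
        for name, ids in checks.items():
            unknown = sorted(ids - known)
            if unknown:
                raise CohortValidationError(
                    f"{name} table references samples absent from the sample map: "
                    f"{unknown[:10]}{'...' if len(unknown) > 10 else ''}"
                )
        orphan = sorted(set(self.methylation.index) - set(self.manifest.index))
        if orphan:
            raise CohortValidationError(
                f"methylation probes missing from manifest: {orphan[:10]}"
            )

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.samples.unique())

    def tumor_samples(self) -> pd.Series:
        """sample -> cancer type restricted to tumor samples."""
        tumors = self.sample_meta.loc[self.sample_meta["sample_type"] == "tumor", "sample"]
        return self.samples.loc[self.samples.index.intersection(tumors)]


def _build_sample_map(clinical: pd.DataFrame, sample_meta: pd.DataFrame) -> pd.Series:
    parts = []
    if len(clinical):
        parts.append(clinical.set_index("sample")["cancer_type"])
    if len(sample_meta):
        parts.append(sample_meta.set_index("sample")["cancer_type"])
    if not parts:
        raise CohortValidationError("no samples in clinical or sample-metadata tables")
    merged = pd.concat(parts)
    conflict = merged.groupby(level=0).nunique()
    bad = sorted(conflict.index[conflict > 1])
    if bad:
        raise CohortValidationError(f"conflicting cancer-type labels for samples {bad[:10]}")
    return merged[~merged.index.duplicated()].rename("cancer_type")


def load_cohort(paths: CohortPaths, panel: GenePanel) -> CohortBundle:
    """Load and validate a full cohort from disk.

    Variant rows whose gene lies outside the panel are retained but
    flagged (``in_panel = False``); counts are logged so that
    input rows = accepted + flagged always holds.
    """
    variants = read_variants(paths.variants)
    catalog = read_catalog(paths.catalog)
    cnv = read_cnv(paths.cnv)
    methylation = read_methylation(paths.methylation)
    manifest = read_manifest(paths.manifest)
    expression = read_expression(paths.expression)
    sample_meta = read_sample_meta(paths.sample_meta)
    clinical = read_clinical(paths.clinical)

    panel_upper = {s.upper() for s in panel.symbols}
    variants = variants.copy()
    variants["in_panel"] = (
        variants["Hugo_Symbol"].astype(str).str.upper().isin(panel_upper)
        if len(variants) else pd.Series(dtype=bool)
    )
    n_flagged = int((~variants["in_panel"]).sum()) if len(variants) else 0
    logger.info(
        "loaded %d variant rows: %d in panel, %d flagged off-panel",
        len(variants), len(variants) - n_flagged, n_flagged,
    )

    bundle = CohortBundle(
        variants=variants, catalog=catalog, cnv=cnv,
        methylation=methylation, manifest=manifest, expression=expression,
        sample_meta=sample_meta, clinical=clinical,
        samples=_build_sample_map(clinical, sample_meta), panel=panel,
    )
    bundle.validate()
    return bundle


def write_cohort(bundle: CohortBundle, directory: str | Path) -> CohortPaths:
    """Write every table of a bundle as TSV files under ``directory``."""
    paths = CohortPaths.in_dir(directory)
    Path(directory).mkdir(parents=True, exist_ok=True)
    bundle.variants.drop(columns=["in_panel"], errors="ignore").to_csv(
        paths.variants, sep="\t", index=False)
    bundle.catalog.to_csv(paths.catalog, sep="\t", index=False)
    bundle.cnv.to_csv(paths.cnv, sep="\t", index_label="gene")
    # %.17g guarantees exact float round trips
    bundle.methylation.to_csv(paths.methylation, sep="\t", index_label="probe",
                              float_format="%.17g")
    bundle.manifest.to_csv(paths.manifest, sep="\t", index_label="probe")
    bundle.expression.to_csv(paths.expression, sep="\t", index_label="gene",
                             float_format="%.17g")
    bundle.sample_meta.to_csv(paths.sample_meta, sep="\t", index=False)
    bundle.clinical.to_csv(paths.clinical, sep="\t", index=False)
    return paths


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a normalized score table as TSV, missing cells as ``-``.

    One row per cancer type; the 12 normalized feature columns plus Sum,
    rank and qualifies are written as-is, with NaN rendered ``-``.
    """
    out = table.copy()
    out.to_csv(path, sep="\t", index_label="cancer_type", na_rep="-",
               float_format="%.6g")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_score_table`."""
    df = pd.read_csv(path, sep="\t", na_values=["-"], index_col="cancer_type",
                     float_precision="round_trip")
    for col in df.columns:
        if col == "rank":
            df[col] = df[col].astype(int)
        elif col == "qualifies":
            df[col] = df[col].astype(bool)
        else:
            df[col] = df[col].astype(float)
    return df
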