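"""Gene panel: the curated BRCAness genes plus the BRCA1/2 references.

The default panel carries the 40 literature-curated BRCAness genes
(homologous-recombination and HR-adjacent genes whose defects phenocopy
BRCA1/2 loss) together with BRCA1 and BRCA2, which serve as gene-level
references throughout the pipeline.  Each gene carries a TSS coordinate
used to define its promoter window for methylation analysis.

Coordinates are 1-based and the packaged table declares its genome build
in a header comment (GRCh38); a custom panel can be supplied through
:func:`read_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import CohortFormatError, CohortValidationError

_REQUIRED = ("symbol", "is_reference", "tss_chrom", "tss_pos")


@dataclass(frozen=True)
class GenePanel:
    """An immutable gene panel.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``symbol`` (str), ``is_reference`` (bool), ``tss_chrom``
        (str), ``tss_pos`` (int, 1-based).  Exactly two reference genes
        are required and symbols must be unique (case-insensitively).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.table.columns]
        if missing:
            raise CohortFormatError(f"panel table missing columns: {missing}")
        t = self.table.copy()
        t["symbol"] = t["symbol"].astype(str)
        t["is_reference"] = t["is_reference"].astype(bool)
        t["tss_pos"] = t["tss_pos"].astype(int)
        upper = t["symbol"].str.upper()
        if upper.duplicated().any():
            dups = sorted(upper[upper.duplicated()].unique())
            raise CohortValidationError(f"duplicate panel symbols: {dups}")
        if int(t["is_reference"].sum()) != 2:
            raise CohortValidationError(
                f"panel must have exactly 2 reference genes, got {int(t['is_reference'].sum())}"
            )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def symbols(self) -> list[str]:
        """All panel gene symbols, references included."""
        return list(self.table["symbol"])

    @property
    def reference_genes(self) -> list[str]:
        """The two reference symbols (BRCA1, BRCA2 in the default panel)."""
        return list(self.table.loc[self.table["is_reference"], "symbol"])

    @property
    def brcaness_genes(self) -> list[str]:
        """The non-reference (BRCAness) symbols."""
        return list(self.table.loc[~self.table["is_reference"], "symbol"])

    def tss(self) -> pd.DataFrame:
        """TSS coordinates indexed by symbol (columns tss_chrom, tss_pos)."""
        return self.table.set_index("symbol")[["tss_chrom", "tss_pos"]]

    def contains(self, symbol: str) -> bool:
        """Case-insensitive membership test."""
        return symbol.upper() in set(s.upper() for s in self.symbols)

    def __len__(self) -> int:
        return len(self.table)


def read_panel(path: str | Path) -> GenePanel:
    """Read a panel from a tab-delimited table (``#`` lines are comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: panel file missing columns {missing}")
    return GenePanel(df)


def load_default_panel() -> GenePanel:
    """Load the packaged default panel: 40 BRCAness genes + BRCA1/2."""
    ref = resources.files("brcaness.data").joinpath("default_panel.tsv")
    with resources.as_file(ref) as path:
        return read_panel(path)
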