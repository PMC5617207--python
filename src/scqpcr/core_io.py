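"""Data model and I/O for targeted single-cell panel-qPCR experiments.

A panel experiment measures a fixed set of genes (here typically 48 TaqMan
assays on a microfluidic dynamic array) in FACS-sorted single cells plus
sorted fluorescent beads that serve as negative controls for ambient-RNA
contamination.  Raw output is a cells x genes matrix of cycle-threshold (Ct)
values.  Ct is inversely related to transcript abundance, so the working
scale everywhere downstream is the inverted value ``ceiling - Ct`` (default
ceiling 35 cycles), a log2-like expression scale on which 0 means
"not detected before the informative cycle ceiling".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "SAMPLE_TYPES",
    "GenePanelEntry",
    "CellMeta",
    "CtMatrix",
    "ExpressionMatrix",
    "AnalysisConfig",
    "read_ct_table",
    "invert_ct",
    "expression_to_ct",
    "write_expression_table",
    "read_expression_table",
]

#: Closed set of functional categories a panel gene may carry.
CATEGORIES = frozenset(
    {
        "housekeeping",
        "neuronal_marker",
        "glial_marker",
        "neuropeptide",
        "transmitter_component",
        "receptor",
        "transcription_factor",
        "calcium_binding",
        "other",
    }
)

SAMPLE_TYPES = frozenset({"cell", "bead"})


@dataclass(frozen=True)
class GenePanelEntry:
    """One assay in the gene panel."""

    symbol: str
    category: str = "other"
    assay_id: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for gene {self.symbol!r}; "
                f"expected one of {sorted(CATEGORIES)}"
            )


@dataclass(frozen=True)
class CellMeta:
    """Metadata for one sorted sample (a cell or a negative-control bead)."""

    cell_id: str
    population: str
    batch: str = ""
    sample_type: str = "cell"

    def __post_init__(self) -> None:
        if not self.cell_id:
            raise ValueError("cell_id must be non-empty")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(
                f"sample_type {self.sample_type!r} not in {sorted(SAMPLE_TYPES)}"
            )


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind}: {i!r}")
        seen.add(i)


@dataclass
class _PanelMatrix:
    """Shared shape/metadata validation for Ct and expression matrices."""

    values: np.ndarray
    cells: list[CellMeta]
    genes: list[GenePanelEntry]
    ceiling: float = 35.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.ceiling <= 0:
            raise ValueError("ceiling must be positive")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x genes array")
        if self.values.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        _check_unique([c.cell_id for c in self.cells], "cell_id")
        _check_unique([g.symbol for g in self.genes], "gene symbol")

    # -- convenience accessors used throughout the pipeline ---------------
    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def gene_index(self, symbol: str) -> int:
        try:
            return self.gene_symbols.index(symbol)
        except ValueError:
            raise KeyError(f"gene {symbol!r} not in panel") from None

    def population_mask(self, population: str, sample_type: str = "cell") -> np.ndarray:
        return np.array(
            [
                c.population == population and c.sample_type == sample_type
                for c in self.cells
            ]
        )

    def sample_type_mask(self, sample_type: str) -> np.ndarray:
        return np.array([c.sample_type == sample_type for c in self.cells])

    def subset_cells(self, keep: Sequence[str] | np.ndarray):
        """Return a copy restricted to the given cell ids (or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            mask = keep
        else:
            wanted = set(keep)
            mask = np.array([c.cell_id in wanted for c in self.cells])
        return replace(
            self,
            values=self.values[mask].copy(),
            cells=[c for c, m in zip(self.cells, mask) if m],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.cell_ids, name="cell_id"),
            columns=self.gene_symbols,
        )


@dataclass
class CtMatrix(_PanelMatrix):
    """Raw cycle-threshold values.

    Missing entries (NaN) and values at or above ``ceiling`` (including
    instrument no-call sentinels such as 999) all encode "not detected".
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        finite = self.values[~np.isnan(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative Ct values are physically impossible")


@dataclass
class ExpressionMatrix(_PanelMatrix):
    """Inverted-Ct expression on a log2-like scale, in ``[0, ceiling]``.

    0 means the transcript was not detected in that cell; any positive value
    means detected, with magnitude ``ceiling - Ct``.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.isnan(self.values).any():
            raise ValueError("expression values must be finite")
        if (self.values < 0).any() or (self.values > self.ceiling).any():
            raise ValueError(f"expression values must lie in [0, {self.ceiling}]")


@dataclass
class AnalysisConfig:
    """Panel-wide constants of the analysis.

    ceiling            maximum informative cycle count (cycles)
    housekeeping_gene  gene used for the cDNA-yield prescreen
    ci_level           coverage level of the housekeeping outlier interval
    alpha              per-test significance level
    fdr_q              Benjamini-Hochberg false-discovery-rate level
    power_reps         Monte Carlo replicates for the power analysis
    effect_levels      detection-probability differences probed by the
                       power analysis
    """

    ceiling: float = 35.0
    housekeeping_gene: str = "Gapdh"
    ci_level: float = 0.95
    alpha: float = 0.05
    fdr_q: float = 0.05
    power_reps: int = 1000
    effect_levels: tuple[float, ...] = (0.0, 0.15, 0.25, 0.35)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.power_reps < 1:
            raise ValueError("power_reps must be >= 1")


# ---------------------------------------------------------------------------
# delimited-table I/O
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV with the delimiter sniffed from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing keeps write->read bit-identical for repr'd floats
    return pd.read_csv(path, sep=sep, dtype={0: str},
                       float_precision="round_trip")


def read_panel_table(path: str | Path) -> list[GenePanelEntry]:
    """Read a panel annotation table with columns symbol, category, assay_id."""
    df = _read_delimited(path)
    required = {"symbol", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel table {path} must have columns {sorted(required)}")
    if "assay_id" not in df.columns:
        df["assay_id"] = ""
    return [
        GenePanelEntry(str(r.symbol), str(r.category), str(r.assay_id))
        for r in df.itertuples()
    ]


def read_meta_table(path: str | Path) -> dict[str, CellMeta]:
    df = _read_delimited(path)
    required = {"cell_id", "population", "batch", "sample_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata table {path} must have columns {sorted(required)}")
    metas = [
        CellMeta(str(r.cell_id), str(r.population), str(r.batch), str(r.sample_type))
        for r in df.itertuples()
    ]
    _check_unique([m.cell_id for m in metas], "cell_id")
    return {m.cell_id: m for m in metas}


def read_ct_table(
    path: str | Path,
    meta_path: str | Path,
    panel_path: str | Path,
    ceiling: float = 35.0,
) -> CtMatrix:
    """Assemble a validated :class:`CtMatrix` from three delimited files.

    The Ct table has ``cell_id`` as its first column and one column per gene
    symbol; empty entries are treated as missing (non-detected).  Cell order
    follows the Ct file, gene order follows the panel file.
    """
    panel = read_panel_table(panel_path)
    meta = read_meta_table(meta_path)

    df = _read_delimited(path)
    if df.columns[0] != "cell_id":
        raise ValueError(f"Ct table {path}: first column must be 'cell_id', "
                         f"got {df.columns[0]!r}")
    ids = [str(i) for i in df["cell_id"]]
    _check_unique(ids, "cell_id")

    panel_symbols = [g.symbol for g in panel]
    missing_cols = sorted(set(panel_symbols) - set(df.columns))
    if missing_cols:
        raise ValueError(f"Ct table {path}: missing gene columns {missing_cols}")

    unknown = sorted(set(ids) - set(meta))
    if unknown:
        raise ValueError(f"Ct table {path}: cells missing from metadata: {unknown}")

    values = df[panel_symbols].to_numpy(dtype=float)
    cells = [meta[i] for i in ids]
    return CtMatrix(values=values, cells=cells, genes=panel, ceiling=ceiling)


def invert_ct(ct: CtMatrix) -> ExpressionMatrix:
    """Map Ct to the inverted log2-like expression scale.

    Each entry becomes ``max(0, ceiling - Ct)``; missing values and any Ct at
    or above the ceiling (no-call sentinels included) become 0.  Metadata is
    carried through unchanged.
    """
    v = ct.values
    finite = v[~np.isnan(v)]
    if finite.size and finite.min() < 0:
        raise ValueError("negative Ct values are physically impossible")
    expr = ct.ceiling - v
    expr = np.where(np.isnan(v) | (expr < 0), 0.0, expr)
    return ExpressionMatrix(
        values=expr, cells=list(ct.cells), genes=list(ct.genes), ceiling=ct.ceiling
    )


def expression_to_ct(x: ExpressionMatrix) -> CtMatrix:
    """Inverse transform: detected entries map back to ``ceiling - value``,
    non-detected entries to missing (NaN)."""
    v = np.where(x.values > 0, x.ceiling - x.values, np.nan)
    return CtMatrix(values=v, cells=list(x.cells), genes=list(x.genes),
                    ceiling=x.ceiling)


def write_expression_table(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that round-trips bit-identically through
    :func:`read_expression_table` (floats serialized via repr)."""
    x.to_dataframe().to_csv(path, sep="\t")


def write_meta_table(cells: Sequence[CellMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "population": [c.population for c in cells],
            "batch": [c.batch for c in cells],
            "sample_type": [c.sample_type for c in cells],
        }
    ).to_csv(path, sep="\t", index=False)


def write_panel_table(genes: Sequence[GenePanelEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "symbol": [g.symbol for g in genes],
            "category": [g.category for g in genes],
            "assay_id": [g.assay_id for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def write_ct_table(ct: CtMatrix, path: str | Path) -> None:
    ct.to_dataframe().to_csv(path, sep="\t")


def read_expression_table(
    path: str | Path,
    meta_path: str | Path,
    panel_path: str | Path,
    ceiling: float = 35.0,
) -> ExpressionMatrix:
    """Read back a table written by :func:`write_expression_table`."""
    ct_like = read_ct_table(path, meta_path, panel_path, ceiling=np.inf)
    return ExpressionMatrix(
        values=np.nan_to_num(ct_like.values, nan=0.0),
        cells=ct_like.cells,
        genes=ct_like.genes,
        ceiling=ceiling,
    )
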