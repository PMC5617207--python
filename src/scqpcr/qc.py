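"""Cell-level quality control preceding all statistics.

Three screens are applied to sorted samples before any inference:

* a housekeeping prescreen that removes cells with no or outlying
  housekeeping-gene signal (low/failed cDNA yield),
* an identity gate that removes cells of a labeled population lacking their
  defining transcript (e.g. a sorted Hcrt/Ox cell with no Hcrt signal),
* a negative-control report listing every gene detected in sorted beads,
  which measures ambient-transcript contamination of the FACS droplet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix

__all__ = [
    "QCReport",
    "housekeeping_prescreen",
    "identity_gate",
    "bead_contamination_report",
    "marker_summary",
    "apply_report",
]


@dataclass
class QCReport:
    """Outcome of one QC screen.

    ``kept_ids`` and ``dropped`` partition the input samples; each dropped
    entry records the rule that removed it.  ``interval`` holds the
    housekeeping acceptance interval when applicable, ``bead_detections``
    maps bead id -> detected gene symbols for the contamination report.
    """

    kept_ids: list[str]
    dropped: list[tuple[str, str]] = field(default_factory=list)
    interval: tuple[float, float] | None = None
    bead_detections: dict[str, list[str]] | None = None

    @property
    def dropped_ids(self) -> list[str]:
        return [cid for cid, _ in self.dropped]

    @property
    def n_contaminated_beads(self) -> int:
        if self.bead_detections is None:
            return 0
        return sum(1 for genes in self.bead_detections.values() if genes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kept_ids": self.kept_ids,
            "dropped": [list(d) for d in self.dropped],
            "interval": list(self.interval) if self.interval else None,
            "bead_detections": self.bead_detections,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def apply_report(x: ExpressionMatrix, report: QCReport) -> ExpressionMatrix:
    """Subset the matrix to the cells a QC report kept."""
    return x.subset_cells(report.kept_ids)


def housekeeping_prescreen(
    x: ExpressionMatrix,
    gene: str = "Gapdh",
    ci_level: float = 0.95,
    method: str = "normal",
) -> QCReport:
    """Drop cells with absent or outlying housekeeping expression.

    Cells (``sample_type == "cell"``) with zero expression of ``gene`` are
    dropped with reason ``"absent"``.  Over the remaining expressing cells an
    acceptance interval is computed and cells outside it are dropped with
    reason ``"outlier"`` (closed interval: boundary cells are kept).

    method="normal" (default) uses the normal coverage interval
    ``mean +/- z * SD`` with the two-sided standard-normal quantile ``z`` for
    ``ci_level`` and the n-1 sample SD; method="quantile" uses the empirical
    central ``ci_level`` quantile interval instead.  Beads are ignored by
    this screen and always kept.
    """
    gi = x.gene_index(gene)
    is_cell = x.sample_type_mask("cell")
    expr = x.values[:, gi]

    absent = is_cell & (expr <= 0)
    expressing = is_cell & (expr > 0)
    vals = expr[expressing]
    if vals.size < 2:
        raise ValueError(
            f"housekeeping prescreen needs >= 2 cells expressing {gene!r}, "
            f"got {vals.size}"
        )

    if method == "normal":
        z = stats.norm.ppf(0.5 + ci_level / 2)
        m = float(np.mean(vals))
        s = float(np.std(vals, ddof=1))
        lo, hi = m - z * s, m + z * s
    elif method == "quantile":
        tail = (1 - ci_level) / 2
        lo, hi = (float(q) for q in np.quantile(vals, [tail, 1 - tail]))
    else:
        raise ValueError(f"unknown interval method {method!r}")

    kept, dropped = [], []
    for i, c in enumerate(x.cells):
        if not is_cell[i]:
            kept.append(c.cell_id)
        elif absent[i]:
            dropped.append((c.cell_id, "absent"))
        elif not (lo <= expr[i] <= hi):
            dropped.append((c.cell_id, "outlier"))
        else:
            kept.append(c.cell_id)
    return QCReport(kept_ids=kept, dropped=dropped, interval=(lo, hi))


def identity_gate(x: ExpressionMatrix, population: str, gene: str) -> QCReport:
    """Drop cells of ``population`` that do not express their defining gene."""
    gi = x.gene_index(gene)
    kept, dropped = [], []
    for i, c in enumerate(x.cells):
        if (
            c.sample_type == "cell"
            and c.population == population
            and x.values[i, gi] <= 0
        ):
            dropped.append((c.cell_id, "identity"))
        else:
            kept.append(c.cell_id)
    return QCReport(kept_ids=kept, dropped=dropped)


def bead_contamination_report(x: ExpressionMatrix) -> QCReport:
    """List, per negative-control bead, every gene with non-zero signal."""
    if not x.genes:
        raise ValueError("empty gene panel")
    bead_mask = x.sample_type_mask("bead")
    if not bead_mask.any():
        raise ValueError("no sample_type='bead' negative controls present")
    symbols = np.array(x.gene_symbols)
    detections = {
        c.cell_id: [str(s) for s in symbols[x.values[i] > 0]]
        for i, c in enumerate(x.cells)
        if bead_mask[i]
    }
    return QCReport(kept_ids=x.cell_ids, dropped=[], bead_detections=detections)


def marker_summary(x: ExpressionMatrix) -> pd.DataFrame:
    """Detection fraction of neuronal and glial marker genes per population.

    Returns a tidy frame with columns population, symbol, category,
    n_detected, n_cells, fraction; empty marker categories yield no rows.
    """
    rows = []
    populations = sorted(
        {c.population for c in x.cells if c.sample_type == "cell"}
    )
    for pop in populations:
        mask = x.population_mask(pop)
        n = int(mask.sum())
        for j, g in enumerate(x.genes):
            if g.category not in ("neuronal_marker", "glial_marker"):
                continue
            k = int((x.values[mask, j] > 0).sum())
            rows.append(
                {
                    "population": pop,
                    "symbol": g.symbol,
                    "category": g.category,
                    "n_detected": k,
                    "n_cells": n,
                    "fraction": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["population", "symbol", "category", "n_detected", "n_cells",
                 "fraction"],
    )
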