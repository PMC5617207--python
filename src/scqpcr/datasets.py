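"""Packaged reference tables.

Three small delimited fixtures ship with the package:

* ``panel48.tsv`` — the 48-assay gene panel with functional categories,
* ``published_counts.tsv`` — per-gene detected/total counts in the two
  profiled populations (MCH n=89, Hcrt/Ox n=69) together with the published
  proportional differences and BH-adjusted p-values they imply,
* ``coloc_counts.tsv`` — dual-label FISH/IHC colocalization counts
  (reference-positive and double-positive cells per probe pair).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .core_io import GenePanelEntry
from .diff_detection import ContingencyTable
from .synthetic import SyntheticSpec, default_spec_from_counts

__all__ = [
    "load_panel",
    "load_published_counts",
    "load_coloc_counts",
    "published_detection_counts",
    "published_counts_spec",
]

_DATA = files("scqpcr") / "data"


def _read(name: str) -> pd.DataFrame:
    with (_DATA / name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_panel() -> list[GenePanelEntry]:
    """The 48-gene panel with functional categories and assay ids."""
    df = _read("panel48.tsv")
    return [
        GenePanelEntry(str(r.symbol), str(r.category), str(r.assay_id))
        for r in df.itertuples()
    ]


def load_published_counts() -> pd.DataFrame:
    """Per-gene detection counts for the two populations.

    Columns: symbol, k1/n1 (MCH), k2/n2 (Hcrt/Ox), prop_diff and
    p_adj_printed/sig as published (p_adj_printed is NaN for entries listed
    only as above the significance level).
    """
    df = _read("published_counts.tsv")
    out = df.rename(
        columns={"k_mch": "k1", "n_mch": "n1", "k_hcrt": "k2", "n_hcrt": "n2"}
    )
    out["sig"] = out["sig"].astype(bool)
    return out


def load_coloc_counts() -> pd.DataFrame:
    """FISH/IHC colocalization count table with published percentages."""
    return _read("coloc_counts.tsv")


def published_detection_counts() -> list[tuple[str, ContingencyTable]]:
    """The published per-gene counts as contingency tables
    (group 1 = MCH, group 2 = Hcrt/Ox)."""
    df = load_published_counts()
    return [
        (
            str(r.symbol),
            ContingencyTable(
                int(r.k1), int(r.n1) - int(r.k1), int(r.k2), int(r.n2) - int(r.k2)
            ),
        )
        for r in df.itertuples()
    ]


def published_counts_spec(seed: int = 0, **kwargs) -> SyntheticSpec:
    """Synthetic-data spec seeded from the published detection proportions,
    with the panel's categories attached."""
    counts = load_published_counts()
    panel_by_symbol = {g.symbol: g for g in load_panel()}
    panel = [panel_by_symbol[str(s)] for s in counts["symbol"]]
    return default_spec_from_counts(counts, seed=seed, panel=panel, **kwargs)
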