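"""Coexpression summaries, colocalization arithmetic and cross-dataset
comparison.

Three families of operations live here:

* within-population coexpression structure of the panel (pairwise Pearson
  correlations on inverted-Ct values, net detection-frequency differences
  for bubble plots, population-average expression vectors),
* arithmetic over externally produced count tables — dual-label FISH/IHC
  colocalization percentages and transgenic reporter-line fidelity
  (specificity/penetrance).  Image segmentation and puncta scoring happen
  upstream; this package consumes only the resulting counts,
* rank correlation between gene-matched expression vectors from different
  datasets, and the latency-threshold classifier for the two
  electrophysiological firing signatures of Hcrt/Ox neurons (H-type: long
  latency to first spike after a hyperpolarizing step; D-type: depolarizing
  post-inhibitory rebound).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix
from .diff_detection import DetectionMatrix, _two_group_masks
from .util import round_half_away

__all__ = [
    "FiringFeature",
    "pearson_matrix",
    "bubble_stats",
    "colocalization_percent",
    "reporter_fidelity",
    "average_expression",
    "spearman_compare",
    "classify_firing_signature",
    "read_count_table",
]


def pearson_matrix(
    x: ExpressionMatrix,
    population: str,
    genes: list[str] | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Pairwise Pearson correlations between genes within one population.

    Computed on continuous inverted-Ct values by default (``binary=True``
    correlates detection indicators instead).  Zero-variance genes yield NaN
    rows/columns (undefined), including their diagonal.
    """
    mask = x.population_mask(population)
    if mask.sum() < 3:
        raise ValueError(
            f"population {population!r} has {int(mask.sum())} cells; need >= 3"
        )
    df = x.to_dataframe().loc[mask]
    if genes is not None:
        df = df[list(genes)]
    if binary:
        df = (df > 0).astype(float)
    corr = df.corr(method="pearson", min_periods=2)
    # pandas leaves the diagonal at 1 even for constant columns; mark those
    # correlations (self included) as undefined
    sd = df.std(axis=0)
    constant = sd.index[sd == 0]
    corr.loc[constant, :] = np.nan
    corr.loc[:, constant] = np.nan
    return corr


def bubble_stats(
    d: DetectionMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-gene net detection-frequency difference and combined expressing
    count between two populations (the bubble-plot statistics; positive net
    difference means more frequent in ``group_a``)."""
    ma, mb = _two_group_masks(d.cells, group_a, group_b)
    n1, n2 = int(ma.sum()), int(mb.sum())
    ka = d.values[ma].sum(axis=0)
    kb = d.values[mb].sum(axis=0)
    return pd.DataFrame(
        {
            "symbol": d.gene_symbols,
            "net_freq_diff": ka / n1 - kb / n2,
            "total_expressing": (ka + kb).astype(int),
        }
    )


def colocalization_percent(n_double: int, n_reference: int) -> float:
    """Percentage of reference-probe-positive cells that are double
    positive, rounded half-away-from-zero to one decimal."""
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not 0 <= n_double <= n_reference:
        raise ValueError("need 0 <= n_double <= n_reference")
    return round_half_away(100.0 * n_double / n_reference, 1)


def reporter_fidelity(
    n_reporter: int, n_ir: int, n_double: int
) -> tuple[float, float]:
    """Specificity and penetrance of a transgenic reporter line.

    specificity = % of reporter-positive cells that are immunoreactive for
    the defining peptide; penetrance = % of immunoreactive cells that are
    reporter positive.
    """
    if n_reporter <= 0 or n_ir <= 0:
        raise ValueError("reporter and immunoreactive counts must be positive")
    if n_double > min(n_reporter, n_ir) or n_double < 0:
        raise ValueError("n_double must be <= both denominators and >= 0")
    return (
        round_half_away(100.0 * n_double / n_reporter, 1),
        round_half_away(100.0 * n_double / n_ir, 1),
    )


def average_expression(
    x: ExpressionMatrix, population: str, detected_only: bool = False
) -> pd.Series:
    """Per-gene mean inverted-Ct expression over one population.

    Non-detected zeros are included by default, so the average reflects both
    prevalence and magnitude; ``detected_only=True`` averages over detected
    cells only (NaN where a gene is never detected).
    """
    mask = x.population_mask(population)
    if not mask.any():
        raise ValueError(f"population {population!r} has no cells")
    df = x.to_dataframe().loc[mask]
    if detected_only:
        return df.where(df > 0).mean(axis=0)
    return df.mean(axis=0)


def _exact_spearman_p(r1: np.ndarray, r2: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value for the Spearman coefficient by full
    enumeration of rank permutations (small n only)."""
    n = len(r1)
    count = 0
    total = 0
    c2 = r2 - r2.mean()
    denom2 = float(np.sqrt((c2**2).sum()))
    c1_all = r1 - r1.mean()
    denom1 = float(np.sqrt((c1_all**2).sum()))
    for perm in itertools.permutations(range(n)):
        c1 = c1_all[list(perm)]
        rho = float((c1 * c2).sum()) / (denom1 * denom2)
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_compare(
    v1: pd.Series | dict, v2: pd.Series | dict
) -> tuple[float, float, int]:
    """Spearman rank correlation between two gene-keyed vectors.

    Computed over the intersection of gene keys with mid-rank ties.  The
    two-sided p-value uses the t-approximation for n >= 10 and an exact
    permutation enumeration below.  Returns (rho, p, n_common).
    """
    s1 = pd.Series(v1).astype(float)
    s2 = pd.Series(v2).astype(float)
    common = s1.index.intersection(s2.index)
    n = len(common)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need >= 3")
    a = s1[common].to_numpy()
    b = s2[common].to_numpy()
    rho = float(stats.spearmanr(a, b).statistic)
    if n >= 10:
        p = float(stats.spearmanr(a, b).pvalue)
    else:
        r1 = stats.rankdata(a)
        r2 = stats.rankdata(b)
        p = _exact_spearman_p(r1, r2, rho)
    return rho, p, n


@dataclass(frozen=True)
class FiringFeature:
    """Pre-extracted electrophysiological features of one recorded neuron."""

    cell_id: str
    latency_ms: float | None
    rebound: bool = False

    def __post_init__(self) -> None:
        if self.latency_ms is not None and self.latency_ms < 0:
            raise ValueError("latency must be non-negative")


def classify_firing_signature(
    f: FiringFeature, threshold_ms: float = 100.0
) -> str:
    """H if the latency to first spike after the hyperpolarizing step
    strictly exceeds the threshold (default 100 ms), else D."""
    if f.latency_ms is None or np.isnan(f.latency_ms):
        raise ValueError(f"cell {f.cell_id}: latency not measured")
    return "H" if f.latency_ms > threshold_ms else "D"


def read_count_table(path) -> pd.DataFrame:
    """Read a colocalization or fidelity count table (TSV/CSV)."""
    from .core_io import _read_delimited

    return _read_delimited(path)
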