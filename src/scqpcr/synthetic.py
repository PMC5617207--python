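"""Synthetic single-cell panel-qPCR datasets with known ground truth.

The generator emulates the statistical structure the analysis assumes: per
gene and population, a cell detects the transcript with a Bernoulli
probability (dropout otherwise), and detected transcripts carry a
log2-scale magnitude drawn from a normal truncated to (0, ceiling].
Collection batches, per-gene batch shifts in detection probability, and
near-empty bead negative controls with rare low-magnitude contamination are
modeled so the QC and batch-test stages can be exercised against planted
truth.  Detection probabilities default to the empirical proportions of the
two profiled populations (n=89 and n=69), making the generated data a
statistical twin of the study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .core_io import CellMeta, ExpressionMatrix, GenePanelEntry

__all__ = [
    "BatchShift",
    "SyntheticSpec",
    "SyntheticTruth",
    "default_spec_from_counts",
    "generate_dataset",
    "inject_batch_effect",
]


@dataclass(frozen=True)
class BatchShift:
    """Planned detection-probability difference between the two equal
    batches of one population: batch 1 keeps the base probability, batch 2
    uses base + shift."""

    population: str
    gene: str
    shift: float


@dataclass
class SyntheticSpec:
    """Generative parameters for one synthetic panel experiment.

    detect_prob is a genes x populations frame of per-cell detection
    probabilities.  mu and sigma give the truncated-normal magnitude model
    for detected transcripts (log2 units on the inverted-Ct scale); each may
    be a scalar or a genes x populations frame.  Each population is split
    into two equal collection batches; ``batch_plan`` lists planted
    between-batch detection shifts.  Each population also contributes
    ``n_beads`` negative-control beads whose genes light up independently
    with probability ``bead_contam_prob`` at low magnitude (Uniform(1, 5)),
    mimicking trace ambient transcripts.
    """

    populations: list[tuple[str, int]]
    detect_prob: pd.DataFrame
    mu: float | pd.DataFrame = 12.0
    sigma: float | pd.DataFrame = 3.0
    batch_plan: list[BatchShift] = field(default_factory=list)
    n_beads: int = 8
    bead_contam_prob: float = 0.005
    ceiling: float = 35.0
    seed: int = 0
    panel: list[GenePanelEntry] | None = None

    def _as_frame(self, value, name: str) -> pd.DataFrame:
        if isinstance(value, pd.DataFrame):
            if list(value.index) != self.genes or list(value.columns) != list(
                self.detect_prob.columns
            ):
                raise ValueError(f"{name} frame must be indexed like detect_prob")
            return value.astype(float)
        return pd.DataFrame(
            float(value),
            index=self.detect_prob.index,
            columns=self.detect_prob.columns,
        )

    def mu_frame(self) -> pd.DataFrame:
        return self._as_frame(self.mu, "mu")

    def sigma_frame(self) -> pd.DataFrame:
        return self._as_frame(self.sigma, "sigma")

    def __post_init__(self) -> None:
        if self.detect_prob.empty:
            raise ValueError("empty detection-probability table")
        pops = [p for p, _ in self.populations]
        if list(self.detect_prob.columns) != pops:
            raise ValueError("detect_prob columns must match population labels")
        probs = self.detect_prob.to_numpy(dtype=float)
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("detection probabilities must lie in [0, 1]")
        if not 0 <= self.bead_contam_prob <= 1:
            raise ValueError("bead_contam_prob must lie in [0, 1]")
        sig = self.sigma_frame().to_numpy()
        if (sig < 0).any():
            raise ValueError("sigma must be >= 0")
        mu = self.mu_frame().to_numpy()
        if ((mu <= 0) | (mu >= self.ceiling)).any():
            raise ValueError("mu must lie strictly inside (0, ceiling)")
        for b in self.batch_plan:
            base = float(self.detect_prob.loc[b.gene, b.population])
            shifted = base + b.shift
            if not 0 <= shifted <= 1:
                raise ValueError(
                    f"batch shift on {b.gene}/{b.population}: shifted "
                    f"probability {shifted} outside [0, 1]"
                )

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.detect_prob.index]

    # -- config-file round trip ------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        def _serialize(value):
            if isinstance(value, pd.DataFrame):
                return {pop: [float(v) for v in value[pop]] for pop in value.columns}
            return float(value)

        payload = {
            "populations": [[p, int(n)] for p, n in self.populations],
            "genes": self.genes,
            "detect_prob": {
                pop: [float(v) for v in self.detect_prob[pop]]
                for pop in self.detect_prob.columns
            },
            "mu": _serialize(self.mu),
            "sigma": _serialize(self.sigma),
            "batch_plan": [
                {"population": b.population, "gene": b.gene, "shift": b.shift}
                for b in self.batch_plan
            ],
            "n_beads": self.n_beads,
            "bead_contam_prob": self.bead_contam_prob,
            "ceiling": self.ceiling,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text())
        detect = pd.DataFrame(
            {k: v for k, v in payload["detect_prob"].items()},
            index=payload["genes"],
        )

        def _deserialize(value):
            if isinstance(value, dict):
                return pd.DataFrame(value, index=payload["genes"])
            return float(value)

        return cls(
            populations=[(p, int(n)) for p, n in payload["populations"]],
            detect_prob=detect,
            mu=_deserialize(payload["mu"]),
            sigma=_deserialize(payload["sigma"]),
            batch_plan=[BatchShift(**b) for b in payload.get("batch_plan", [])],
            n_beads=int(payload["n_beads"]),
            bead_contam_prob=float(payload["bead_contam_prob"]),
            ceiling=float(payload["ceiling"]),
            seed=int(payload["seed"]),
        )


@dataclass
class SyntheticTruth:
    """Realized detection indicators (cells x genes, beads included) plus
    the generating spec — the ground truth for recovery tests."""

    detected: pd.DataFrame
    spec: SyntheticSpec


#: Abundance-coupled default magnitude model: detected transcripts of a gene
#: that is prevalent in a population are abundant (high inverted-Ct), rarely
#: detected transcripts sit near the detection floor.  Dropout probability
#: falling with mean expression is the canonical behaviour of single-cell
#: qPCR, and it keeps trace detections of a marker in the "wrong" population
#: at trace magnitude.
MU_FLOOR = 6.0
MU_SPAN = 12.0


def default_spec_from_counts(
    counts: pd.DataFrame,
    group_a: str = "MCH",
    group_b: str = "HcrtOx",
    mu: float | pd.DataFrame | None = None,
    sigma: float | pd.DataFrame = 3.0,
    seed: int = 0,
    panel: list[GenePanelEntry] | None = None,
) -> SyntheticSpec:
    """Spec whose detection probabilities are the empirical proportions of a
    per-gene count table (columns symbol, k1, n1, k2, n2).

    By default the detected-magnitude mean is coupled to prevalence,
    ``mu = MU_FLOOR + MU_SPAN * detect_prob`` (range 6-18, mid-scale on the
    35-cycle inverted-Ct axis); pass a scalar or frame to override.
    """
    if counts.empty:
        raise ValueError("empty count table")
    for col in ("symbol", "k1", "n1", "k2", "n2"):
        if col not in counts.columns:
            raise ValueError(f"count table missing column {col!r}")
    n1 = int(counts["n1"].iloc[0])
    n2 = int(counts["n2"].iloc[0])
    detect = pd.DataFrame(
        {
            group_a: counts["k1"].to_numpy() / counts["n1"].to_numpy(),
            group_b: counts["k2"].to_numpy() / counts["n2"].to_numpy(),
        },
        index=[str(s) for s in counts["symbol"]],
    )
    if mu is None:
        mu = MU_FLOOR + MU_SPAN * detect

    return SyntheticSpec(
        populations=[(group_a, n1), (group_b, n2)],
        detect_prob=detect,
        mu=mu,
        sigma=sigma,
        seed=seed,
        panel=panel,
    )


def _truncated_normal(
    rng: np.random.Generator,
    mus: np.ndarray,
    sigmas: np.ndarray,
    ceiling: float,
) -> np.ndarray:
    """Elementwise Normal(mu, sigma) truncated to (0, ceiling]; sigma=0
    entries degenerate to the constant mu."""
    out = np.asarray(mus, dtype=float).copy()
    positive = np.asarray(sigmas) > 0
    if positive.any():
        m = out[positive]
        s = np.asarray(sigmas, dtype=float)[positive]
        out[positive] = truncnorm.rvs(
            (0.0 - m) / s, (ceiling - m) / s, loc=m, scale=s, random_state=rng
        )
    return out


def generate_dataset(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one synthetic dataset; deterministic given (spec, seed).

    Cells of each population are split into two equal collection batches
    (``<pop>_b1``, ``<pop>_b2``, first half b1).  Per cell and gene the
    transcript is detected with the spec'd (batch-shifted where planned)
    probability; detected values are truncated-normal magnitudes, beads are
    zero except for rare low-magnitude contamination.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = spec.genes
    panel = spec.panel or [GenePanelEntry(g) for g in genes]
    if [g.symbol for g in panel] != genes:
        raise ValueError("panel symbols do not match detect_prob index")

    cells: list[CellMeta] = []
    blocks: list[np.ndarray] = []
    truth_blocks: list[np.ndarray] = []

    mu_frame = spec.mu_frame()
    sigma_frame = spec.sigma_frame()
    for pop, n in spec.populations:
        half = n // 2
        probs = np.tile(spec.detect_prob[pop].to_numpy(dtype=float), (n, 1))
        for planted in spec.batch_plan:
            if planted.population == pop:
                j = genes.index(planted.gene)
                probs[half:, j] += planted.shift
        detected = rng.random((n, len(genes))) < probs
        values = np.zeros((n, len(genes)))
        mus = np.tile(mu_frame[pop].to_numpy(dtype=float), (n, 1))[detected]
        sigmas = np.tile(sigma_frame[pop].to_numpy(dtype=float), (n, 1))[detected]
        values[detected] = _truncated_normal(rng, mus, sigmas, spec.ceiling)
        blocks.append(values)
        truth_blocks.append(detected)
        cells.extend(
            CellMeta(
                cell_id=f"{pop}_{i + 1:03d}",
                population=pop,
                batch=f"{pop}_b1" if i < half else f"{pop}_b2",
                sample_type="cell",
            )
            for i in range(n)
        )

    for pop, _ in spec.populations:
        contam = rng.random((spec.n_beads, len(genes))) < spec.bead_contam_prob
        values = np.zeros((spec.n_beads, len(genes)))
        values[contam] = rng.uniform(1.0, 5.0, size=int(contam.sum()))
        blocks.append(values)
        truth_blocks.append(contam)
        cells.extend(
            CellMeta(
                cell_id=f"bead_{pop}_{i + 1:02d}",
                population=pop,
                batch=f"{pop}_beads",
                sample_type="bead",
            )
            for i in range(spec.n_beads)
        )

    values = np.vstack(blocks)
    x = ExpressionMatrix(values=values, cells=cells, genes=panel,
                         ceiling=spec.ceiling)
    truth = SyntheticTruth(
        detected=pd.DataFrame(
            np.vstack(truth_blocks), index=x.cell_ids, columns=genes
        ),
        spec=spec,
    )
    return x, truth


def inject_batch_effect(
    spec: SyntheticSpec, population: str, gene: str, shift: float
) -> SyntheticSpec:
    """Return a spec with a planted between-batch detection shift on one
    gene of one population (batch 2 probability = base + shift)."""
    if shift == 0:
        return spec
    if gene not in spec.genes:
        raise ValueError(f"gene {gene!r} not in spec")
    if population not in [p for p, _ in spec.populations]:
        raise ValueError(f"population {population!r} not in spec")
    new = replace(
        spec, batch_plan=[*spec.batch_plan, BatchShift(population, gene, shift)]
    )
    return new
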