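"""Simulation-based power analysis for two-population detection comparisons.

The question: at the study's sample sizes, what is the probability that the
two-sided Fisher exact test at level alpha detects a true difference
``delta = |p1 - p2|`` in per-cell detection probabilities?  Each replicate
draws detection counts ``Binomial(n1, p1)`` and ``Binomial(n2, p2)``, tests
the resulting 2x2 table, and the rejection fraction across replicates
estimates the power.  An exact-enumeration companion sums binomial-weighted
rejection indicators over all (k1, k2) outcomes and serves as the
small-sample cross-check of the Monte Carlo estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .diff_detection import ContingencyTable, fisher_two_sided

__all__ = ["PowerResult", "simulate_power", "exact_power", "power_grid"]


@dataclass
class PowerResult:
    """Monte Carlo power estimate for one two-proportion design."""

    n1: int
    n2: int
    p1: float
    p2: float
    alpha: float
    reps: int
    power_hat: float
    seed: int

    @property
    def delta(self) -> float:
        return abs(self.p1 - self.p2)

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power_hat * (1 - self.power_hat) / self.reps))


def _validate(n1: int, n2: int, p1: float, p2: float, alpha: float) -> None:
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    for name, p in (("p1", p1), ("p2", p2)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name}={p} must be a probability in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")


def simulate_power(
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> PowerResult:
    """Monte Carlo power of the two-sided Fisher exact test.

    The rejection criterion is strict, ``p < alpha`` (the test is discrete
    and conservative, so at delta=0 the rejection rate sits below alpha).
    Deterministic given ``seed``.
    """
    _validate(n1, n2, p1, p2, alpha)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    k1 = rng.binomial(n1, p1, size=reps)
    k2 = rng.binomial(n2, p2, size=reps)
    # Fisher p depends only on the counts; evaluate each distinct pair once.
    pairs, inverse = np.unique(np.column_stack([k1, k2]), axis=0,
                               return_inverse=True)
    pvals = np.array(
        [
            fisher_two_sided(ContingencyTable(int(a), n1 - int(a),
                                              int(c), n2 - int(c)))
            for a, c in pairs
        ]
    )
    rejected = pvals[inverse] < alpha
    return PowerResult(
        n1=n1, n2=n2, p1=p1, p2=p2, alpha=alpha, reps=reps,
        power_hat=float(rejected.mean()), seed=seed,
    )


def exact_power(
    n1: int, n2: int, p1: float, p2: float, alpha: float = 0.05
) -> float:
    """Exact power by enumeration over all (k1, k2) outcomes.

    Sums ``Binom(n1,p1)(k1) * Binom(n2,p2)(k2)`` over every outcome the test
    rejects; feasible for the panel's modest group sizes.
    """
    _validate(n1, n2, p1, p2, alpha)
    w1 = binom.pmf(np.arange(n1 + 1), n1, p1)
    w2 = binom.pmf(np.arange(n2 + 1), n2, p2)
    power = 0.0
    for k1 in range(n1 + 1):
        if w1[k1] == 0.0:
            continue
        for k2 in range(n2 + 1):
            if w2[k2] == 0.0:
                continue
            t = ContingencyTable(k1, n1 - k1, k2, n2 - k2)
            if fisher_two_sided(t) < alpha:
                power += w1[k1] * w2[k2]
    return float(power)


def _cell_seed(master_seed: int, baseline: float, delta: float) -> int:
    """Stable per-cell substream seed derived from the master seed and the
    grid coordinates, so grid cells are independent and individually
    reproducible."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed),
        spawn_key=(int(round(baseline * 10_000)), int(round(delta * 10_000))),
    )
    return int(ss.generate_state(1)[0] % (2**31))


def power_grid(
    n1: int,
    n2: int,
    deltas,
    baselines,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Power surface over (baseline p1, effect delta) with p2 = p1 + delta.

    Every cell must be feasible (p1 + delta <= 1); infeasible cells raise an
    error listing them.  Each cell runs :func:`simulate_power` on its own
    deterministic substream of the master seed.
    """
    deltas = list(deltas)
    baselines = list(baselines)
    infeasible = [
        (b, d) for b in baselines for d in deltas if b + d > 1 or b < 0
    ]
    if infeasible:
        raise ValueError(f"infeasible (baseline, delta) cells: {infeasible}")
    rows = []
    for b in baselines:
        for d in deltas:
            res = simulate_power(
                n1, n2, b, b + d, alpha=alpha, reps=reps,
                seed=_cell_seed(seed, b, d),
            )
            rows.append(
                {
                    "baseline": b,
                    "delta": d,
                    "n1": n1,
                    "n2": n2,
                    "alpha": alpha,
                    "reps": reps,
                    "power_hat": res.power_hat,
                    "mc_se": res.mc_se,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(rows)
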