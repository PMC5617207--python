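"""Simulation-based power analysis at the study's sample sizes.

For group sizes n1=69 and n2=89, estimates the power of the two-sided
Fisher exact test (alpha = 0.05, 1000 Monte Carlo replicates per cell)
over detection-probability differences of 0, 15, 25 and 35 percentage
points at baselines 0.1, 0.3 and 0.5, and cross-checks the largest effect
against the exact-enumeration power.
"""

from pathlib import Path

from scqpcr.power_sim import exact_power, power_grid

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 17


def main() -> None:
    grid = power_grid(
        n1=69, n2=89,
        deltas=(0.0, 0.15, 0.25, 0.35),
        baselines=(0.1, 0.3, 0.5),
        alpha=0.05, reps=1000, seed=SEED,
    )
    grid.to_csv(BASE / "power_grid.tsv", sep="\t", index=False)
    print(grid.pivot(index="baseline", columns="delta",
                     values="power_hat").to_string())

    mc = grid.query("baseline == 0.3 and delta == 0.35").iloc[0]
    ex = exact_power(69, 89, 0.30, 0.65, alpha=0.05)
    print(f"\nlargest effect (0.30 vs 0.65): Monte Carlo "
          f"{mc.power_hat:.1%} +/- {3 * mc.mc_se:.1%}, exact {ex:.1%}")
    null_ok = (grid.query("delta == 0").power_hat
               <= 0.05 + 3 * grid.query("delta == 0").mc_se).all()
    print(f"null rejection rates within 5% + 3 MC-SE: {bool(null_ok)}")


if __name__ == "__main__":
    main()
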