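import math
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import fisher_exact as scipy_fisher

from scqpcr.diff_detection import (
    ContingencyTable,
    batch_effect_test,
    bh_adjust,
    binarize,
    detection_counts,
    detection_matrix_from_counts,
    differential_detection_table,
    fisher_two_sided,
    proportional_difference,
)

from conftest import make_expr


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact rational
    arithmetic: sum hypergeometric point probabilities not exceeding the
    observed one (with the same 1e-7 relative tie tolerance)."""
    n1, n2, K, N = a + b, c + d, a + c, a + b + c + d

    def point(k: int) -> Fraction:
        return Fraction(
            math.comb(n1, k) * math.comb(n2, K - k), math.comb(N, K)
        )

    obs = point(a)
    cutoff = obs + obs * Fraction(1, 10**7)
    total = Fraction(0)
    for k in range(max(0, K - n2), min(K, n1) + 1):
        if point(k) <= cutoff:
            total += point(k)
    return min(1.0, float(total))


def bh_oracle(pvals):
    """Step-up adjustment written from the definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, m * p[idx] / i)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# fisher_two_sided
# ---------------------------------------------------------------------------

def test_fisher_trivial_cases():
    assert fisher_two_sided(ContingencyTable(5, 0, 5, 0)) == 1.0
    assert fisher_two_sided(ContingencyTable(0, 5, 0, 5)) == 1.0
    # hand-enumerable 2x2 with margins (5, 5)
    assert fisher_two_sided(ContingencyTable(2, 3, 3, 2)) == pytest.approx(
        fisher_oracle(2, 3, 3, 2), rel=1e-12
    )


def test_fisher_extreme_table_needs_log_space():
    """The most extreme published table has a raw p of ~1e-44, far below
    what naive probability products can represent accurately."""
    p = fisher_two_sided(ContingencyTable(1, 88, 69, 0))
    assert p == pytest.approx(fisher_oracle(1, 88, 69, 0), rel=1e-10)
    assert p == pytest.approx(1.0669869e-44, rel=1e-5)


def test_fisher_agrees_with_exact_oracle_exhaustively_small():
    for n1 in range(1, 9):
        for n2 in range(1, 9):
            for a in range(n1 + 1):
                for c in range(n2 + 1):
                    t = ContingencyTable(a, n1 - a, c, n2 - c)
                    assert fisher_two_sided(t) == pytest.approx(
                        fisher_oracle(a, n1 - a, c, n2 - c), rel=1e-10
                    ), (a, n1, c, n2)


def test_fisher_agrees_with_oracle_random_tables_margins_30():
    rng = np.random.default_rng(42)
    for _ in range(250):
        n1, n2 = rng.integers(1, 31, size=2)
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        t = ContingencyTable(a, int(n1) - a, c, int(n2) - c)
        expected = fisher_oracle(t.a, t.b, t.c, t.d)
        assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-10)


def test_fisher_matches_scipy_on_generic_tables():
    """Independent library cross-check away from point-probability ties."""
    rng = np.random.default_rng(5)
    for _ in range(100):
        n1, n2 = rng.integers(2, 40, size=2)
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        ours = fisher_two_sided(ContingencyTable(a, int(n1) - a, c, int(n2) - c))
        theirs = scipy_fisher([[a, n1 - a], [c, n2 - c]]).pvalue
        assert ours == pytest.approx(theirs, rel=1e-8, abs=1e-12)


def test_fisher_symmetries():
    rng = np.random.default_rng(9)
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(0, 20, size=4))
        p = fisher_two_sided(ContingencyTable(a, b, c, d))
        # swapping the two groups
        assert p == pytest.approx(
            fisher_two_sided(ContingencyTable(c, d, a, b)), rel=1e-12
        )
        # swapping detected/not-detected in both groups simultaneously
        assert p == pytest.approx(
            fisher_two_sided(ContingencyTable(b, a, d, c)), rel=1e-12
        )


def test_fisher_rejects_invalid_counts():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        ContingencyTable(1.5, 2, 3, 4)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def test_bh_hand_examples():
    assert bh_adjust([0.03]).tolist() == [0.03]
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)


def test_bh_matches_definition_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 60))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p), rel=1e-12)


def test_bh_structural_properties():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(size=30), [1e-9]])
    adj = bh_adjust(p)
    assert (adj <= 1.0).all()
    # ordered by raw p, adjusted values are non-decreasing
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
    # the smallest p gets the Bonferroni value
    assert adj[np.argmin(p)] == pytest.approx(min(1.0, len(p) * p.min()))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# proportional difference and table assembly
# ---------------------------------------------------------------------------

def test_proportional_difference_published_rows():
    assert proportional_difference(ContingencyTable(14, 75, 60, 9)) == 71.0
    assert proportional_difference(ContingencyTable(39, 50, 68, 1)) == 55.0
    assert proportional_difference(ContingencyTable(3, 3, 4, 4)) == 0.0
    with pytest.raises(ValueError):
        proportional_difference(ContingencyTable(0, 0, 1, 1))


def test_binarize_and_detection_counts(published_counts):
    x = make_expr([[5.0, 0.0], [0.1, 0.0]])
    d = binarize(x)
    assert d.values.tolist() == [[1, 0], [1, 0]]

    dm = detection_matrix_from_counts(published_counts)
    counts = dict(detection_counts(dm, "MCH", "HcrtOx"))
    gad1 = counts["Gad1"]
    assert (gad1.a, gad1.b, gad1.c, gad1.d) == (87, 2, 39, 30)
    # all-detected gene
    gls = counts["Gls"]
    assert (gls.a, gls.b, gls.c, gls.d) == (89, 0, 69, 0)


def test_detection_counts_validates_groups(published_counts):
    dm = detection_matrix_from_counts(published_counts)
    with pytest.raises(ValueError, match="no cells"):
        detection_counts(dm, "MCH", "Vgat")
    with pytest.raises(ValueError, match="distinct"):
        detection_counts(dm, "MCH", "MCH")


def test_differential_table_reproduces_published_anchors(published_diff):
    t = published_diff.set_index("symbol")
    assert t.loc["Pdyn", "p_adj"] == pytest.approx(5.12e-43, rel=5e-3)
    assert bool(t.loc["Pdyn", "significant"])
    assert t.loc["Gal", "p_adj"] > 0.05
    assert not bool(t.loc["Gal", "significant"])
    # ranked by descending proportional difference
    assert (t.prop_diff_pct.to_numpy()[:-1] >= t.prop_diff_pct.to_numpy()[1:]).all()
    assert published_diff.symbol.iloc[0] == "Pdyn"


def test_null_permutations_rarely_flag_anything(synth_dataset):
    """Random relabelings of one population should almost never produce a
    significant gene at FDR 5% (and raw Fisher p is conservative)."""
    x, _ = synth_dataset
    mch = x.subset_cells(x.population_mask("MCH"))
    rng = np.random.default_rng(0)
    n = len(mch.cells)
    flagged_runs = 0
    raw_rates = []
    for _ in range(40):
        half = rng.permutation(n) < n // 2
        relabeled = make_expr(
            mch.values,
            populations=["A" if h else "B" for h in half],
            gene_names=mch.gene_symbols,
        )
        t = differential_detection_table(binarize(relabeled), "A", "B")
        flagged_runs += int(t.significant.any())
        raw_rates.append((t.p_raw < 0.05).mean())
    assert flagged_runs <= 2  # >= 95% of permutations flag nothing
    assert np.mean(raw_rates) <= 0.05


# ---------------------------------------------------------------------------
# batch effects
# ---------------------------------------------------------------------------

def test_batch_effect_identical_halves_and_constant_gene():
    vals = np.tile([[10.0, 0.0, 7.0]], (40, 1))
    x = make_expr(vals, batches=["b1"] * 20 + ["b2"] * 20,
                  gene_names=["g1", "g2", "g3"])
    bt = batch_effect_test(binarize(x), "P")
    assert not bt.significant.any()
    # an all-detected gene across both batches is maximally null
    assert (bt.set_index("symbol").loc["g1", "p_raw"]) == 1.0


def test_batch_effect_requires_two_batches():
    x = make_expr(np.ones((4, 1)), batches=["b1"] * 4)
    with pytest.raises(ValueError, match="2 batches"):
        batch_effect_test(binarize(x), "P")


def test_batch_effect_recovers_planted_shift():
    from scqpcr.datasets import published_counts_spec
    from scqpcr.synthetic import generate_dataset, inject_batch_effect

    spec = inject_batch_effect(published_counts_spec(), "MCH", "Nnat", 0.5)
    x, _ = generate_dataset(spec, seed=3)
    bt = batch_effect_test(binarize(x), "MCH")
    flagged = set(bt.loc[bt.significant, "symbol"])
    assert "Nnat" in flagged
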