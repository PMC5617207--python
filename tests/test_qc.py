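import numpy as np
import pytest

from scqpcr.qc import (
    apply_report,
    bead_contamination_report,
    housekeeping_prescreen,
    identity_gate,
    marker_summary,
)

from conftest import make_expr


def _col(values, **kw):
    return make_expr(np.asarray(values, dtype=float)[:, None],
                     gene_names=["Gapdh"], **kw)


def test_prescreen_zero_variance_cohort_keeps_expressing_cells():
    """All expressing cells identical: degenerate interval [10, 10], only the
    absent cell is dropped."""
    x = _col([10, 10, 10, 10, 0])
    rep = housekeeping_prescreen(x, "Gapdh", 0.95)
    assert rep.interval == (10.0, 10.0)
    assert rep.dropped == [("c004", "absent")]
    assert len(rep.kept_ids) == 4


def test_prescreen_matches_hand_computed_normal_interval():
    vals = [8.0, 9.0, 10.0, 11.0, 12.0, 30.0]
    x = _col(vals)
    rep = housekeeping_prescreen(x, "Gapdh", 0.95)
    m, s = np.mean(vals), np.std(vals, ddof=1)
    assert rep.interval == pytest.approx((m - 1.959964 * s, m + 1.959964 * s),
                                         abs=1e-5)
    # 30 lies above m + 1.96 s for these six values, so it alone is dropped
    assert 30.0 > m + 1.959964 * s
    assert rep.dropped == [("c005", "outlier")]


def test_prescreen_quantile_alternative():
    vals = np.linspace(1, 30, 100)
    rep = housekeeping_prescreen(_col(vals), "Gapdh", 0.90, method="quantile")
    lo, hi = rep.interval
    assert lo == pytest.approx(np.quantile(vals, 0.05))
    assert hi == pytest.approx(np.quantile(vals, 0.95))


def test_prescreen_removes_contaminated_cells_preferentially():
    """A 5% low-yield contamination at expression 1.0 against a Normal(12, 2)
    cohort is removed at a far higher rate than clean cells."""
    rng = np.random.default_rng(7)
    clean = np.clip(rng.normal(12, 2, 950), 0.1, 34)
    contam = np.full(50, 1.0)
    x = _col(np.concatenate([clean, contam]))
    rep = housekeeping_prescreen(x, "Gapdh", 0.95)
    dropped = set(rep.dropped_ids)
    contam_ids = {f"c{i:03d}" for i in range(950, 1000)}
    contam_rate = len(dropped & contam_ids) / 50
    clean_rate = len(dropped - contam_ids) / 950
    assert contam_rate > 0.9
    assert clean_rate < 0.1


def test_prescreen_requires_expressing_cells_and_known_gene():
    x = _col([0, 0, 5])
    with pytest.raises(ValueError, match=">= 2"):
        housekeeping_prescreen(x, "Gapdh", 0.95)
    with pytest.raises(KeyError, match="Actb"):
        housekeeping_prescreen(_col([5, 6, 7]), "Actb", 0.95)


def test_prescreen_is_idempotent_on_separated_outliers_and_keeps_mean_cell():
    """With outliers well clear of a tight cohort, the screen converges in
    one pass: reapplying it to its own output changes nothing, and a cell
    at the cohort mean is always kept."""
    vals = np.concatenate([np.linspace(10, 12, 30), [30.0]])
    vals[0] = vals[:30].mean()
    x = _col(vals)
    rep = housekeeping_prescreen(x, "Gapdh", 0.95)
    assert rep.dropped == [("c030", "outlier")]
    assert "c000" in rep.kept_ids
    filtered = apply_report(x, rep)
    rep2 = housekeeping_prescreen(filtered, "Gapdh", 0.95)
    assert rep2.dropped == []
    assert rep2.kept_ids == rep.kept_ids


def test_identity_gate_is_idempotent():
    vals = np.concatenate([np.zeros(3), np.full(7, 8.0)])[:, None]
    x = make_expr(vals, gene_names=["Hcrt"])
    rep = identity_gate(x, "P", "Hcrt")
    filtered = apply_report(x, rep)
    rep2 = identity_gate(filtered, "P", "Hcrt")
    assert rep2.dropped == [] and rep2.kept_ids == rep.kept_ids


def test_prescreen_ignores_beads():
    x = _col([10, 11, 12, 0], sample_types=["cell", "cell", "cell", "bead"])
    rep = housekeeping_prescreen(x, "Gapdh", 0.95)
    assert "c003" in rep.kept_ids  # the bead is not screened


def test_identity_gate_drops_only_nonexpressing_population_cells():
    vals = np.ones((70, 1)) * 20.0
    vals[41, 0] = 0.0
    x = make_expr(vals, populations=["HcrtOx"] * 70, gene_names=["Hcrt"])
    rep = identity_gate(x, "HcrtOx", "Hcrt")
    assert len(rep.kept_ids) == 69
    assert rep.dropped == [("c041", "identity")]

    all_on = identity_gate(make_expr(np.ones((5, 1)), gene_names=["Hcrt"],
                                     populations=["P"] * 5), "P", "Hcrt")
    assert all_on.dropped == []

    all_off = identity_gate(make_expr(np.zeros((5, 1)), gene_names=["Hcrt"],
                                      populations=["P"] * 5), "P", "Hcrt")
    assert len(all_off.dropped) == 5 and all_off.kept_ids == []


def test_identity_gate_leaves_other_populations_alone():
    x = make_expr(np.zeros((4, 1)), populations=["A", "A", "B", "B"],
                  gene_names=["Hcrt"])
    rep = identity_gate(x, "A", "Hcrt")
    assert rep.kept_ids == ["c002", "c003"]


def test_bead_report_clean_and_contaminated():
    vals = np.zeros((8, 3))
    x = make_expr(vals, sample_types=["bead"] * 8,
                  gene_names=["Hcrt", "Nptx2", "Pmch"])
    rep = bead_contamination_report(x)
    assert rep.n_contaminated_beads == 0

    vals = np.zeros((8, 3))
    vals[2, 0] = 3.0
    vals[2, 1] = 1.5
    x = make_expr(vals, sample_types=["bead"] * 8,
                  gene_names=["Hcrt", "Nptx2", "Pmch"])
    rep = bead_contamination_report(x)
    assert rep.n_contaminated_beads == 1
    assert rep.bead_detections["c002"] == ["Hcrt", "Nptx2"]


def test_bead_report_requires_beads_and_genes():
    with pytest.raises(ValueError, match="bead"):
        bead_contamination_report(make_expr(np.zeros((2, 1))))
    with pytest.raises(ValueError, match="panel"):
        bead_contamination_report(make_expr(np.zeros((2, 0)),
                                            sample_types=["bead"] * 2))


def test_marker_summary_fractions_per_population():
    # 3 cells MCH, 2 cells HcrtOx; one neuronal and one glial marker
    vals = np.array(
        [[5.0, 0.0], [6.0, 0.0], [0.0, 0.0], [4.0, 1.0], [3.0, 0.0]]
    )
    x = make_expr(
        vals,
        populations=["MCH", "MCH", "MCH", "HcrtOx", "HcrtOx"],
        gene_names=["Map2", "Gfap"],
        categories=["neuronal_marker", "glial_marker"],
    )
    df = marker_summary(x).set_index(["population", "symbol"])
    assert df.loc[("MCH", "Map2"), "fraction"] == pytest.approx(2 / 3)
    assert df.loc[("MCH", "Gfap"), "fraction"] == 0.0
    assert df.loc[("HcrtOx", "Gfap"), "fraction"] == 0.5


def test_marker_summary_binomial_recovery():
    rng = np.random.default_rng(11)
    det = rng.random(1000) < 0.5
    vals = np.where(det, 10.0, 0.0)[:, None]
    x = make_expr(vals, gene_names=["Map2"], categories=["neuronal_marker"])
    df = marker_summary(x)
    assert df.fraction.iloc[0] == pytest.approx(0.5, abs=0.05)
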