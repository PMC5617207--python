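"""Multivariate structure of the QC-filtered synthetic dataset.

Runs PCA on per-gene z-scored expression (expecting the two populations to
separate along PC1 with the defining neuropeptides on opposite poles) and
fits 95% coverage ellipses in PC1/PC2.  Hierarchical clustering runs on the
raw inverted-Ct values (z-scoring is a PCA preprocessing step here, not a
clustering one) with both supported linkages, reporting the 2-cut purity
against the true population labels.
"""

from pathlib import Path

import pandas as pd

from scqpcr.core_io import read_expression_table
from scqpcr.multivariate import (
    agglomerative_cluster,
    cluster_purity,
    coverage_ellipse,
    run_pca,
    top_loadings,
    zscore,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    x = read_expression_table(BASE / "expression_qc.tsv",
                              BASE / "synthetic" / "cell_meta.tsv",
                              BASE / "synthetic" / "panel.tsv")
    cells_only = x.subset_cells(x.sample_type_mask("cell"))
    z, flagged = zscore(cells_only)
    if flagged:
        print(f"zero-variance genes excluded from structure: {flagged}")

    pca = run_pca(z)
    pca.scores_frame().iloc[:, :5].to_csv(BASE / "pca_scores.tsv", sep="\t")
    pca.loadings_frame().iloc[:, :5].to_csv(BASE / "pca_loadings.tsv", sep="\t")
    vf = pca.variance_fraction
    print(f"PC1 {vf[0]:.1%} / PC2 {vf[1]:.1%} of total variance")
    pos, neg = top_loadings(pca, component=0, k=6)
    print(f"PC1 positive pole: {pos}")
    print(f"PC1 negative pole: {neg}")

    labels = pd.Series({c.cell_id: c.population for c in cells_only.cells})
    for pop in ("MCH", "HcrtOx"):
        ids = [c.cell_id for c in cells_only.cells if c.population == pop]
        ell = coverage_ellipse(pca.scores_frame().loc[ids, ["PC1", "PC2"]].to_numpy())
        inside = ell.contains(pca.scores_frame().loc[ids, ["PC1", "PC2"]].to_numpy())
        print(f"{pop}: 95% ellipse covers {inside.mean():.1%} of its cells")

    raw = cells_only.to_dataframe()
    rows = []
    for linkage in ("ward", "complete"):
        tree = agglomerative_cluster(raw, linkage=linkage)
        purity = cluster_purity(tree, k=2, labels=labels)
        rows.append({"linkage": linkage, "k": 2, "purity": purity})
        print(f"{linkage} linkage, k=2 purity: {purity:.3f}")
    pd.DataFrame(rows).to_csv(BASE / "cluster_purity.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
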