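"""Quality control of the simulated dataset.

Reads the raw Ct table written by 01_simulate_dataset.py, inverts it onto
the log2-like expression scale, then applies the three screens in order:
the Gapdh prescreen (cells absent for the housekeeping transcript, then
outliers beyond the 95% normal coverage interval), the identity gate
(sorted Hcrt/Ox cells must express Hcrt), and the bead negative-control
report.  Writes the filtered expression table and a JSON QC report.
"""

import json
from pathlib import Path

from scqpcr.core_io import invert_ct, read_ct_table, write_expression_table
from scqpcr.qc import (
    apply_report,
    bead_contamination_report,
    housekeeping_prescreen,
    identity_gate,
)

BASE = Path(__file__).resolve().parents[1] / "results"
IN = BASE / "synthetic"


def main() -> None:
    ct = read_ct_table(IN / "ct_matrix.tsv", IN / "cell_meta.tsv",
                       IN / "panel.tsv")
    x = invert_ct(ct)

    gapdh = housekeeping_prescreen(x, gene="Gapdh", ci_level=0.95)
    x = apply_report(x, gapdh)
    hcrt_gate = identity_gate(x, population="HcrtOx", gene="Hcrt")
    x = apply_report(x, hcrt_gate)
    beads = bead_contamination_report(x)

    write_expression_table(x, BASE / "expression_qc.tsv")
    report = {
        "gapdh_interval": gapdh.interval,
        "dropped_absent_or_outlier": gapdh.dropped,
        "dropped_identity": hcrt_gate.dropped,
        "contaminated_beads": {
            b: genes for b, genes in beads.bead_detections.items() if genes
        },
        "n_kept_cells": sum(1 for c in x.cells if c.sample_type == "cell"),
    }
    (BASE / "qc_report.json").write_text(json.dumps(report, indent=2))

    print(f"Gapdh prescreen interval: [{gapdh.interval[0]:.2f}, "
          f"{gapdh.interval[1]:.2f}]; dropped {len(gapdh.dropped)} cells")
    print(f"identity gate dropped {len(hcrt_gate.dropped)} Hcrt-negative cells")
    print(f"contaminated beads: {beads.n_contaminated_beads} / "
          f"{len(beads.bead_detections)}")
    print(f"kept {report['n_kept_cells']} cells -> results/expression_qc.tsv")


if __name__ == "__main__":
    main()
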