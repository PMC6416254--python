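"""Prune redundant length variables by pairwise correlation.

Reads the simulated table, computes the Pearson correlation matrix of the
8 length variables and keeps one representative per correlated cluster.
Expected outcome under the study conditions: L2 and L8 collapse onto the
crown height L6, the concealed field L7 onto the scale length L5, leaving
L1, L3, L4, L5, L6 for clustering.
"""

import json
from pathlib import Path

import scalemorph as sm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = sm.read_measurement_table(RESULTS / "synthetic_scales.csv")
    report = sm.select_variables(table)
    (RESULTS / "variable_selection.json").write_text(
        json.dumps(report.as_dict(), indent=2) + "\n"
    )
    print("kept:", ", ".join(report.kept))
    for dropped, rep in report.dropped.items():
        print(f"dropped {dropped} (represented by {rep})")


if __name__ == "__main__":
    main()
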