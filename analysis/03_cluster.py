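"""Q-type agglomerative clustering of the scales.

Clusters the 226 simulated scales on the 5 selected length variables
(squared Euclidean distance, between-groups linkage), compares candidate
group counts k = 7, 8, 9, and writes the k=8 partition. The choice of k=8
mirrors the study design; compare_k only reports diagnostics.
"""

import json
from pathlib import Path

import pandas as pd

import scalemorph as sm

RESULTS = Path(__file__).resolve().parents[1] / "results"
SELECTED = ("L1", "L3", "L4", "L5", "L6")


def main() -> None:
    table = sm.read_measurement_table(RESULTS / "synthetic_scales.csv")
    diag = sm.compare_k(table, SELECTED, ks=(7, 8, 9))
    rows = []
    for k, d in sorted(diag.items()):
        rows.append({
            "k": k,
            "group_sizes": "/".join(map(str, d["group_sizes"])),
            "within_dispersion": round(d["within_dispersion"], 2),
            "mean_silhouette": round(d["mean_silhouette"], 4),
        })
        print(rows[-1])
    pd.DataFrame(rows).to_csv(RESULTS / "compare_k.csv", index=False)

    part = diag[8]["partition"]
    pd.DataFrame({
        "scale_id": part.scale_ids, "cluster": part.labels,
    }).to_csv(RESULTS / "partition_k8.csv", index=False)
    print("k=8 group sizes:", part.group_sizes())


if __name__ == "__main__":
    main()
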