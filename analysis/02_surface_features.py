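#!/usr/bin/env python
"""Compute surface-chemistry descriptors for the toy structures: SASA and
tripeptide-relative SASA per residue, secondary structure, then the
34-descriptor table; finally compare the four main residue-class surface
compositions between the two label groups (Mann-Whitney U). The toy labels
track the hand-picked sequences, not any biology, so the p-values describe
this small fixture set only.

Reads results/structures + results/labels.tsv (from 01_simulate_inputs.py);
writes results/feature_table.csv and results/group_stats.tsv.
"""

from pathlib import Path

import pandas as pd

from surfclass import build_feature_table, group_report, read_structure

OUT = Path("results")


def main() -> None:
    labels = pd.read_csv(OUT / "labels.tsv", sep="\t", index_col=0)["class"]
    inputs = []
    for path in sorted((OUT / "structures").glob("*.pdb")):
        s = read_structure(path)
        inputs.append((s, labels[s.protein_id]))
    table = build_feature_table(inputs)
    table.to_csv(OUT / "feature_table.csv")
    print(f"feature table: {table.shape[0]} proteins x {table.shape[1] - 1} descriptors")

    rows = []
    for desc in (
        "surf_hydrophilic_pct",
        "surf_hydrophobic_pct",
        "surf_positive_pct",
        "surf_negative_pct",
    ):
        rep = group_report(table, desc, n_bins=8)
        (pair, p) = next(iter(rep.p_values.items()))
        rows.append(
            {
                "descriptor": desc,
                "mean_" + pair[0]: round(rep.means[pair[0]], 2),
                "mean_" + pair[1]: round(rep.means[pair[1]], 2),
                "p_value": p,
                "test": rep.test,
            }
        )
        print(f"{desc}: means {rep.means}, p={p:.3f}")
    pd.DataFrame(rows).to_csv(OUT / "group_stats.tsv", sep="\t", index=False)
    print("wrote group_stats.tsv")


if __name__ == "__main__":
    main()
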