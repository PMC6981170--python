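#!/usr/bin/env python
"""Match synthetic single-cell expression against the predicted state catalog.

Generates negative-binomial counts with dropout for cells placed at every
predicted attractor pattern, assigns each cell to a catalog state by exact
binary-pattern match, and clusters a 4-state subset on the correlation
distance as a sanity check of the grouping logic.

Writes: synthetic_counts.tsv, cell_assignments.csv, assignment_summary.csv,
        cluster_labels.csv
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

import endonet as en
from endonet.state_matching import (assign_cells, catalog_from_atlas,
                                    correlation_cluster, transform_expression)
from endonet.synthetic import GeneratorSpec, generate_cells


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cells-per-state", type=int, default=200)
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    network = en.pancreas_network()
    atlas = en.find_equilibria(network, en.HillParams(n=4))
    catalog = catalog_from_atlas(atlas)

    spec = GeneratorSpec(catalog=catalog, cells_per_state=args.cells_per_state,
                         seed=args.seed)
    matrix, truth = generate_cells(spec)
    matrix.to_csv(args.out_dir / "synthetic_counts.tsv", sep="\t")

    assignment = assign_cells(transform_expression(matrix, "count"), catalog)
    pd.DataFrame({"cell": assignment.cell_ids, "assigned": assignment.labels,
                  "truth": list(truth)}).to_csv(
        args.out_dir / "cell_assignments.csv", index=False)
    assignment.summary.to_csv(args.out_dir / "assignment_summary.csv", index=False)
    recovery = sum(a == t for a, t in zip(assignment.labels, truth)) / len(truth)
    detected = sorted(set(assignment.labels) - {"unmatched"})
    print(f"exact-pattern recovery: {recovery:.3f} over {len(truth)} cells; "
          f"{len(detected)}/{len(catalog)} catalog states detected")

    subset = {"S2": 60, "S6": 60, "S7": 60, "S11": 60}
    m4, t4 = generate_cells(GeneratorSpec(catalog=catalog, cells_per_state=subset,
                                          seed=args.seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        groups = correlation_cluster(
            transform_expression(m4.loc[catalog.genes], "count", log2=True), 4)
    pd.DataFrame({"cell": m4.columns, "group": groups, "truth": list(t4)}).to_csv(
        args.out_dir / "cluster_labels.csv", index=False)
    agreement = pd.crosstab(t4.values, groups)
    print("4-state correlation-clustering cross-tab:")
    print(agreement.to_string())


if __name__ == "__main__":
    main()
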