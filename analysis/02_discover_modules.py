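#!/usr/bin/env python
"""Discover foraging modules in the simulated cohort.

Reads the sessions written by 01_simulate_cohort.py, segments each into
round-trip excursions, computes the behavioral measure battery, and runs the
discovery pipeline: correlation-threshold sweep, Ward clustering with the
hybrid tree cut, shuffled-matrix cluster-count null, balanced train/test
partition, distance-IGP permutation test with q < 0.1, and nearest-centroid
annotation of every excursion.  Writes modules.json, assignments.csv and the
sweep table to results/modules/.

Run:  python analysis/02_discover_modules.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from foragedecomp import discovery, measures, tracking

COHORT = Path(__file__).resolve().parent.parent / "results" / "cohort"
RESULTS = Path(__file__).resolve().parent.parent / "results" / "modules"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    design = pd.read_csv(COHORT / "sessions" / "design.csv", index_col=0)
    excursions, meta_rows = [], []
    for mouse, row in design.iterrows():
        session = tracking.read_tracking(
            row["file"], metadata={"mouse": mouse, **row.drop("file").to_dict()})
        for e in tracking.segment_excursions(session, window=(0.0, 1e9)):
            excursions.append(e)
            meta_rows.append({"mouse": mouse, "genotype": row["genotype"],
                              "sex": row["sex"], "phase": row["phase"],
                              "cross": row["cross"],
                              "excursion": e.key.excursion})
    matrix = measures.measure_matrix(excursions)
    scaled = measures.scale_matrix(matrix)
    metadata = pd.DataFrame(meta_rows, index=matrix.index)
    print(f"{len(excursions)} excursions x {matrix.shape[1]} measures "
          f"({len(scaled.constant_columns)} constant columns zeroed)")

    res = discovery.discover_modules(scaled.data, metadata, seed=args.seed,
                                     null_iterations=500, nperm=500)
    sweep = res["sweep"]
    pd.DataFrame(
        [(r, len(m), c) for r, m, c in sweep.entries],
        columns=["threshold", "n_retained", "n_clusters"],
    ).to_csv(RESULTS / "sweep.csv", index=False)
    print(f"sweep selected r = {sweep.selected_threshold} "
          f"({len(sweep.selected_measures)} retained measures)")
    nt = res["null_test"]
    print(f"cluster-count null: observed {nt['observed']} clusters, "
          f"shuffled median {int(pd.Series(nt['null_counts']).median())}, "
          f"lower-tail p = {nt['p']:.4g}")

    modules = res["modules"]
    (RESULTS / "modules.json").write_text(modules.to_json())
    out = metadata.join(res["assignments"])
    out.to_csv(RESULTS / "assignments.csv", index_label="cimar")
    print(f"{len(modules)} reproducible modules at q < {modules.q_threshold} "
          f"(IGP {min(modules.igp_values.values()):.2f}-"
          f"{max(modules.igp_values.values()):.2f}); "
          f"annotated {len(out)} excursions")


if __name__ == "__main__":
    main()
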