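#!/usr/bin/env python
"""Module-transition dynamics: stereotypy and the sex comparison.

Orders each mouse's annotated modules by excursion start time, pools 1-step
transition counts, tests whether the next module depends on the previous one
(Monte Carlo Fisher), and compares male vs female chains by the Euclidean
distance between stationary distributions with a per-mouse sequence
permutation null.  Writes results/transitions/.

Run:  python analysis/04_module_transitions.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from foragedecomp.transitions import (build_transition_matrix,
                                      compare_groups_permutation,
                                      dependence_test,
                                      stationary_distribution)

BASE = Path(__file__).resolve().parent.parent / "results"
RESULTS = BASE / "transitions"


def sequences_by(ass: pd.DataFrame, mask) -> dict:
    out = {}
    for mouse, grp in ass[mask].groupby("mouse"):
        out[mouse] = grp.sort_values("excursion")["module"].tolist()
    return {m: s for m, s in out.items() if len(s) >= 2}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=5000)
    args = ap.parse_args()
    RESULTS.mkdir(parents=True, exist_ok=True)

    ass = pd.read_csv(BASE / "modules" / "assignments.csv")
    vocab = sorted(ass["module"].unique())

    for sex in ("male", "female"):
        seqs = sequences_by(ass, ass["sex"] == sex)
        t = build_transition_matrix(seqs, vocabulary=vocab)
        t.counts.to_csv(RESULTS / f"transition_counts_{sex}.csv")
        dep = dependence_test(t, mc_iterations=20_000, seed=args.seed)
        pi = stationary_distribution(t)
        print(f"{sex}: {t.counts.to_numpy().sum()} transitions from "
              f"{len(seqs)} mice; dependence p = {dep.p:.4g}; "
              f"stationary = {[round(float(x), 3) for x in pi]}")

    males = sequences_by(ass, ass["sex"] == "male")
    females = sequences_by(ass, ass["sex"] == "female")
    dist, p = compare_groups_permutation(males, females, nperm=args.nperm,
                                         seed=args.seed, vocabulary=vocab)
    pd.DataFrame([{"distance": dist, "p": p, "nperm": args.nperm}]).to_csv(
        RESULTS / "sex_comparison.csv", index=False)
    print(f"male vs female stationary-distribution distance = {dist:.4f}, "
          f"permutation p = {p:.4g} ({args.nperm} per-mouse permutations)")


if __name__ == "__main__":
    main()
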