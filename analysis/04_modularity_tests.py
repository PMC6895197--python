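#!/usr/bin/env python
"""CR modularity tests per hypothesis and group, plus strength comparisons.

Tests the five flower modularity hypotheses on the jointly Procrustes-fitted
specimens, separately per pollination-syndrome-like group, and across all
species with phylogenetic correction; then compares the strength of
modularity (effect sizes) between groups.  Writes a Table-1-shaped summary
(hypothesis x group -> CR, p, Z).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from floramorph import (
    builtin_hypotheses,
    compare_modularity,
    gpa,
    modularity_test,
    phylo_modularity,
    read_landmarks,
    read_tree,
    species_means,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--nperm", type=int, default=999)
    ap.add_argument("--data", default="results/02_imputation/landmarks_imputed.csv")
    ap.add_argument("--tree", default="results/data/tree.nwk")
    ap.add_argument("--out", default="results/04_modularity")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = read_landmarks(args.data)
    fit = gpa(table)
    means = species_means(fit)
    tree = read_tree(args.tree, prune_to=means.specimen_ids)
    hyps = builtin_hypotheses()
    rng = np.random.default_rng(args.seed)
    groups = [g for g in dict.fromkeys(fit.groups) if g]

    rows, comp_rows = [], []
    for hyp in hyps:
        per_group = {}
        for grp in groups:
            idx = [i for i, g in enumerate(fit.groups) if g == grp]
            res = modularity_test(fit.aligned[idx], hyp, nperm=args.nperm,
                                  seed=int(rng.integers(2**31)),
                                  landmark_labels=fit.landmark_labels, label=grp)
            per_group[grp] = res
            rows.append({"hypothesis": hyp.name, "group": grp, "n": len(idx),
                         "CR": res.cr_obs, "p": res.p, "Z": res.z})
        res = phylo_modularity(means, tree, hyp, nperm=args.nperm,
                               seed=int(rng.integers(2**31)))
        rows.append({"hypothesis": hyp.name, "group": "all (phylogenetic)",
                     "n": means.n_specimens, "CR": res.cr_obs, "p": res.p,
                     "Z": res.z})
        comp = compare_modularity(list(per_group.values()), list(per_group))
        for row in comp.table:
            comp_rows.append(dict(row, hypothesis=hyp.name))

    df = pd.DataFrame(rows)
    df.to_csv(out / "modularity_table.tsv", sep="\t", index=False)
    pd.DataFrame(comp_rows).to_csv(out / "strength_comparisons.tsv", sep="\t", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sig = df[df["p"] <= 0.05]
    print(f"\n{len(sig)}/{len(df)} tests significant at alpha=0.05; "
          "the generating 3-module partition should be among them in every group")


if __name__ == "__main__":
    main()
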