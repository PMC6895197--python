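#!/usr/bin/env python
"""Procrustes alignment, species mean shapes, and the PCA shape space.

Aligns the imputed specimens (removing position, orientation and size),
averages aligned coordinates within species, and ordinates both specimens
and species means by PCA, reporting the variance captured by the leading
axes and how the three groups separate.
"""

import argparse
from pathlib import Path

import pandas as pd

from floramorph import gpa, read_landmarks, shape_pca, species_means, write_landmarks


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/02_imputation/landmarks_imputed.csv")
    ap.add_argument("--out", default="results/03_shape_space")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = read_landmarks(args.data)

    fit = gpa(table)
    print(f"GPA converged={fit.converged} after {fit.iterations} iterations; "
          f"centroid sizes {fit.centroid_sizes.min():.3f}-{fit.centroid_sizes.max():.3f}")

    means = species_means(fit)
    write_landmarks(means, out / "species_mean_shapes.csv")
    print(f"{means.n_specimens} species mean shapes "
          f"({sum(1 for s in set(fit.species_ids) if fit.species_ids.count(s) == 1)} singletons pass through)")

    for label, space, ids in (
        ("specimens", shape_pca(fit), fit.specimen_ids),
        ("species means", shape_pca(means), means.specimen_ids),
    ):
        k = min(6, space.scores.shape[1])
        df = pd.DataFrame(space.scores[:, :k], columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "id", ids)
        tag = label.replace(" ", "_")
        df.to_csv(out / f"pca_scores_{tag}.tsv", sep="\t", index=False)
        print(f"PCA of {label}: " + ", ".join(
            f"PC{i+1} {v:.1f}%" for i, v in enumerate(space.pct_variance[:3])))


if __name__ == "__main__":
    main()
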