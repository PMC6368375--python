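#!/usr/bin/env python
"""Multivariate analysis of the pre-processed matrix: PCA with the
Hotelling T2 outlier screen, then 2-component PLS-DA with leave-one-out
Q2, a 199-permutation significance test, and |loading| > 0.0005 biomarker
selection.

Reads results/matrix.txt, writes scores/loadings/selection tables and a
JSON summary under results/multivariate/.
"""

import json
from pathlib import Path

import pandas as pd

from nmrstress import (
    FeatureMatrix,
    hotelling_outliers,
    loo_q2,
    pca_fit,
    permutation_test_q2,
    plsda_fit,
    select_biomarkers_by_loading,
)

MATRIX = Path("results/matrix.txt")
COHORT = Path("results/cohort")
OUT = Path("results/multivariate")
SEED = 20260928


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    X = FeatureMatrix.from_tsv(MATRIX, COHORT / "design.tsv")

    pca = pca_fit(X, n_components=2)
    screen = hotelling_outliers(pca, alpha=0.05)
    print(f"PCA screen: {int(screen['outlier'].sum())} of {len(screen)} samples "
          f"outside the 95% T2 limit ({screen['limit'].iloc[0]:.2f})")

    pls = plsda_fit(X, n_components=2)
    q2 = loo_q2(X, n_components=2)
    perm = permutation_test_q2(X, n_components=2, n_permutations=199, seed=SEED,
                               design=X.design)
    print(f"PLS-DA (2 comps): R2X={pls.r2x_cum:.3f} R2Y={pls.r2y_cum:.3f} "
          f"Q2={q2:.3f} permutation p={perm.p_value:.4f}")

    selected = select_biomarkers_by_loading(pls, threshold=0.0005)
    print(f"{len(selected)} bins pass |loading| > 0.0005; top bins at "
          f"{[round(v, 2) for v in selected.head(5)['ppm']]} ppm")

    pd.DataFrame(pls.scores, index=X.values.index,
                 columns=["t1", "t2"]).to_csv(OUT / "scores.tsv", sep="\t")
    pd.DataFrame(pls.x_loadings, index=X.bin_centers,
                 columns=["p1", "p2"]).to_csv(OUT / "loadings.tsv", sep="\t",
                                              index_label="ppm")
    selected.to_csv(OUT / "selected_bins.tsv", sep="\t", index=False)
    summary = {
        "r2x": pls.r2x_cum, "r2y": pls.r2y_cum, "q2": q2,
        "permutation_p": perm.p_value,
        "n_outliers": int(screen["outlier"].sum()),
        "n_selected_bins": int(len(selected)),
    }
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
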