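"""End-to-end discovery runs and replicate studies.

``discovery_run`` executes the full chain on one simulated cohort:
simulate -> preprocess -> PCA/T2 screen -> PLS-DA -> LOO Q2 -> label
permutation test -> loading selection -> volcano screen -> shift
assignment.  ``parameter_recovery_study`` and ``null_calibration_study``
repeat the chain over many seeded cohorts to measure recovery of the
injected effects and the type-I error of the permutation test.

Replicate studies default to 8,192-point spectra (bin width about
0.024 ppm) rather than the full 32,768 so that hundreds of cohorts remain
cheap; the chemical-shift resolution relevant to the pipeline (bins much
wider than the 0.002-ppm linewidth, narrower than the exclusion windows)
is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .assign import assign_shifts, supported_metabolites
from .chemometrics import (
    PermutationResult,
    PLSModel,
    hotelling_outliers,
    loo_q2,
    pca_fit,
    permutation_test_q2,
    plsda_fit,
    select_biomarkers_by_loading,
)
from .library import MetaboliteLibrary, default_effects, default_library
from .preprocess import FeatureMatrix, preprocess_cohort
from .simulate import SimConfig, simulate_cohort
from .volcano import volcano

__all__ = [
    "DiscoveryResult",
    "discovery_run",
    "hippurate_bin_mask",
    "parameter_recovery_study",
    "null_calibration_study",
]


@dataclass
class DiscoveryResult:
    matrix: FeatureMatrix
    pca_outliers: pd.DataFrame
    pls: PLSModel
    q2: float
    permutation: PermutationResult
    selected_bins: pd.DataFrame
    volcano_table: pd.DataFrame
    assignments: pd.DataFrame
    supported: pd.DataFrame


def discovery_run(
    cfg: SimConfig,
    lib: MetaboliteLibrary | None = None,
    n_components: int = 2,
    n_permutations: int = 199,
    loading_threshold: float = 0.0005,
    assign_tolerance: float = 0.01,
    perm_seed: int | None = None,
) -> DiscoveryResult:
    """Run the whole discovery pipeline on one simulated cohort."""
    lib = lib or default_library()
    spectra, design, _truth = simulate_cohort(cfg, lib)
    X = preprocess_cohort(spectra, design)
    pca = pca_fit(X, n_components=2)
    outliers = hotelling_outliers(pca, alpha=0.05)
    pls = plsda_fit(X, n_components=n_components)
    q2 = loo_q2(X, n_components=n_components)
    pls = replace(pls, q2=q2)
    perm = permutation_test_q2(
        X,
        n_components=n_components,
        n_permutations=n_permutations,
        seed=cfg.seed + 1 if perm_seed is None else perm_seed,
        design=X.design,
    )
    selected = select_biomarkers_by_loading(pls, threshold=loading_threshold)
    vol = volcano(X)
    sig = vol[vol["significant"]]
    assignments = assign_shifts(sig["ppm"].to_numpy(), lib, assign_tolerance) \
        if len(sig) else assign_shifts(np.array([]), lib, assign_tolerance)[0:0]
    supported = supported_metabolites(sig if len(sig) else vol.iloc[0:0],
                                      lib, assign_tolerance)
    return DiscoveryResult(
        matrix=X,
        pca_outliers=outliers,
        pls=pls,
        q2=q2,
        permutation=perm,
        selected_bins=selected,
        volcano_table=vol,
        assignments=assignments,
        supported=supported,
    )


def hippurate_bin_mask(
    ppms: np.ndarray,
    lib: MetaboliteLibrary | None = None,
    tolerance: float = 0.015,
) -> np.ndarray:
    """Boolean mask of bins lying within ``tolerance`` of a hippurate shift."""
    lib = lib or default_library()
    shifts = np.asarray(lib.shifts("Hippurate"))
    ppms = np.asarray(ppms, dtype=float)
    return (np.abs(ppms[:, None] - shifts[None, :]) <= tolerance).any(axis=1)


def _study_config(seed: int, n_points: int, effects: dict[str, float]) -> SimConfig:
    return SimConfig(n_points=n_points, effects=effects, seed=seed)


def parameter_recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    n_points: int = 8192,
    n_permutations: int = 99,
    n_components: int = 2,
    q2_threshold: float = 0.4,
    p_threshold: float = 0.05,
    top_k: int = 10,
    effects: dict[str, float] | None = None,
    lib: MetaboliteLibrary | None = None,
) -> pd.DataFrame:
    """Replicate recovery of the injected treatment effects.

    Each replicate simulates a fresh 32-sample crossover cohort with the
    study-magnitude fold changes, and records the LOO Q2, the permutation
    p-value and whether a hippurate-resonance bin ranks in the top
    ``top_k`` component-1 loadings.
    """
    lib = lib or default_library()
    effects = default_effects() if effects is None else effects
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(2 * n_replicates) % (2**31)]
    rows = []
    for r in range(n_replicates):
        cfg = _study_config(rep_seeds[2 * r], n_points, effects)
        spectra, design, _ = simulate_cohort(cfg, lib)
        X = preprocess_cohort(spectra, design)
        q2 = loo_q2(X, n_components=n_components)
        perm = permutation_test_q2(
            X, n_components=n_components, n_permutations=n_permutations,
            seed=rep_seeds[2 * r + 1], design=X.design,
        )
        pls = plsda_fit(X, n_components=n_components)
        ranked = select_biomarkers_by_loading(pls, threshold=0.0)
        top = ranked.head(top_k)["ppm"].to_numpy()
        hip_top = bool(hippurate_bin_mask(top, lib).any())
        rows.append(
            {
                "replicate": r,
                "q2": q2,
                "perm_p": perm.p_value,
                "q2_pass": q2 >= q2_threshold,
                "perm_pass": perm.p_value < p_threshold,
                "hippurate_in_top": hip_top,
            }
        )
    return pd.DataFrame(rows)


def null_calibration_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_points: int = 8192,
    n_permutations: int = 199,
    n_components: int = 2,
    alpha: float = 0.05,
    lib: MetaboliteLibrary | None = None,
) -> pd.DataFrame:
    """Type-I error of the Q2 permutation test under no treatment effect."""
    lib = lib or default_library()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s) for s in ss.generate_state(2 * n_replicates) % (2**31)]
    rows = []
    for r in range(n_replicates):
        cfg = _study_config(rep_seeds[2 * r], n_points, {})
        spectra, design, _ = simulate_cohort(cfg, lib)
        X = preprocess_cohort(spectra, design)
        perm = permutation_test_q2(
            X, n_components=n_components, n_permutations=n_permutations,
            seed=rep_seeds[2 * r + 1], design=X.design,
        )
        rows.append(
            {"replicate": r, "perm_p": perm.p_value,
             "reject": perm.p_value < alpha}
        )
    return pd.DataFrame(rows)
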