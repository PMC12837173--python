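"""Replicated simulation experiments for statistical calibration and power.

These drive the model-validation studies: type-I error of the temporal
contrast under a null cohort, recovery of planted temporal deficits, and the
age-stratified deficit pattern (a deficit present in young adults but absent
in older ones).  Each experiment simulates cohorts directly on the density
scale (see :func:`octaquant.synthetic.simulate_density_records`) so hundreds
of mixed-model fits stay affordable, and derives every replicate's seed
deterministically from a single base seed.
"""

from __future__ import annotations

import numpy as np

from .stats import age_stratified_analysis, analyze_site
from .synthetic import CohortSimConfig, simulate_density_records


def _replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def temporal_contrast_pvalues(
    cfg: CohortSimConfig,
    n_reps: int,
    base_seed: int,
    alpha_adjusted: bool = False,
) -> np.ndarray:
    """Temporal-contrast p-values over simulated cohort replicates."""
    out = np.empty(n_reps)
    col = "p_adjusted" if alpha_adjusted else "p_raw"
    for r, seed in enumerate(_replicate_seeds(base_seed, n_reps)):
        records = simulate_density_records(cfg, "onh", seed=int(seed))
        contrasts = analyze_site(records).contrasts.set_index("quadrant")
        out[r] = contrasts.loc["temporal", col]
    return out


def temporal_null_rejection_rate(
    n_per_group: int = 40,
    n_reps: int = 200,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of null-cohort replicates whose temporal contrast rejects.

    With no planted deficit this estimates the test's type-I error and should
    sit near ``alpha``.
    """
    cfg = CohortSimConfig(n_control=n_per_group, n_ssd=n_per_group,
                          temporal_deficit=0.0)
    p = temporal_contrast_pvalues(cfg, n_reps, base_seed)
    return float((p < alpha).mean())


def temporal_contrast_estimates(
    delta: float,
    n_per_group: int = 40,
    n_reps: int = 30,
    base_seed: int = 0,
) -> np.ndarray:
    """Temporal contrast estimates (control - SSD) across replicates at one delta."""
    cfg = CohortSimConfig(n_control=n_per_group, n_ssd=n_per_group,
                          temporal_deficit=delta)
    out = np.empty(n_reps)
    for r, seed in enumerate(_replicate_seeds(base_seed, n_reps)):
        records = simulate_density_records(cfg, "onh", seed=int(seed))
        contrasts = analyze_site(records).contrasts.set_index("quadrant")
        out[r] = contrasts.loc["temporal", "estimate"]
    return out


def age_pattern_success_rate(
    delta_young: float = 0.3,
    delta_old: float = 0.0,
    n_per_group: int = 45,
    n_reps: int = 50,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates reproducing the young-only deficit pattern.

    Success means the young-stratum temporal contrast is significant while
    the old-stratum one is not, at level ``alpha``.  Stratified headline
    contrasts are judged on their raw p-values: the BH family is the set of
    four quadrant contrasts within a fitted model, not the across-stratum
    comparison.
    """
    cfg = CohortSimConfig(n_control=n_per_group, n_ssd=n_per_group,
                          age_deficit_interaction={"young": delta_young,
                                                   "old": delta_old})
    hits = 0
    for seed in _replicate_seeds(base_seed, n_reps):
        records = simulate_density_records(cfg, "onh", seed=int(seed))
        strat = age_stratified_analysis(records)
        young_p = strat.young.contrasts.set_index("quadrant").loc["temporal", "p_raw"]
        old_p = strat.old.contrasts.set_index("quadrant").loc["temporal", "p_raw"]
        hits += (young_p < alpha) and (old_p >= alpha)
    return hits / n_reps
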