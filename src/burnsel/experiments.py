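"""Canned simulation experiments that exercise the whole pipeline.

These are the study's synthetic validation recipes: ground-truth
parameter recovery on burn-selecting animals, permutation-test
calibration on null tables, and generator/simulator fidelity summaries.
They are used by the test suite and by the reproduction script, and are
runnable directly for exploration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import model as model_mod
from . import synth, telemetry

#: Covariate roster for ground-truth recovery runs: the burn-class
#: fractions the selection acts on (both focal scales) plus terrain and
#: climate covariates.  Canopy cover and burn-edge distance are excluded
#: because the generator derives them from the burn classes themselves,
#: which would make "which covariate drove selection" unidentifiable.
RECOVERY_COVARIATES = [
    "slope", "hli", "cti", "precip", "dist_draw",
    "frac_new_high_s", "frac_new_high_l", "frac_new_low_l",
    "frac_skip_s", "frac_skip_l",
]

#: Mosaic grain (correlation length, m) for recovery runs.  Patches must
#: be finer than the 810 m analysis window; at coarser grain the
#: within-window new-high and skip fractions are near-complementary
#: (|rho| ~ 0.8) and the two generating covariates are statistically
#: confounded, so no error-minimizing selection could retain both.
RECOVERY_BURN_GRAIN_M = 450.0

#: Ground-truth standardized selection strength: avoidance of new
#: high-severity burn and preference for fire skips.
RECOVERY_BETAS = {"frac_new_high_l": -1.5, "frac_skip_l": 1.5}


def recovery_trial(
    seed: int,
    n_trees: int = 200,
    shape: tuple[int, int] = (250, 250),
    n_used: int = 1000,
) -> dict:
    """One parameter-recovery replicate.

    Used points are drawn by point-level habitat selection with known
    coefficients (avoidance of new high-severity burn, preference for
    fire skips, standardized beta = -1.5 / +1.5) within the burn
    perimeter, paired with an equal number of uniform within-burn
    available points (~2 * ``n_used`` rows), and the full
    model-development pipeline is run.  Success means the chosen variable
    set represents both burn classes and, for each class, the selected
    covariate with the highest importance has a partial-dependence slope
    signed like the generating coefficient.
    """
    cl = dict(synth.LandscapeConfig().correlation_lengths)
    cl["burn"] = RECOVERY_BURN_GRAIN_M
    cfg = synth.preset(
        "tripod", seed=(1000 + seed) % (2**31 - 1), shape=shape, correlation_lengths=cl
    )
    stack = synth.build_landscape(cfg)
    burn = stack["burn"]
    perimeter = burn.like((burn.values != 0).astype(np.int16))
    used = telemetry.sample_used_points(
        stack, dict(RECOVERY_BETAS), n_used, seed=(100 + seed) % (2**31 - 1),
        mask=perimeter,
    )
    avail = telemetry.sample_available(perimeter, len(used), seed=seed + 1)
    table = telemetry.build_table(
        used, avail, stack, covariates=RECOVERY_COVARIATES, balance_seed=seed + 2
    )
    result = model_mod.run_burn_model(
        table,
        seed=seed,
        config=model_mod.ModelConfig(n_trees=n_trees, n_permutations=0),
    )
    nh = [v for v in result.selected_vars if v.startswith("frac_new_high")]
    sk = [v for v in result.selected_vars if v.startswith("frac_skip")]

    def lead_sign(group):
        if not group:
            return None
        lead = max(group, key=lambda v: result.importances[v])
        return result.partial_dependence[lead].slope_sign()

    return {
        "selected": result.selected_vars,
        "n_rows": len(table),
        "both_classes_selected": bool(nh and sk),
        "signs_match": bool(nh and sk) and lead_sign(nh) == -1 and lead_sign(sk) == 1,
        "holdout_accuracy": result.holdout_accuracy,
    }


def recovery_rate(n_runs: int = 20, seed: int = 0, n_trees: int = 200) -> dict:
    """Fraction of recovery replicates that identify both burn classes
    with correctly signed effects."""
    trials = [recovery_trial(seed * 1000 + k) for k in range(n_runs)]
    hits = sum(t["signs_match"] for t in trials)
    return {
        "n_runs": n_runs,
        "n_success": hits,
        "rate": hits / n_runs,
        "trials": trials,
    }


def null_table(n: int, p: int, seed: int) -> pd.DataFrame:
    """Balanced table whose labels are independent of its covariates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
    df.insert(0, "used", np.repeat([0, 1], n // 2))
    return df


def permutation_calibration(
    n_datasets: int = 100,
    n: int = 400,
    p: int = 6,
    B: int = 99,
    n_trees: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    engine: str = "hist",
) -> dict:
    """Type-I error of the permutation test on null tables.

    Each replicate dataset has labels independent of its covariates; the
    rejection rate at ``alpha`` should match ``alpha`` up to binomial
    noise when the test is calibrated.
    """
    rejections = 0
    pvals = []
    for k in range(n_datasets):
        df = null_table(n, p, seed=seed * 7919 + k)
        pv, _ = model_mod.permutation_significance(
            df.drop(columns="used"),
            df["used"].to_numpy(),
            n_trees=n_trees,
            B=B,
            seed=(seed + 31 * k) % (2**31 - 1),
            engine=engine,
        )
        pvals.append(pv)
        rejections += pv <= alpha
    return {
        "n_datasets": n_datasets,
        "rejections": rejections,
        "rate": rejections / n_datasets,
        "pvalues": pvals,
    }


def generator_fidelity(seed: int = 0, size: int = 400) -> dict:
    """Achieved within-perimeter burn-class fractions for the tripod
    composition at the stated grid size."""
    cfg = synth.preset("tripod", seed=seed, shape=(size, size))
    burn = synth.generate_burn_mosaic(synth.generate_dem(cfg), cfg)
    return synth.achieved_burn_fractions(burn)


def simulator_fidelity(seed: int = 0, n_steps: int = 2000, size: int = 200) -> dict:
    """Realized fix rate and mean step length of a selection-free animal."""
    cfg = synth.preset("tripod", seed=seed, shape=(size, size))
    stack = synth.build_landscape(cfg, scales=False)
    _, info = telemetry.simulate_track(
        stack, telemetry.MovementConfig(n_steps=n_steps, seed=seed + 1)
    )
    return {
        "fix_rate": info["fix_rate"],
        "mean_step_m": info["mean_step_m"],
        "n_steps": n_steps,
    }
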