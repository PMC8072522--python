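"""Calibration and recovery experiments for the analysis pipeline.

These are the simulation studies that validate the statistical machinery
under the study's conditions: null calibration of the seed-level FDR
selection, recovery of planted aberrant connections, parameter recovery
and type-I error of the treatment-effect model, and the deterministic
signal-processing contracts.  Both the test suite and the acceptance
script drive the same entry points.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import denoise as den_mod
from . import inference as inf_mod
from . import motion as motion_mod
from . import selection as sel_mod
from . import synthdata as sd


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def null_selection_calibration(
    n_reps: int = 100,
    n_per_group: int = 20,
    n_rois: int = 40,
    n_frames: int = 160,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Empirical false-selection rate under identical group distributions.

    Both groups share one correlation template; any selected connection is
    a false selection.  Returns the rate over all tested pairs pooled
    across replicates (nominal target: at most about the seed-level alpha).
    """
    n_false = 0
    n_tested = 0
    for s in _child_seeds(seed, n_reps):
        simd = sd.simulate_group_matrices(
            n_per_group, n_per_group, n_rois, n_frames, rng=np.random.default_rng(s)
        )
        res = sel_mod.test_all_connections(
            simd["z_stack"], simd["groups"], simd["mean_fd"]
        )
        selected, _ = sel_mod.seed_level_fdr(res["p"], alpha=alpha)
        ii, jj = np.triu_indices(n_rois, k=1)
        tested = np.isfinite(res["p"][ii, jj])
        n_false += int(selected[ii, jj][tested].sum())
        n_tested += int(tested.sum())
    return {
        "false_selection_rate": n_false / n_tested,
        "n_pairs_tested": n_tested,
        "n_reps": n_reps,
        "alpha": alpha,
    }


PLANTED_PAIRS = [(0, 1), (2, 3), (4, 6), (5, 7), (8, 10)]


def planted_recovery(
    n_reps: int = 50,
    n_per_group: int = 15,
    n_rois: int = 40,
    n_frames: int = 160,
    shift: float = -0.6,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Recovery of five planted hypo-connections (stroke < healthy).

    A replicate succeeds when at least 4 of the 5 planted pairs are
    selected with the correct hypo label.
    """
    pairs = [(i, j, shift) for i, j in PLANTED_PAIRS]
    successes = 0
    total_hits = 0
    for s in _child_seeds(seed + 1, n_reps):
        simd = sd.simulate_group_matrices(
            n_per_group,
            n_per_group,
            n_rois,
            n_frames,
            group1_shifts=pairs,
            rng=np.random.default_rng(s),
        )
        res = sel_mod.test_all_connections(
            simd["z_stack"], simd["groups"], simd["mean_fd"]
        )
        selected, _ = sel_mod.seed_level_fdr(res["p"], alpha=alpha)
        hits = sum(
            1
            for i, j in PLANTED_PAIRS
            if selected[i, j] and res["coefficient"][i, j] < 0
        )
        total_hits += hits
        successes += hits >= 4
    return {
        "success_fraction": successes / n_reps,
        "mean_pairs_recovered": total_hits / n_reps,
        "n_reps": n_reps,
    }


def treatment_effect_recovery(
    n_reps: int = 200,
    true_difference: float = -0.15,
    seed: int = 0,
) -> dict:
    """Bias and 95% CI coverage for a planted between-arm change difference."""
    estimates = []
    covered = 0
    for s in _child_seeds(seed + 2, n_reps):
        tidy = sd.simulate_index_cohort(
            arm_difference=true_difference, rng=np.random.default_rng(s)
        )
        eff = inf_mod.treatment_effect(tidy)
        estimates.append(eff.estimate)
        q = stats.t.ppf(0.975, eff.df)
        covered += (
            eff.estimate - q * eff.se <= true_difference <= eff.estimate + q * eff.se
        )
    mean_est = float(np.mean(estimates))
    return {
        "mean_estimate": mean_est,
        "bias": mean_est - true_difference,
        "coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def treatment_effect_type_i(n_reps: int = 200, seed: int = 0) -> dict:
    """Rejection rate at p < 0.05 for null cohorts (no arm difference)."""
    rejections = 0
    for s in _child_seeds(seed + 3, n_reps):
        tidy = sd.simulate_index_cohort(
            arm_difference=0.0, rng=np.random.default_rng(s)
        )
        eff = inf_mod.treatment_effect(tidy)
        rejections += eff.p < 0.05
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def signal_processing_contracts(n_frames: int = 250, tr: float = 1.7) -> dict:
    """Deterministic filter/FD/scrubbing contract numbers."""
    t = np.arange(n_frames) * tr
    inband = np.sin(2 * np.pi * 0.03 * t)
    outband = np.sin(2 * np.pi * 0.2 * t)
    inband_ratio = float(
        den_mod.bandpass(inband, tr).std() / inband.std()
    )
    filtered_out = den_mod.bandpass(outband, tr)
    attenuation = float(outband.std() / max(filtered_out.std(), 1e-300))

    params = np.zeros((10, 6))
    params[5:, 3] = 0.01  # 0.01 rad rotation step
    fd_step = float(motion_mod.compute_fd(params)[5])

    rng = np.random.default_rng(0)
    fd = rng.uniform(0, 1, 500)
    gc = rng.uniform(0, 100, 500)
    summary = motion_mod.build_censor_mask(fd, gc)
    exact = bool(
        np.array_equal(summary.censor_mask, (fd > 0.5) | (np.abs(gc) > 50))
    )
    return {
        "inband_amplitude_ratio": inband_ratio,
        "stopband_attenuation": attenuation,
        "fd_rotation_step_mm": fd_step,
        "scrub_mask_matches_definition": exact,
    }
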