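"""Closed-loop validation studies: synthesize, corrupt, solve, score.

This module packages the standard parameter-recovery protocol:

* **noiseless arm** — sample ground-truth pRFs for each model, synthesize
  BOLD for the nine-run spatiotemporal design with the default HRF, solve
  with the same model, and score per-parameter recovery;
* **noisy arm** — the same with composite noise calibrated to 0.1 dB SNR;
* **design-comparison arm** — the noisy CST ground truth re-synthesized
  and re-solved under the four-run toonotopy design.

Problem sizes and optimizer budgets here are the package's desk-scale
defaults (a single CPU solves the full protocol in tens of minutes); the
study conditions themselves — sampling distributions, SNR, design
geometry — are fixed by the synthesizer and stimulus modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import models
from .design import spatiotemporal_sequence, toonotopy_sequence
from .evaluate import RecoveryReport, recovery_report
from .hrf import default_hrf
from .solver import FineSearchSpec, GridSpec, build_engine, solve_voxels, variance_explained
from .synth import GroundTruthSet, NoiseSpec, add_noise, sample_spatial, sample_ground_truth, synthesize_bold

MODEL_KINDS = ("spatial", "cst", "dnst")

# Fine-search budgets: noiseless solves are pushed to high precision
# (recovery should be limited by the method, not the optimizer); noisy
# solves stop earlier because the noise floor dominates.
NOISELESS_FINE = {
    "spatial": FineSearchSpec(maxfev=150, polish_maxfev=200),
    "cst": FineSearchSpec(maxfev=250, polish_maxfev=350),
    "dnst": FineSearchSpec(maxfev=300, polish_maxfev=450),
}
NOISY_FINE = {
    "spatial": FineSearchSpec(maxfev=150, polish_maxfev=200,
                              polish_double=False),
    "cst": FineSearchSpec(maxfev=150, polish_maxfev=200,
                          polish_double=False),
    "dnst": FineSearchSpec(maxfev=150, polish_maxfev=200,
                           polish_double=False),
}


def _subseeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class RecoveryArm:
    """One model's simulate-and-solve result."""

    model_kind: str
    gt: GroundTruthSet
    clean: np.ndarray                  # (n_samples, n_voxels)
    data: np.ndarray                   # clean or noisy
    solved: list
    report: RecoveryReport
    gt_pred_r2: np.ndarray = field(default=None)

    def mape(self, name: str) -> float:
        return self.report.mape(name)


def run_recovery_arm(
    model_kind: str,
    stim,
    n_voxels: int,
    gt_seed: int,
    noise_seed: int | None = None,
    solve_seed: int = 0,
    snr_db: float | None = 0.1,
    shared_spatial=None,
    gt: GroundTruthSet | None = None,
    fine: FineSearchSpec | None = None,
    grid: GridSpec | None = None,
) -> RecoveryArm:
    """Sample (or reuse) ground truth, synthesize, optionally add noise,
    solve, and report recovery.  ``snr_db=None`` keeps the data noiseless."""
    hrf = default_hrf()
    engine = build_engine(stim, model_kind, hrf)
    gt = gt or sample_ground_truth(model_kind, n_voxels, seed=gt_seed,
                                   shared_spatial=shared_spatial)
    clean = synthesize_bold(gt, stim, engine=engine)
    run_breaks_s = stim.run_breaks // int(round(1000.0 / stim.dt_ms))
    if snr_db is None:
        data = clean
    else:
        data = add_noise(clean, NoiseSpec(target_snr_db=snr_db),
                         run_breaks_s, seed=noise_seed)
    if fine is None:
        fine = (NOISELESS_FINE if snr_db is None else NOISY_FINE)[model_kind]
    solved = solve_voxels(data, stim, model_kind, grid=grid, fine=fine,
                          hrf=hrf, seed=solve_seed, engine=engine)
    report = recovery_report(solved, gt)
    r2 = np.array([
        variance_explained(clean[:, i], data[:, i])
        for i in range(clean.shape[1])
    ])
    return RecoveryArm(model_kind, gt, clean, data, solved, report, r2)


def noiseless_recovery_study(seed: int, n_voxels: int = 30) -> dict[str, RecoveryArm]:
    """Noiseless nine-run recovery for all three models (shared spatial
    ground truth)."""
    s = _subseeds(seed, 4)
    stim = spatiotemporal_sequence(n_runs=9, seed=s[0])
    spatial = sample_spatial(n_voxels, np.random.default_rng(s[1]))
    return {
        kind: run_recovery_arm(kind, stim, n_voxels, gt_seed=s[2],
                               snr_db=None, shared_spatial=spatial,
                               solve_seed=s[3])
        for kind in MODEL_KINDS
    }


def noisy_recovery_study(
    seed: int, n_voxels: int = 50, snr_db: float = 0.1
) -> dict[str, RecoveryArm]:
    """Noisy (0.1 dB SNR) nine-run recovery for all three models."""
    s = _subseeds(seed, 5)
    stim = spatiotemporal_sequence(n_runs=9, seed=s[0])
    spatial = sample_spatial(n_voxels, np.random.default_rng(s[1]))
    return {
        kind: run_recovery_arm(kind, stim, n_voxels, gt_seed=s[2],
                               noise_seed=s[3] + i, snr_db=snr_db,
                               shared_spatial=spatial, solve_seed=s[4])
        for i, kind in enumerate(MODEL_KINDS)
    }


def toonotopy_comparison_arm(
    seed: int,
    gt: GroundTruthSet,
    snr_db: float = 0.1,
    n_runs: int = 4,
) -> RecoveryArm:
    """Solve an existing CST ground-truth set under the toonotopy design."""
    s = _subseeds(seed, 3)
    stim = toonotopy_sequence(n_runs=n_runs)
    return run_recovery_arm("cst", stim, gt.n_voxels, gt_seed=0,
                            noise_seed=s[1], snr_db=snr_db, gt=gt,
                            solve_seed=s[2])


# ---------------------------------------------------------------------------
# Headline quantities
# ---------------------------------------------------------------------------

def worst_recovery_accuracy_pct(arms: dict[str, RecoveryArm]) -> float:
    """min over models and parameters of (100 - median APE)."""
    return min(
        100.0 - arm.mape(name)
        for arm in arms.values()
        for name in models.free_param_names(arm.model_kind)
    )


def worst_center_mape_pct(arms: dict[str, RecoveryArm]) -> float:
    return max(
        max(arm.mape("x"), arm.mape("y")) for arm in arms.values()
    )


def worst_sigma_mape_pct(arms: dict[str, RecoveryArm]) -> float:
    return max(arm.mape("sigma") for arm in arms.values())


def cst_tau_error_ms(arms: dict[str, RecoveryArm],
                     reference_ms: float = 200.0) -> float:
    """Median tau APE expressed in ms at a reference time scale."""
    return arms["cst"].mape("tau") / 100.0 * reference_ms


def mean_gt_prediction_r2(arms: dict[str, RecoveryArm]) -> float:
    """Mean variance explained of the noiseless ground-truth prediction
    against its noisy series, pooled across models."""
    return float(np.concatenate(
        [arm.gt_pred_r2 for arm in arms.values()]
    ).mean())
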