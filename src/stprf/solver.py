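"""Two-stage coarse-to-fine pRF parameter estimation.

Stage 1 enumerates a grid of spatial parameters (with fixed default
temporal parameters and, for CST, a small grid of compressive exponents),
scoring each point by the variance explained with GLM-estimated gains.
Stage 2 runs a bounded derivative-free local search (Nelder-Mead on
box-normalized parameters) over *all* model parameters simultaneously,
from three initializations: the grid solution with default temporal
parameters, and two with randomized temporal parameters.  The best
restart by variance explained wins, followed by a short polish from that
point.

Variance explained is ``R^2 = 1 - sum((model - data)^2) / sum(data^2)``
— residual sum of squares over the *raw* (not mean-centered) sum of
squares of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import models
from ._engine import ModelEngine
from .design import StimulusSequence
from .exceptions import ParameterError, ShapeError
from .hrf import default_hrf
from .models import (
    CST_N_BOUNDS,
    CST_TAU_BOUNDS,
    DNST_N_BOUNDS,
    DNST_SIGMA_BOUNDS,
    DNST_TAU1_BOUNDS,
    DNST_TAU2_BOUNDS,
    PRFParams,
    free_param_names,
)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Grid-search stage specification.

    Defaults materialize the full published grid: x/y spanning the
    24 deg stimulus extent in corner-origin coordinates (0..24 deg, 0.4
    deg steps, i.e., -12..+12 deg around fixation), sigma log-linearly
    sampled with 96 steps in [0.1, 12] deg, CST exponent grid
    {0.25, 0.5, 0.75, 1}, and fixed default temporal parameters
    (CST tau = 4.93 samples; DN-ST tau1 = 0.05 s, tau2 = 0.1 s,
    n = 2, sigma = 0.1).  That grid has ~1.4M points for CST;
    :meth:`coarse` gives a reduced desk-scale grid with the same
    structure and bounds.
    """

    xy_min_deg: float = 0.0
    xy_max_deg: float = 24.0
    xy_step_deg: float = 0.4
    sigma_min_deg: float = 0.1
    sigma_max_deg: float = 12.0
    sigma_steps: int = 96
    n_grid: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    cst_tau: float = 4.93
    # (tau1 s, tau2 s, n, sigma)
    dnst_defaults: tuple[float, float, float, float] = (0.05, 0.1, 2.0, 0.1)

    def x_values(self) -> np.ndarray:
        """Grid x positions in fixation-centered coordinates (deg)."""
        half = (self.xy_max_deg - self.xy_min_deg) / 2.0
        n = int(round((self.xy_max_deg - self.xy_min_deg) / self.xy_step_deg)) + 1
        return np.linspace(-half, half, n)

    y_values = x_values

    def sigma_values(self) -> np.ndarray:
        return np.geomspace(self.sigma_min_deg, self.sigma_max_deg,
                            self.sigma_steps)

    @classmethod
    def coarse(cls, xy_step_deg: float = 2.0, sigma_steps: int = 10) -> "GridSpec":
        """Reduced grid for CPU-scale solving (same ranges, fewer points)."""
        return cls(xy_step_deg=xy_step_deg, sigma_steps=sigma_steps)


@dataclass(frozen=True)
class FineSearchSpec:
    """Fine-search stage specification.

    Spatial parameters are bounded to +/- 5 deg around the grid estimate;
    model-specific temporal bounds are the published search ranges.
    ``maxfev`` is the function-evaluation budget per restart; after the
    restarts, the best point is polished with a ``polish_maxfev`` budget.
    """

    n_restarts: int = 3
    spatial_halfwidth_deg: float = 5.0
    maxfev: int = 250
    polish_maxfev: int = 300
    xatol: float = 1e-4
    fatol: float = 1e-9
    polish_step: float = 0.02
    # double-precision polish resolves parameters below the single-
    # precision objective noise; worth skipping when a noise floor
    # dominates the fit anyway
    polish_double: bool = True
    seed: int | None = None

    def bounds(self, model_kind: str, coarse_theta: np.ndarray) -> list[tuple[float, float]]:
        hw = self.spatial_halfwidth_deg
        x0, y0, s0 = coarse_theta[:3]
        b = [
            (x0 - hw, x0 + hw),
            (y0 - hw, y0 + hw),
            (max(s0 - hw, 0.01), s0 + hw),
        ]
        if model_kind == "cst":
            b += [CST_TAU_BOUNDS, CST_N_BOUNDS]
        elif model_kind == "dnst":
            b += [DNST_TAU1_BOUNDS, DNST_TAU2_BOUNDS,
                  DNST_SIGMA_BOUNDS, DNST_N_BOUNDS]
        return b


@dataclass
class SolveResult:
    """Per-voxel solution: parameters, fit quality, and diagnostics."""

    params: PRFParams
    r2_train: float
    r2_cv: float | None = None
    hrf_used: str = "default"
    converged: bool = True
    restarts: list = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    voxel_id: str = "v0"

    @property
    def model_kind(self) -> str:
        return models.model_kind_of(self.params)


# ---------------------------------------------------------------------------
# Variance explained and betas
# ---------------------------------------------------------------------------

def variance_explained(pred: np.ndarray, data: np.ndarray) -> float:
    """R^2 = 1 - RSS / sum(data^2); NaN when the data are all zero."""
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    if pred.shape != data.shape:
        raise ShapeError(f"pred {pred.shape} != data {data.shape}")
    denom = float(data @ data)
    if denom <= 0.0:
        return np.nan
    resid = data - pred
    return 1.0 - float(resid @ resid) / denom


def estimate_betas(predictors: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Ordinary least squares channel gains (sign-unconstrained).

    ``predictors``: (n_regressors, n_samples) HRF-convolved 1 s channel
    predictions.  Falls back to a tiny ridge penalty with a warning when
    the predictors are collinear.
    """
    X = np.atleast_2d(np.asarray(predictors, dtype=float))
    y = np.asarray(data, dtype=float)
    if X.shape[1] != len(y):
        raise ShapeError(f"predictors {X.shape} vs data {y.shape}")
    G = X @ X.T
    if np.linalg.matrix_rank(G) < G.shape[0]:
        warnings.warn("collinear predictors; using ridge fallback")
        G = G + 1e-8 * np.eye(G.shape[0]) * max(np.trace(G), 1.0)
    return np.linalg.solve(G, X @ y)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def build_engine(
    stim: StimulusSequence, model_kind: str, hrf: np.ndarray | None = None
) -> ModelEngine:
    return ModelEngine(stim, model_kind, default_hrf() if hrf is None else hrf)


def grid_search(
    bold: np.ndarray,
    stim: StimulusSequence,
    model_kind: str,
    grid: GridSpec | None = None,
    hrf: np.ndarray | None = None,
    engine: ModelEngine | None = None,
    bank: dict | None = None,
):
    """Stage-1 exhaustive search; returns (theta, r2) per voxel.

    ``bold`` is (n_samples,) for one voxel or (n_samples, n_voxels).
    Pass a prebuilt ``engine``/``bank`` to share work across many voxels.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 1 and not np.any(bold):
        return None, {"degenerate_voxel": True}
    engine = engine or build_engine(stim, model_kind, hrf)
    bank = bank or engine.grid_bank(grid or GridSpec.coarse())
    return engine.grid_score(bank, bold)


# ---------------------------------------------------------------------------
# Fine search
# ---------------------------------------------------------------------------

def _theta_to_params(model_kind: str, theta, betas) -> PRFParams:
    sp = models.SpatialParams(*map(float, theta[:3]))
    if model_kind == "spatial":
        return sp
    if model_kind == "cst":
        return models.CSTParams(sp, float(theta[3]), float(theta[4]),
                                beta_sus=float(betas[0]),
                                beta_tran=float(betas[1]))
    return models.DNSTParams(sp, float(theta[3]), float(theta[4]),
                             float(theta[5]), float(theta[6]),
                             beta=float(betas[0]))


def fine_search(
    bold: np.ndarray,
    stim: StimulusSequence,
    model_kind: str,
    coarse_theta: np.ndarray,
    spec: FineSearchSpec | None = None,
    hrf: np.ndarray | None = None,
    engine: ModelEngine | None = None,
    polish_engine: ModelEngine | None = None,
    rng: np.random.Generator | None = None,
    voxel_id: str = "v0",
) -> SolveResult:
    """Stage-2 bounded local search over all model parameters.

    Nelder-Mead operates on parameters affinely rescaled to the unit box
    so every coordinate has comparable step sizes; betas are profiled out
    by OLS inside the objective.
    """
    spec = spec or FineSearchSpec()
    engine = engine or build_engine(stim, model_kind, hrf)
    rng = rng or np.random.default_rng(spec.seed)
    data = np.asarray(bold, dtype=float)
    names = free_param_names(model_kind)
    coarse_theta = np.asarray(coarse_theta, dtype=float)
    bounds = np.array(spec.bounds(model_kind, coarse_theta))
    lo, span = bounds[:, 0], bounds[:, 1] - bounds[:, 0]

    def unscale(u):
        return lo + np.clip(u, 0.0, 1.0) * span

    def objective(u):
        r2, _ = engine.r2(unscale(u), data)
        return -r2

    grid_defaults = {
        "cst": np.array([GridSpec.cst_tau, 0.5]),
        "dnst": np.array([0.05, 0.1, 0.1, 2.0]),
        "spatial": np.array([]),
    }[model_kind]

    inits = []
    base = coarse_theta[: len(names)].copy()
    if model_kind == "cst" and len(coarse_theta) >= 5:
        # grid already chose tau (fixed) and n
        inits.append(base)
    elif model_kind == "dnst" and len(coarse_theta) >= 7:
        inits.append(base)
    else:
        inits.append(np.concatenate([coarse_theta[:3], grid_defaults]))
    # randomized restarts: Latin-hypercube strata over the temporal
    # parameters so the restarts jointly cover their ranges
    n_rand = max(spec.n_restarts - 1, 0)
    n_temporal = len(names) - 3
    if n_rand and n_temporal:
        strata = np.stack(
            [rng.permutation(n_rand) for _ in range(n_temporal)], axis=1
        )
        for j in range(n_rand):
            frac = (strata[j] + rng.random(n_temporal)) / n_rand
            extra = lo[3:] + frac * span[3:]
            inits.append(np.concatenate([coarse_theta[:3], extra]))
    # duplicate inits (e.g. the spatial model has no temporal parameters
    # to randomize) would repeat identical searches; drop them
    uniq, seen = [], set()
    for th in inits:
        key = tuple(np.round(th, 12))
        if key not in seen:
            seen.add(key)
            uniq.append(th)
    inits = uniq

    restarts = []
    best_u, best_f = None, np.inf
    nm_opts = {"maxfev": spec.maxfev, "xatol": spec.xatol,
               "fatol": spec.fatol, "adaptive": len(names) > 4}
    unit_bounds = [(0.0, 1.0)] * len(names)
    for i, theta0 in enumerate(inits):
        u0 = np.clip((theta0 - lo) / span, 0.0, 1.0)
        res = minimize(objective, u0, method="Nelder-Mead",
                       bounds=unit_bounds, options=nm_opts)
        restarts.append({"init": theta0.tolist(), "r2": -float(res.fun),
                         "nfev": int(res.nfev)})
        if res.fun < best_f:
            best_f, best_u = res.fun, res.x

    # polish from the winner, starting from a small simplex so the final
    # parameters are resolved finely around the best restart
    if not spec.polish_double:
        polish_engine = engine
    elif polish_engine is None:
        polish_engine = ModelEngine(stim, model_kind, engine.hrf,
                                    dtype=np.float64)

    def objective64(u):
        r2, _ = polish_engine.r2(unscale(u), data)
        return -r2

    step = spec.polish_step
    simplex = np.vstack([best_u] * (len(names) + 1))
    for k in range(len(names)):
        simplex[k + 1, k] = np.clip(
            best_u[k] + (step if best_u[k] < 0.5 else -step), 0.0, 1.0
        )
    res = minimize(objective64, best_u, method="Nelder-Mead",
                   bounds=unit_bounds,
                   options={"maxfev": spec.polish_maxfev,
                            "xatol": spec.xatol / 10, "fatol": 1e-12,
                            "adaptive": len(names) > 4,
                            "initial_simplex": simplex})
    best_f64 = objective64(best_u)
    if res.fun < best_f64:
        best_f64, best_u = res.fun, res.x

    theta = unscale(best_u)
    reg = polish_engine.regressors(theta)
    betas, r2 = polish_engine.fit_betas(reg, data)
    converged = np.isfinite(r2)
    params = _theta_to_params(model_kind, theta, betas)
    flags = {}
    if np.isfinite(r2) and r2 < 0.10:
        flags["low_r2"] = True
    if model_kind == "cst" and theta[3] >= CST_TAU_BOUNDS[1] * 0.999:
        flags["tau_at_bound"] = True
    return SolveResult(params=params, r2_train=float(r2),
                       converged=bool(converged), restarts=restarts,
                       flags=flags, voxel_id=voxel_id)


# ---------------------------------------------------------------------------
# High-level drivers
# ---------------------------------------------------------------------------

def solve_voxels(
    bold: np.ndarray,
    stim: StimulusSequence,
    model_kind: str,
    grid: GridSpec | None = None,
    fine: FineSearchSpec | None = None,
    hrf: np.ndarray | None = None,
    seed: int | None = 0,
    voxel_ids=None,
    engine: ModelEngine | None = None,
    bank: dict | None = None,
) -> list[SolveResult]:
    """Grid + fine search for a (n_samples, n_voxels) BOLD matrix.

    The grid bank is built once and shared by all voxels; fine-search
    restart randomization derives per-voxel streams from ``seed``.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 1:
        bold = bold[:, None]
    n_vox = bold.shape[1]
    grid = grid or GridSpec.coarse()
    fine = fine or FineSearchSpec()
    engine = engine or build_engine(stim, model_kind, hrf)
    polish_engine = (
        ModelEngine(stim, model_kind, engine.hrf, dtype=np.float64)
        if fine.polish_double else engine
    )
    bank = bank or engine.grid_bank(grid)
    thetas, _ = engine.grid_score(bank, bold)
    seeds = np.random.SeedSequence(seed).spawn(n_vox)
    ids = voxel_ids or [f"v{i:04d}" for i in range(n_vox)]
    out = []
    for i in range(n_vox):
        if not np.any(bold[:, i]):
            out.append(SolveResult(
                params=models.SpatialParams(0.0, 0.0, 1.0),
                r2_train=np.nan, converged=False,
                flags={"degenerate_voxel": True}, voxel_id=ids[i]))
            continue
        out.append(fine_search(
            bold[:, i], stim, model_kind, thetas[i], spec=fine,
            engine=engine, polish_engine=polish_engine,
            rng=np.random.default_rng(seeds[i]), voxel_id=ids[i]))
    return out


def threefold_runs(n_runs: int) -> list[tuple[list[int], list[int]]]:
    """(train, test) run-index partitions for threefold cross-validation."""
    if n_runs % 3 != 0:
        raise ParameterError(
            f"{n_runs} runs do not split into three folds; pass explicit folds"
        )
    per = n_runs // 3
    folds = []
    for f in range(3):
        test = list(range(f * per, (f + 1) * per))
        train = [r for r in range(n_runs) if r not in test]
        folds.append((train, test))
    return folds


def crossvalidate(
    bold: np.ndarray,
    stim: StimulusSequence,
    model_kind: str,
    grid: GridSpec | None = None,
    fine: FineSearchSpec | None = None,
    hrf: np.ndarray | None = None,
    seed: int | None = 0,
    folds: list[tuple[list[int], list[int]]] | None = None,
) -> np.ndarray:
    """Mean held-out variance explained per voxel (threefold by default).

    Each fold fits on six concatenated runs and evaluates Eq.-style R^2 on
    the held-out three runs; folds are averaged.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim == 1:
        bold = bold[:, None]
    folds = folds or threefold_runs(stim.n_runs)
    bin_frames = int(round(1000.0 / stim.dt_ms))
    run_bins = [
        (sl.stop - sl.start) // bin_frames for sl in stim.run_slices()
    ]
    edges = np.concatenate([[0], np.cumsum(run_bins)])

    def rows(run_idx):
        return np.concatenate(
            [np.arange(edges[r], edges[r + 1]) for r in run_idx]
        )

    r2_folds = np.zeros((len(folds), bold.shape[1]))
    for f, (train, test) in enumerate(folds):
        stim_tr = stim.subset_runs(train)
        stim_te = stim.subset_runs(test)
        results = solve_voxels(bold[rows(train)], stim_tr, model_kind,
                               grid=grid, fine=fine, hrf=hrf, seed=seed)
        eng_te = build_engine(stim_te, model_kind, hrf)
        data_te = bold[rows(test)]
        for i, res in enumerate(results):
            pred = eng_te.predict_bold(res.params)
            r2_folds[f, i] = variance_explained(pred, data_te[:, i])
    return r2_folds.mean(axis=0)
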