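"""Recovery metrics, model comparison, and spatiotemporal pRF summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .exceptions import ParameterError, ShapeError
from .models import CSTParams, sustained_irf
from .synth import GroundTruthSet


@dataclass
class RecoveryReport:
    """Per-parameter recovery accuracy of a solved set vs. ground truth."""

    model_kind: str
    table: pd.DataFrame      # index: parameter; columns: mape_pct, pearson_r
    n_voxels: int
    outlier_policy: str = "none"

    def mape(self, name: str) -> float:
        return float(self.table.loc[name, "mape_pct"])

    def pearson(self, name: str) -> float:
        return float(self.table.loc[name, "pearson_r"])


# ---------------------------------------------------------------------------
# Error metrics
# ---------------------------------------------------------------------------

def absolute_percentage_errors(estimates, truths) -> np.ndarray:
    """100 * |est - truth| / |truth| per pair; NaN where truth is zero."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape:
        raise ShapeError(f"estimates {est.shape} != truths {tru.shape}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ape = 100.0 * np.abs(est - tru) / np.abs(tru)
    ape[tru == 0] = np.nan
    return ape


def mape(estimates, truths, trim_above_pct: float | None = None) -> float:
    """Median absolute percentage error.

    Pairs with zero ground truth are undefined and excluded (they are
    reported separately by :func:`recovery_report`).  With
    ``trim_above_pct`` (e.g. 90), errors beyond that percentile are
    dropped before taking the median — a display convention; headline
    medians use the untrimmed errors, on which the median is already
    robust.
    """
    ape = absolute_percentage_errors(estimates, truths)
    ape = ape[np.isfinite(ape)]
    if ape.size == 0:
        return np.nan
    if trim_above_pct is not None:
        ape = ape[ape <= np.percentile(ape, trim_above_pct)]
    return float(np.median(ape))


def recovery_report(
    solved,
    gt: GroundTruthSet,
    trim_above_pct: float | None = None,
) -> RecoveryReport:
    """Per-parameter MAPE and Pearson r for a solved voxel set.

    ``solved`` is a list of :class:`stprf.solver.SolveResult` (or of
    parameter objects) aligned with ``gt.params``.
    """
    if len(solved) != gt.n_voxels:
        raise ShapeError(
            f"{len(solved)} solutions for {gt.n_voxels} ground-truth voxels"
        )
    names = models.free_param_names(gt.model_kind)
    est_rows = [
        models.params_to_dict(getattr(s, "params", s)) for s in solved
    ]
    tru_rows = [models.params_to_dict(p) for p in gt.params]
    rows = {}
    for name in names:
        est = np.array([r[name] for r in est_rows])
        tru = np.array([r[name] for r in tru_rows])
        finite = np.abs(tru) > 0
        r = (
            np.corrcoef(est[finite], tru[finite])[0, 1]
            if finite.sum() > 1 else np.nan
        )
        rows[name] = {
            "mape_pct": mape(est, tru, trim_above_pct),
            "pearson_r": float(r),
            "n_undefined": int((~finite).sum()),
        }
    policy = (
        f"trimmed>{trim_above_pct}th pct" if trim_above_pct else "none"
    )
    return RecoveryReport(gt.model_kind, pd.DataFrame(rows).T,
                          gt.n_voxels, policy)


# ---------------------------------------------------------------------------
# Temporal windows and averaged spatiotemporal profiles
# ---------------------------------------------------------------------------

def temporal_window_fwhm(params: CSTParams | float, dt_ms: float = 10.0) -> float:
    """FWHM of the sustained temporal impulse response, in ms.

    Accepts CST parameters or a bare tau (model samples).  The gamma's
    self-similarity makes the FWHM exactly linear in tau; it is measured
    on a finely upsampled kernel.
    """
    tau = params.tau if isinstance(params, CSTParams) else float(params)
    if not tau > 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    # evaluate the continuous gamma at fine resolution (0.1 sample steps)
    up = 10
    t = (np.arange(int(np.ceil(5 * 9 * tau * up))) + 0.5) / up
    h = (t / tau) ** 8 * np.exp(-t / tau)
    half = h.max() / 2.0
    above = np.flatnonzero(h >= half)
    return float((above[-1] - above[0] + 1) / up * dt_ms)


@dataclass
class SpatiotemporalProfile:
    """Zero-centered average spatiotemporal pRF cross-section.

    ``profile[i, j]`` is the product of the spatial cross-section at
    position ``space_deg[i]`` with the temporal impulse response at
    ``time_ms[j]``, averaged across voxels after shifting every pRF to
    x = y = 0.
    """

    profile: np.ndarray
    space_deg: np.ndarray
    time_ms: np.ndarray
    channel: str
    n_voxels: int
    zero_centered: bool = True


def average_strf(
    params_list,
    channel: str = "sustained",
    space_halfwidth_deg: float = 6.0,
    n_space: int = 121,
    t_max_ms: float = 1000.0,
    dt_ms: float = 10.0,
) -> SpatiotemporalProfile:
    """Average zero-centered spatiotemporal receptive field of CST voxels.

    Each voxel contributes the outer product of its (zero-centered)
    Gaussian spatial cross-section and its sustained or on-transient
    impulse response; the products are averaged pointwise across voxels.
    """
    if channel not in ("sustained", "on_transient"):
        raise ParameterError(f"unsupported channel {channel!r}")
    params_list = list(params_list)
    if not params_list:
        raise ParameterError("empty parameter list")
    space = np.linspace(-space_halfwidth_deg, space_halfwidth_deg, n_space)
    n_t = int(round(t_max_ms / dt_ms))
    acc = np.zeros((n_space, n_t))
    for p in params_list:
        if not isinstance(p, CSTParams):
            raise ParameterError("average_strf expects CST parameters")
        cross = np.exp(-(space**2) / (2.0 * p.spatial.sigma**2))
        if channel == "sustained":
            irf = sustained_irf(p.tau)
        else:
            irf = models.transient_irfs(p.tau)[0]
        tvec = np.zeros(n_t)
        tvec[: min(n_t, len(irf))] = irf[:n_t]
        acc += np.outer(cross, tvec)
    return SpatiotemporalProfile(
        profile=acc / len(params_list),
        space_deg=space,
        time_ms=(np.arange(n_t) + 0.5) * dt_ms,
        channel=channel,
        n_voxels=len(params_list),
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def compare_models_permutation(
    r2_a,
    r2_b,
    n_iter: int = 50_000,
    seed: int | None = 0,
) -> float:
    """Two-sided sign-flip permutation test on paired R^2 differences.

    Exhaustive enumeration of all 2^n sign patterns when that is cheaper
    than ``n_iter`` Monte-Carlo draws; identical inputs give p = 1.
    """
    a = np.asarray(r2_a, dtype=float)
    b = np.asarray(r2_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ShapeError("paired samples required")
    d = a - b
    n = len(d)
    obs = abs(d.mean())
    if n == 0:
        return np.nan
    if 2**n <= n_iter:
        signs = np.array(
            np.meshgrid(*([[-1.0, 1.0]] * n), indexing="ij")
        ).reshape(n, -1)
        perm = np.abs(d @ signs) / n
        return float(np.mean(perm >= obs - 1e-15))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_iter, n))
    perm = np.abs(signs @ d) / n
    # add-one correction keeps Monte-Carlo p-values off zero
    return float((np.sum(perm >= obs - 1e-15) + 1) / (n_iter + 1))


def fdr_correct(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Eccentricity binning
# ---------------------------------------------------------------------------

def bin_by_eccentricity(
    params_list,
    values=None,
    width_deg: float = 2.0,
    max_ecc_deg: float = 12.0,
) -> pd.DataFrame:
    """Per-eccentricity-bin medians of a voxel-wise quantity.

    ``values`` defaults to the temporal window FWHM for CST parameters
    and to sigma otherwise.  Empty bins are reported with count 0 and a
    NaN median.
    """
    params_list = list(params_list)
    spatial = [models.spatial_of(p) for p in params_list]
    ecc = np.array([s.eccentricity for s in spatial])
    if values is None:
        if params_list and isinstance(params_list[0], CSTParams):
            values = [temporal_window_fwhm(p) for p in params_list]
        else:
            values = [s.sigma for s in spatial]
    values = np.asarray(values, dtype=float)
    edges = np.arange(0.0, max_ecc_deg + width_deg, width_deg)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (ecc >= lo) & (ecc < hi)
        rows.append({
            "ecc_lo": lo,
            "ecc_hi": hi,
            "count": int(mask.sum()),
            "median": float(np.median(values[mask])) if mask.any() else np.nan,
        })
    return pd.DataFrame(rows)
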