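"""Hemodynamics: two-gamma HRF, neural-to-BOLD projection, voxel-wise HRF fits.

The HRF is a difference of two gamma densities, each parameterized by its
peak latency and full width at half maximum (FWHM) in seconds.  The
default parameters (peaks 5.4 / 10.9 s, FWHMs 5.2 / 7.35 s) reproduce the
Vistasoft two-gamma HRF; the undershoot's relative amplitude is not part
of that parameterization and defaults to 0.35 (held fixed during
optimization unless explicitly freed).

Predicted neural activity at 10 ms is convolved with the HRF and averaged
within 1 s bins to match the fMRI sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize

from .design import DT_MS, StimulusSequence
from .exceptions import ParameterError, ShapeError, SingularDesignError
from .models import NeuralTimeCourse, convolve_runs


@dataclass(frozen=True)
class HRFParams:
    """Two-gamma HRF parameters (seconds)."""

    peak1_s: float = 5.4
    fwhm1_s: float = 5.2
    peak2_s: float = 10.9
    fwhm2_s: float = 7.35
    undershoot_weight: float = 0.35

    def __post_init__(self) -> None:
        if self.peak1_s <= 0 or self.fwhm1_s <= 0 or self.fwhm2_s <= 0:
            raise ParameterError("HRF peaks and widths must be positive")
        if self.peak2_s <= self.peak1_s:
            raise ParameterError("undershoot peak must follow the main peak")
        if self.undershoot_weight < 0:
            raise ParameterError("undershoot weight must be >= 0")


@dataclass
class VoxelTimeCourse:
    """Percent-signal-change BOLD at 1 s sampling for one voxel."""

    values: np.ndarray
    run_breaks: np.ndarray
    voxel_id: str = "v0"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.run_breaks = np.asarray(self.run_breaks, dtype=int)
        if np.any(np.isnan(self.values)):
            raise ParameterError(f"voxel {self.voxel_id}: NaN samples")


# ---------------------------------------------------------------------------
# Two-gamma construction
# ---------------------------------------------------------------------------

def _gamma_shape_scale(peak_s: float, fwhm_s: float) -> tuple[float, float]:
    """Shape/scale of a gamma density with the given mode and FWHM.

    The mode fixes ``(k - 1) * theta = peak``; the FWHM of the density is
    then a monotone function of the shape ``k`` alone, solved numerically.
    """
    def fwhm_of(k: float) -> float:
        theta = peak_s / (k - 1.0)
        mode = peak_s
        # half-max points solve (k-1) ln(t/mode) - (t-mode)/theta = -ln 2
        def g(t):
            return (k - 1.0) * np.log(t / mode) - (t - mode) / theta + np.log(2.0)
        lo = brentq(g, mode * 1e-8, mode)
        hi = brentq(g, mode, mode * 60.0)
        return hi - lo

    def obj(k):
        return fwhm_of(k) - fwhm_s

    k = brentq(obj, 1.05, 4000.0, xtol=1e-10)
    return k, peak_s / (k - 1.0)


def two_gamma_hrf(
    params: HRFParams | None = None,
    dt_ms: float = DT_MS,
    duration_s: float = 40.0,
) -> np.ndarray:
    """HRF kernel sampled at ``dt_ms``: gamma1 - w * gamma2, peak-normalized.

    Each gamma is scaled to unit peak amplitude before weighting, so
    ``undershoot_weight`` is the undershoot's amplitude relative to the
    main response; the final kernel has maximum 1.
    """
    params = params or HRFParams()
    dt_s = dt_ms / 1000.0
    t = (np.arange(int(round(duration_s / dt_s))) + 0.5) * dt_s

    def unit_peak_gamma(peak, fwhm):
        k, theta = _gamma_shape_scale(peak, fwhm)
        logpdf = (k - 1.0) * np.log(t) - t / theta
        logpdf -= (k - 1.0) * np.log(peak) - peak / theta  # peak value -> 1
        return np.exp(logpdf)

    h = unit_peak_gamma(params.peak1_s, params.fwhm1_s)
    if params.undershoot_weight > 0:
        h = h - params.undershoot_weight * unit_peak_gamma(
            params.peak2_s, params.fwhm2_s
        )
    return h / h.max()


def default_hrf(dt_ms: float = DT_MS) -> np.ndarray:
    """The default (Vistasoft-parameterized) HRF kernel at ``dt_ms``."""
    return two_gamma_hrf(HRFParams(), dt_ms=dt_ms)


# ---------------------------------------------------------------------------
# Neural -> BOLD
# ---------------------------------------------------------------------------

def bold_predictors(
    neural: NeuralTimeCourse | np.ndarray,
    hrf: np.ndarray,
    run_breaks=None,
    dt_ms: float = DT_MS,
    bin_s: float = 1.0,
    mode: str = "mean",
) -> np.ndarray:
    """HRF-convolved, 1 s-resampled regressors, one row per channel group.

    A three-channel (CST) neural time course yields two regressors:
    sustained, and the summed on+off transient.  Other inputs yield one
    regressor per channel.  ``mode="mean"`` averages each 1 s bin (the
    default); ``mode="stride"`` takes every ``bin``-th sample.
    """
    if isinstance(neural, NeuralTimeCourse):
        ch = neural.channels
        dt_ms = neural.dt_ms
    else:
        ch = np.atleast_2d(np.asarray(neural, dtype=float))
    if ch.shape[0] == 3:
        ch = np.stack([ch[0], ch[1] + ch[2]])
    bin_frames = int(round(bin_s * 1000.0 / dt_ms))
    n_bins = ch.shape[1] // bin_frames
    out = np.empty((ch.shape[0], n_bins))
    for i, c in enumerate(ch):
        conv = convolve_runs(c, hrf, run_breaks)
        conv = conv[: n_bins * bin_frames]
        if mode == "mean":
            out[i] = conv.reshape(n_bins, bin_frames).mean(axis=1)
        elif mode == "stride":
            out[i] = conv.reshape(n_bins, bin_frames)[:, 0]
        else:
            raise ParameterError(f"unknown downsampling mode {mode!r}")
    return out


def neural_to_bold(
    neural: NeuralTimeCourse | np.ndarray,
    hrf: np.ndarray,
    betas,
    run_breaks=None,
    dt_ms: float = DT_MS,
    mode: str = "mean",
) -> np.ndarray:
    """Predicted BOLD at 1 s: beta-weighted sum of HRF-convolved regressors."""
    pred = bold_predictors(neural, hrf, run_breaks, dt_ms=dt_ms, mode=mode)
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    if len(betas) != pred.shape[0]:
        raise ShapeError(
            f"{len(betas)} betas for {pred.shape[0]} regressors"
        )
    return betas @ pred


# ---------------------------------------------------------------------------
# Voxel-wise HRF optimization
# ---------------------------------------------------------------------------

def condition_design_matrix(stim: StimulusSequence, bin_s: float = 1.0) -> np.ndarray:
    """Location-by-orientation boxcar design at 1 s (one column per location).

    Codes only *where* the bar is (step x angle), deliberately ignoring the
    within-slot temporal condition, so HRF estimates are not biased toward
    any presentation schedule.  Columns are ordered by aperture index.
    """
    bin_frames = int(round(bin_s * 1000.0 / stim.dt_ms))
    n_bins = stim.n_frames // bin_frames
    n_cond = len(stim.apertures)
    X = np.zeros((n_bins, n_cond))
    for slot in stim.slots:
        a = slot["start"] // bin_frames
        b = (slot["start"] + slot["n_frames"]) // bin_frames
        X[a:b, slot["aperture"]] = 1.0
    return X


def _hrf_at_1s(params: HRFParams, bin_s: float = 1.0) -> np.ndarray:
    h = two_gamma_hrf(params)
    bin_frames = int(round(bin_s * 1000.0 / DT_MS))
    n = len(h) // bin_frames
    return h[: n * bin_frames].reshape(n, bin_frames).mean(axis=1)


def _glm_rss(data, X, hrf_params, run_breaks_s, betas=None):
    h1s = _hrf_at_1s(hrf_params)
    Xc = np.column_stack(
        [convolve_runs(col, h1s, run_breaks_s) for col in X.T]
    )
    if betas is None:
        betas, *_ = np.linalg.lstsq(Xc, data, rcond=None)
    resid = data - Xc @ betas
    return float(resid @ resid), betas


def optimize_voxel_hrf(
    data: VoxelTimeCourse,
    design: np.ndarray,
    init: HRFParams | None = None,
    max_outer: int = 50,
    rtol: float = 1e-4,
) -> HRFParams:
    """Alternating GLM / HRF-shape optimization for one voxel.

    Alternates (a) ordinary least squares for the condition betas given
    the current HRF with (b) a bounded Nelder-Mead update of the four
    latency/width parameters given the betas, until the relative residual
    change falls below ``rtol``.  The undershoot amplitude stays fixed.
    """
    init = init or HRFParams()
    y = data.values
    if design.shape[0] != len(y):
        raise ShapeError(
            f"design has {design.shape[0]} rows, data {len(y)} samples"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("condition design matrix is rank deficient")

    cur = init
    rss, betas = _glm_rss(y, design, cur, data.run_breaks)
    bounds = [(1.0, 12.0), (1.0, 12.0), (4.0, 25.0), (2.0, 20.0)]

    def pack(p: HRFParams):
        return [p.peak1_s, p.fwhm1_s, p.peak2_s, p.fwhm2_s]

    for _ in range(max_outer):
        # (b) HRF-shape step with betas held fixed
        def obj(v):
            if v[2] <= v[0] + 0.5:
                return np.inf
            try:
                p = replace(cur, peak1_s=v[0], fwhm1_s=v[1],
                            peak2_s=v[2], fwhm2_s=v[3])
                return _glm_rss(y, design, p, data.run_breaks, betas)[0]
            except (ParameterError, ValueError):
                return np.inf

        res = minimize(obj, pack(cur), method="Nelder-Mead", bounds=bounds,
                       options={"maxfev": 150, "xatol": 1e-3, "fatol": 1e-10})
        if not np.isfinite(res.fun):
            break
        cand = replace(cur, peak1_s=res.x[0], fwhm1_s=res.x[1],
                       peak2_s=res.x[2], fwhm2_s=res.x[3])
        # (a) refit betas under the candidate HRF; accept only if the
        # jointly refit residual improves (keeps RSS non-increasing)
        cand_rss, cand_betas = _glm_rss(y, design, cand, data.run_breaks)
        if cand_rss >= rss - 1e-15:
            break
        improved = rss - cand_rss
        cur, rss, betas = cand, cand_rss, cand_betas
        if improved <= rtol * max(rss, 1e-12):
            break
    return cur
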