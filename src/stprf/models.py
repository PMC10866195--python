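"""Image-computable pRF forward models: Spatial, CST, and DN-ST.

All three models share a 2D isotropic Gaussian spatial receptive field and
map a binarized space-time stimulus to a predicted neural time course at
10 ms resolution:

* **Spatial** — purely linear: the neural response is the frame-by-frame
  dot product of the stimulus with the Gaussian RF.
* **CST** (compressive spatiotemporal) — the spatial drive is filtered by
  three temporal impulse responses (sustained gamma; biphasic on- and
  off-transient difference-of-gammas), rectified, and compressed by a
  power law with exponent ``n`` in [0.1, 1].
* **DN-ST** (delayed divisive normalization) — the drive is filtered by a
  monophasic gamma ``t * exp(-t / tau1)``, then divisively normalized by a
  semisaturation constant plus a delayed (exponentially low-pass filtered)
  copy of itself, with exponent ``n_dn``.

Units: x, y, sigma in degrees of visual angle.  The CST time constant
``tau`` is expressed in model time samples of 10 ms (centiseconds), the
convention of its search bounds [4, 100]; multiply by 10 for ms, and note
the sustained gamma peaks at ``8 * tau`` samples (see
:func:`cst_peak_time_ms`).  DN-ST ``tau1``/``tau2`` are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import gammaln

from .design import DT_MS, BarGeometry, StimulusSequence
from .exceptions import ParameterError, ShapeError

# Fixed temporal-channel shape constants of the CST model.
KAPPA_SUS = 1.0
M_SUS = 9.0
KAPPA_INH = 1.33
M_INH = 10.0

# Parameter search bounds (the solver's fine-search box; also the sampling
# ranges for simulated ground truth).
CST_TAU_BOUNDS = (4.0, 100.0)        # model samples (10 ms units)
CST_N_BOUNDS = (0.1, 1.0)
DNST_TAU1_BOUNDS = (0.01, 1.0)       # s
DNST_TAU2_BOUNDS = (0.01, 1.0)       # s
DNST_SIGMA_BOUNDS = (0.01, 0.5)
DNST_N_BOUNDS = (1.0, 6.0)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialParams:
    """Center (deg) and size (deg) of the 2D Gaussian spatial RF."""

    x: float
    y: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x, self.y))


@dataclass(frozen=True)
class CSTParams:
    """CST model parameters.

    ``tau`` is in 10 ms model samples; ``n_exp`` is the compressive
    exponent shared by all channels; ``beta_sus``/``beta_tran`` scale the
    sustained and (combined on+off) transient BOLD regressors.
    """

    spatial: SpatialParams
    tau: float
    n_exp: float
    beta_sus: float = 1.0
    beta_tran: float = 1.0
    kappa_sus: float = KAPPA_SUS
    m_sus: float = M_SUS
    kappa_inh: float = KAPPA_INH
    m_inh: float = M_INH

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if not CST_N_BOUNDS[0] <= self.n_exp <= CST_N_BOUNDS[1]:
            raise ParameterError(
                f"n_exp must be in {CST_N_BOUNDS}, got {self.n_exp}"
            )


@dataclass(frozen=True)
class DNSTParams:
    """DN-ST model parameters (tau1, tau2 in seconds)."""

    spatial: SpatialParams
    tau1: float
    tau2: float
    sigma_dn: float
    n_dn: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        for name, v in (("tau1", self.tau1), ("tau2", self.tau2),
                        ("sigma_dn", self.sigma_dn), ("n_dn", self.n_dn)):
            if not v > 0:
                raise ParameterError(f"{name} must be > 0, got {v}")


PRFParams = SpatialParams | CSTParams | DNSTParams


def spatial_of(params: PRFParams) -> SpatialParams:
    return params if isinstance(params, SpatialParams) else params.spatial


@dataclass
class NeuralTimeCourse:
    """Predicted neural response at 10 ms: one or three channel vectors."""

    channels: np.ndarray                 # (n_channels, n_frames)
    dt_ms: float = DT_MS
    labels: tuple[str, ...] = ("neural",)

    @property
    def n_frames(self) -> int:
        return self.channels.shape[1]


# ---------------------------------------------------------------------------
# Spatial receptive field and drive
# ---------------------------------------------------------------------------

def gaussian_rf(
    params: SpatialParams,
    grid: BarGeometry | tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Unnormalized 2D isotropic Gaussian (value 1 at the pRF center).

    ``grid`` is either a :class:`BarGeometry` (its pixel grid is used) or a
    ``(X, Y)`` meshgrid pair in degrees.
    """
    X, Y = grid.pixel_grid() if isinstance(grid, BarGeometry) else grid
    return np.exp(
        -((X - params.x) ** 2 + (Y - params.y) ** 2) / (2.0 * params.sigma**2)
    )


def spatial_drive(stim: StimulusSequence | np.ndarray, rf: np.ndarray) -> np.ndarray:
    """Per-frame weighted overlap of the stimulus with a spatial RF."""
    if isinstance(stim, StimulusSequence):
        return stim.drive(rf)
    if stim.shape[1:] != rf.shape:
        raise ShapeError(f"stimulus grid {stim.shape[1:]} != RF grid {rf.shape}")
    return np.tensordot(stim, rf, axes=([1, 2], [0, 1]))


# ---------------------------------------------------------------------------
# Temporal impulse responses
# ---------------------------------------------------------------------------

def _gamma_kernel(tau: float, kappa: float, m: float, tail_mass: float = 1e-9) -> np.ndarray:
    """Discretized gamma density (t/ktau)^(m-1) exp(-t/ktau) / (ktau (m-1)!).

    Time is in model samples; the density is evaluated at sample midpoints
    over a support holding all but ``tail_mass`` of the distribution
    (the 1 - tail_mass quantile of Gamma(m) scaled by kappa * tau) and
    renormalized to unit sum, so convolution preserves the drive's scale.
    (m-1)! is computed via the log-gamma function so non-integer m works.
    """
    if not tau > 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    kt = kappa * tau
    from scipy.special import gammainccinv

    n = max(int(np.ceil(float(gammainccinv(m, tail_mass)) * kt)), 4)
    t = np.arange(n) + 0.5
    log_h = (m - 1) * np.log(t / kt) - t / kt - np.log(kt) - gammaln(m)
    h = np.exp(log_h)
    return h / h.sum()


def sustained_irf(
    tau: float, kappa: float = KAPPA_SUS, m: float = M_SUS, dt_ms: float = DT_MS
) -> np.ndarray:
    """Sustained (monophasic gamma) impulse response; peaks at (m-1)*kappa*tau.

    ``tau`` in units of ``dt_ms`` samples; the returned kernel is sampled
    at ``dt_ms`` and sums to 1.
    """
    del dt_ms  # tau is already expressed in samples
    return _gamma_kernel(tau, kappa, m)


def transient_irfs(tau: float, dt_ms: float = DT_MS) -> tuple[np.ndarray, np.ndarray]:
    """On/off transient impulse responses (biphasic difference of gammas).

    ``h_on`` is the unit-area sustained gamma minus a slower inhibitory
    gamma (kappa=1.33, m=10); since each lobe has unit area the kernel
    integrates to ~0.  ``h_off = -h_on``.
    """
    exc = _gamma_kernel(tau, KAPPA_SUS, M_SUS)
    inh = _gamma_kernel(tau, KAPPA_INH, M_INH)
    n = max(len(exc), len(inh))
    h_on = np.zeros(n)
    h_on[: len(exc)] += exc
    h_on[: len(inh)] -= inh
    return h_on, -h_on


def cst_peak_time_ms(tau: float, dt_ms: float = DT_MS) -> float:
    """Time-to-peak of the sustained gamma, in ms (= 8 * tau samples)."""
    return (M_SUS - 1) * KAPPA_SUS * tau * dt_ms


def dnst_irf(tau1_s: float, dt_ms: float = DT_MS) -> np.ndarray:
    """DN-ST monophasic impulse response t * exp(-t / tau1), unit sum.

    Normalizing to unit sum after discretization keeps the scale of the
    filtered drive (and hence the meaning of ``sigma_dn``) independent of
    the sampling interval.
    """
    if not tau1_s > 0:
        raise ParameterError(f"tau1 must be > 0, got {tau1_s}")
    dt_s = dt_ms / 1000.0
    n = max(int(np.ceil(18.0 * tau1_s / dt_s)), 4)
    t = (np.arange(n) + 0.5) * dt_s
    h = t * np.exp(-t / tau1_s)
    return h / h.sum()


def dnst_decay(tau2_s: float, dt_ms: float = DT_MS) -> np.ndarray:
    """DN-ST exponential-decay low-pass filter exp(-t / tau2), unit sum."""
    if not tau2_s > 0:
        raise ParameterError(f"tau2 must be > 0, got {tau2_s}")
    dt_s = dt_ms / 1000.0
    n = max(int(np.ceil(18.0 * tau2_s / dt_s)), 4)
    t = (np.arange(n) + 0.5) * dt_s
    h = np.exp(-t / tau2_s)
    return h / h.sum()


# ---------------------------------------------------------------------------
# Causal convolution respecting run boundaries
# ---------------------------------------------------------------------------

def convolve_runs(
    x: np.ndarray, kernel: np.ndarray, run_breaks=None
) -> np.ndarray:
    """Causal, left-zero-padded convolution applied independently per run.

    Runs are separate acquisitions: responses never bleed across run
    boundaries.  ``run_breaks`` lists the start index of each run
    (default: one run).
    """
    if run_breaks is None or len(run_breaks) <= 1:
        return fftconvolve(x, kernel)[: len(x)]
    out = np.empty_like(x, dtype=float)
    edges = list(run_breaks) + [len(x)]
    for a, b in zip(edges[:-1], edges[1:]):
        out[a:b] = fftconvolve(x[a:b], kernel)[: b - a]
    return out


def _drive_of(stim, params: SpatialParams, normalize: bool) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(stim, StimulusSequence):
        rf = gaussian_rf(params, stim.geometry)
        breaks = stim.run_breaks
    else:
        side = stim.shape[1]
        geom = BarGeometry()  # default 24 deg field
        if side != geom.grid_px:
            raise ShapeError(
                "raw frame arrays must use the default 61 px grid; "
                "pass a StimulusSequence for other geometries"
            )
        rf = gaussian_rf(params, geom)
        breaks = None
    d = spatial_drive(stim, rf)
    if normalize:
        d = d / rf.sum()
    return d, breaks


# ---------------------------------------------------------------------------
# Model predictions (neural stage, 10 ms)
# ---------------------------------------------------------------------------

def predict_spatial(
    stim: StimulusSequence | np.ndarray, params: SpatialParams
) -> NeuralTimeCourse:
    """Linear spatial model: the neural response is the spatial drive."""
    d, _ = _drive_of(stim, params, normalize=False)
    return NeuralTimeCourse(d[None, :], labels=("spatial",))


def predict_cst(
    stim: StimulusSequence | np.ndarray, params: CSTParams
) -> NeuralTimeCourse:
    """CST model: three channels, each ReLU-rectified and compressed.

    Channel i response: ``max(0, h_i (*) drive) ** n`` with h_1 the
    sustained gamma, h_2 the on-transient biphasic kernel, h_3 = -h_2.
    """
    d, breaks = _drive_of(stim, params.spatial, normalize=False)
    h1 = _gamma_kernel(params.tau, params.kappa_sus, params.m_sus)
    h2, _ = _custom_transient(params)
    r_sus = convolve_runs(d, h1, breaks)
    r_tra = convolve_runs(d, h2, breaks)
    n = params.n_exp
    p1 = np.maximum(r_sus, 0.0) ** n
    p2 = np.maximum(r_tra, 0.0) ** n
    p3 = np.maximum(-r_tra, 0.0) ** n
    return NeuralTimeCourse(
        np.stack([p1, p2, p3]),
        labels=("sustained", "on_transient", "off_transient"),
    )


def _custom_transient(params: CSTParams) -> tuple[np.ndarray, np.ndarray]:
    exc = _gamma_kernel(params.tau, params.kappa_sus, params.m_sus)
    inh = _gamma_kernel(params.tau, params.kappa_inh, params.m_inh)
    n = max(len(exc), len(inh))
    h = np.zeros(n)
    h[: len(exc)] += exc
    h[: len(inh)] -= inh
    return h, -h


def predict_dnst(
    stim: StimulusSequence | np.ndarray,
    params: DNSTParams,
    delayed: str = "conv",
) -> NeuralTimeCourse:
    """DN-ST model: exponentiated drive divided by a delayed normalization pool.

    ``p = |r|^n / (sigma_dn^n + (|r| (*) h2)^n)`` with
    ``r = h1 (*) drive``.  The spatial drive is scaled by the RF's total
    mass so it lies in [0, 1] (a contrast-like unit), which puts the
    semisaturation constant's range [0.01, 0.5] on the scale of the
    signal it normalizes.  With ``delayed="pointwise"`` the bracketed term
    is a pointwise product with the decay filter instead of a convolution.
    """
    d, breaks = _drive_of(stim, params.spatial, normalize=True)
    h1 = dnst_irf(params.tau1)
    h2 = dnst_decay(params.tau2)
    r = convolve_runs(d, h1, breaks)
    absr = np.abs(r)
    if delayed == "conv":
        # clip FFT rounding noise so fractional exponents stay real
        delayed_pool = np.maximum(convolve_runs(absr, h2, breaks), 0.0)
    elif delayed == "pointwise":
        pool = np.zeros_like(absr)
        pool[: len(h2)] = h2[: len(pool)]
        delayed_pool = absr * pool
    else:
        raise ParameterError(f"unknown delayed mode {delayed!r}")
    n = params.n_dn
    p = absr**n / (params.sigma_dn**n + delayed_pool**n)
    return NeuralTimeCourse(p[None, :], labels=("dnst",))


def predict_neural(stim, params: PRFParams, **kw) -> NeuralTimeCourse:
    """Dispatch to the model matching the parameter type."""
    if isinstance(params, SpatialParams):
        return predict_spatial(stim, params)
    if isinstance(params, CSTParams):
        return predict_cst(stim, params)
    if isinstance(params, DNSTParams):
        return predict_dnst(stim, params, **kw)
    raise ParameterError(f"unknown parameter type {type(params)!r}")


# ---------------------------------------------------------------------------
# Parameter table I/O
# ---------------------------------------------------------------------------

MODEL_KINDS = ("spatial", "cst", "dnst")

_PARAM_COLUMNS = {
    "spatial": ("x", "y", "sigma"),
    "cst": ("x", "y", "sigma", "tau", "n_exp", "beta_sus", "beta_tran"),
    "dnst": ("x", "y", "sigma", "tau1", "tau2", "sigma_dn", "n_dn", "beta"),
}


def model_kind_of(params: PRFParams) -> str:
    return {SpatialParams: "spatial", CSTParams: "cst", DNSTParams: "dnst"}[
        type(params)
    ]


def params_to_dict(params: PRFParams) -> dict:
    sp = spatial_of(params)
    d = {"x": sp.x, "y": sp.y, "sigma": sp.sigma}
    if isinstance(params, CSTParams):
        d.update(tau=params.tau, n_exp=params.n_exp,
                 beta_sus=params.beta_sus, beta_tran=params.beta_tran)
    elif isinstance(params, DNSTParams):
        d.update(tau1=params.tau1, tau2=params.tau2,
                 sigma_dn=params.sigma_dn, n_dn=params.n_dn, beta=params.beta)
    return d


def params_from_dict(model_kind: str, d: dict) -> PRFParams:
    sp = SpatialParams(float(d["x"]), float(d["y"]), float(d["sigma"]))
    if model_kind == "spatial":
        return sp
    if model_kind == "cst":
        return CSTParams(sp, float(d["tau"]), float(d["n_exp"]),
                         float(d.get("beta_sus", 1.0)),
                         float(d.get("beta_tran", 1.0)))
    if model_kind == "dnst":
        return DNSTParams(sp, float(d["tau1"]), float(d["tau2"]),
                          float(d["sigma_dn"]), float(d["n_dn"]),
                          float(d.get("beta", 1.0)))
    raise ParameterError(f"unknown model kind {model_kind!r}")


def free_param_names(model_kind: str) -> tuple[str, ...]:
    """Names of the parameters the solver fits (betas are estimated by GLM)."""
    return {
        "spatial": ("x", "y", "sigma"),
        "cst": ("x", "y", "sigma", "tau", "n_exp"),
        "dnst": ("x", "y", "sigma", "tau1", "tau2", "sigma_dn", "n_dn"),
    }[model_kind]
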