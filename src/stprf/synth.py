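"""Synthesizer: ground-truth pRF populations and noisy simulated BOLD.

Ground-truth pRF centers are drawn with eccentricity |N(0, 5 deg)|
truncated to [0, 10] deg (a half-normal "spanning" the stimulated field)
at uniform polar angle, sizes from N(1.6, 0.7 deg) truncated to
[0.2, 3] deg, and model-specific temporal parameters uniformly within the
solver's fine-search bounds.  Noiseless BOLD is generated by the matching
forward model with the default two-gamma HRF, then corrupted by a
composite of white, physiological (cardiac + respiratory sinusoids) and
low-frequency drift noise scaled to a target signal-to-noise ratio in
decibels (power ratio of the mean-removed series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from ._engine import ModelEngine
from .design import StimulusSequence
from .exceptions import CalibrationError, ParameterError
from .hrf import HRFParams, two_gamma_hrf
from .models import (
    CST_N_BOUNDS,
    CST_TAU_BOUNDS,
    DNST_N_BOUNDS,
    DNST_SIGMA_BOUNDS,
    DNST_TAU1_BOUNDS,
    DNST_TAU2_BOUNDS,
    CSTParams,
    DNSTParams,
    SpatialParams,
)

ECC_RANGE_DEG = (0.0, 10.0)
SIGMA_RANGE_DEG = (0.2, 3.0)


@dataclass
class GroundTruthSet:
    """A sampled population of ground-truth pRFs for one model kind."""

    model_kind: str
    params: list[models.PRFParams]
    seed: int | None
    n_voxels: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([models.params_to_dict(p) for p in self.params])

    def theta(self) -> np.ndarray:
        """(n_voxels, n_free) array of the solver-estimated parameters."""
        names = models.free_param_names(self.model_kind)
        rows = [models.params_to_dict(p) for p in self.params]
        return np.array([[r[k] for k in names] for r in rows])


@dataclass(frozen=True)
class NoiseSpec:
    """Composite fMRI noise scaled to a target SNR (dB).

    Power mix of the three zero-mean components before scaling:
    white Gaussian, physiological sinusoids (cardiac ~1.17 Hz — aliased
    by the 1 s sampling — and respiratory ~0.3 Hz, random phases), and a
    per-run slow cosine drift with period >= the run length.
    """

    target_snr_db: float = 0.1
    white_weight: float = 0.5
    physio_weight: float = 0.25
    drift_weight: float = 0.25
    cardiac_hz: float = 1.17
    respiratory_hz: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        w = self.white_weight + self.physio_weight + self.drift_weight
        if not w > 0:
            raise ParameterError("noise component weights must sum > 0")


# ---------------------------------------------------------------------------
# Ground-truth sampling
# ---------------------------------------------------------------------------

def _truncated_normal(rng, loc, scale, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(loc, scale, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def sample_spatial(n: int, rng: np.random.Generator) -> list[SpatialParams]:
    ecc = np.abs(rng.normal(0.0, 5.0, size=4 * n))
    ecc = ecc[ecc <= ECC_RANGE_DEG[1]][:n]
    while len(ecc) < n:
        extra = np.abs(rng.normal(0.0, 5.0, size=n))
        ecc = np.concatenate([ecc, extra[extra <= ECC_RANGE_DEG[1]]])[:n]
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sigma = _truncated_normal(rng, 1.6, 0.7, *SIGMA_RANGE_DEG, n)
    return [
        SpatialParams(float(e * np.cos(t)), float(e * np.sin(t)), float(s))
        for e, t, s in zip(ecc, theta, sigma)
    ]


def sample_ground_truth(
    model_kind: str,
    n: int = 300,
    seed: int | None = 0,
    shared_spatial: list[SpatialParams] | None = None,
) -> GroundTruthSet:
    """Sample a ground-truth population for one model.

    Pass the same ``shared_spatial`` list to several calls to give all
    models identical spatial parameters for cross-model comparisons.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    spatial = shared_spatial or sample_spatial(n, rng)
    if len(spatial) != n:
        raise ParameterError("shared_spatial length != n")
    if model_kind == "spatial":
        params: list[models.PRFParams] = list(spatial)
    elif model_kind == "cst":
        tau = rng.uniform(*CST_TAU_BOUNDS, size=n)
        n_exp = rng.uniform(*CST_N_BOUNDS, size=n)
        params = [
            CSTParams(sp, float(t), float(ne))
            for sp, t, ne in zip(spatial, tau, n_exp)
        ]
    elif model_kind == "dnst":
        t1 = rng.uniform(*DNST_TAU1_BOUNDS, size=n)
        t2 = rng.uniform(*DNST_TAU2_BOUNDS, size=n)
        sdn = rng.uniform(*DNST_SIGMA_BOUNDS, size=n)
        ndn = rng.uniform(*DNST_N_BOUNDS, size=n)
        params = [
            DNSTParams(sp, float(a), float(b), float(c), float(d))
            for sp, a, b, c, d in zip(spatial, t1, t2, sdn, ndn)
        ]
    else:
        raise ParameterError(f"unknown model kind {model_kind!r}")
    return GroundTruthSet(model_kind, params, seed, n)


# ---------------------------------------------------------------------------
# Forward synthesis
# ---------------------------------------------------------------------------

def synthesize_bold(
    gt: GroundTruthSet,
    stim: StimulusSequence,
    hrf: HRFParams | np.ndarray | None = None,
    engine: ModelEngine | None = None,
) -> np.ndarray:
    """Noiseless BOLD (n_samples, n_voxels) at 1 s for a ground-truth set."""
    if isinstance(hrf, HRFParams) or hrf is None:
        kernel = two_gamma_hrf(hrf)
    else:
        kernel = np.asarray(hrf, dtype=float)
    engine = engine or ModelEngine(stim, gt.model_kind, kernel)
    cols = [engine.predict_bold(p) for p in gt.params]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def measure_snr_db(signal: np.ndarray, noise: np.ndarray) -> float:
    """10 log10 of the power ratio, power = mean squared deviation from
    the series mean."""
    signal = np.asarray(signal, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if signal.shape != noise.shape:
        raise ParameterError("signal and noise must have equal length")
    ps = np.var(signal)
    pn = np.var(noise)
    if pn <= 0:
        return np.inf
    return float(10.0 * np.log10(ps / pn))


def _noise_components(
    n: int, run_breaks: np.ndarray, spec: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance white / physio / drift components, (3, n)."""
    t = np.arange(n, dtype=float)  # 1 s sampling
    white = rng.standard_normal(n)
    phys = (
        np.sin(2 * np.pi * spec.cardiac_hz * t + rng.uniform(0, 2 * np.pi))
        + np.sin(2 * np.pi * spec.respiratory_hz * t + rng.uniform(0, 2 * np.pi))
    )
    drift = np.empty(n)
    edges = list(run_breaks) + [n]
    for a, b in zip(edges[:-1], edges[1:]):
        run_len = b - a
        period = run_len * rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        drift[a:b] = np.cos(2 * np.pi * np.arange(run_len) / period + phase)
    comps = np.stack([white, phys, drift])
    sd = comps.std(axis=1, keepdims=True)
    return comps / np.maximum(sd, 1e-12)


def add_noise(
    bold: np.ndarray,
    spec: NoiseSpec | None = None,
    run_breaks: np.ndarray | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Signal plus composite noise calibrated per voxel to the target SNR.

    ``bold`` is (n_samples,) or (n_samples, n_voxels); each voxel gets an
    independent noise stream.  An infinite target SNR returns the input
    unchanged.  The realized SNR (power-ratio definition of
    :func:`measure_snr_db`) is exact up to float rounding.
    """
    spec = spec or NoiseSpec()
    bold = np.asarray(bold, dtype=float)
    single = bold.ndim == 1
    B = bold[:, None] if single else bold
    n, n_vox = B.shape
    if run_breaks is None:
        run_breaks = np.array([0])
    if np.isinf(spec.target_snr_db):
        return bold.copy()
    root = np.random.default_rng(
        seed if seed is not None else spec.seed
    )
    streams = root.spawn(n_vox)
    w = np.array([spec.white_weight, spec.physio_weight, spec.drift_weight])
    w = w / w.sum()
    out = np.empty_like(B)
    for v in range(n_vox):
        sig_power = np.var(B[:, v])
        if sig_power <= 0:
            raise CalibrationError(
                f"voxel {v}: zero-variance signal, cannot calibrate SNR"
            )
        comps = _noise_components(n, run_breaks, spec, streams[v])
        noise = np.sqrt(w) @ comps
        noise = noise - noise.mean()
        target_power = sig_power / 10.0 ** (spec.target_snr_db / 10.0)
        noise *= np.sqrt(target_power / np.var(noise))
        out[:, v] = B[:, v] + noise
    return out[:, 0] if single else out
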