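"""Fast forward-model evaluation for solving and synthesis.

The stimulus is a schedule of (bar aperture, temporal profile) slots, so
the linear stages of every model factorize exactly:

* the spatial drive of a slot is ``overlap(aperture) * profile(t)``, and
* convolution with a temporal kernel distributes over slots, so each
  slot contributes ``overlap * (kernel (*) profile)`` — one small
  convolution per *temporal condition*, reused by every slot.

Likewise, HRF convolution followed by 1 s bin-averaging is a single
linear map evaluated only at the bin centers, implemented as one matrix
product per run (``_BinnedConv``).  Both factorizations are exact (same
arithmetic as :mod:`stprf.models` + :mod:`stprf.hrf`, reordered), which
the test suite verifies, and reduce one model evaluation on the full
nine-run experiment to a few milliseconds.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import fftconvolve

from . import models
from .design import StimulusSequence
from .exceptions import ParameterError

_EPS = 1e-12

try:  # optional JIT for the per-slot scatter loop (pure-numpy fallback)
    from numba import njit

    @njit(cache=False, fastmath=True)
    def _scatter_slots(R, run_idx, starts, aps, profs, conv, ov):
        for i in range(run_idx.shape[0]):
            r = run_idx[i]
            s0 = starts[i]
            w = ov[aps[i]]
            cp = conv[profs[i]]
            for t in range(cp.shape[0]):
                R[r, s0 + t] += w * cp[t]

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speedup
    HAVE_NUMBA = False


def _fast_pow(x: np.ndarray, n: float) -> np.ndarray:
    """x ** n for nonnegative x, with cheap paths for quarter powers."""
    if n == 1.0:
        return x
    if n == 0.5:
        return np.sqrt(x)
    if n == 0.25:
        return np.sqrt(np.sqrt(x))
    if n == 0.75:
        s = np.sqrt(x)
        return s * np.sqrt(s)
    return x**n


class _BinnedConv:
    """Exact 'convolve with HRF at 10 ms then average 1 s bins' operator."""

    def __init__(self, hrf: np.ndarray, bin_frames: int):
        self.bin_frames = bf = bin_frames
        cs = np.concatenate([[0.0], np.cumsum(hrf)])
        n_h = len(hrf)
        n_l = (n_h + bf - 1) // bf + 1
        l_idx = np.arange(n_l)[:, None] * bf
        i_idx = np.arange(bf)[None, :]
        hi = np.clip(l_idx - i_idx + bf, 0, n_h)
        lo = np.clip(l_idx - i_idx, 0, n_h)
        self.W = (cs[hi] - cs[lo]) / bf          # (n_l, bf)
        self.Wt32 = self.W.T.astype(np.float32)
        self.n_l = n_l

    def apply(self, p: np.ndarray) -> np.ndarray:
        """p: (..., n_bins * bin_frames) neural signal -> (..., n_bins)."""
        *lead, n = p.shape
        nb = n // self.bin_frames
        q = p[..., : nb * self.bin_frames].reshape(*lead, nb, self.bin_frames)
        wt = self.Wt32 if q.dtype == np.float32 else self.W.T
        z = q @ wt                                # (..., nb, n_l)
        # out[k] = sum_l z[k - l, l]: a diagonal sum, taken over a
        # zero-padded strided view instead of a python loop over lags
        n_l = z.shape[-1]
        zp = np.zeros((*lead, nb + n_l, n_l), dtype=z.dtype)
        zp[..., n_l:, :] = z
        s = zp.strides
        diag = np.lib.stride_tricks.as_strided(
            zp[..., n_l:, :],
            shape=(*lead, nb, n_l),
            strides=(*s[:-2], s[-2], s[-1] - s[-2]),
        )
        return diag.sum(axis=-1)


class ModelEngine:
    """Per-(stimulus, model, HRF) evaluation context.

    Provides BOLD regressors at 1 s for arbitrary parameter vectors, an
    R^2 objective with GLM-profiled betas, and vectorized grid banks.
    """

    def __init__(
        self,
        stim: StimulusSequence,
        model_kind: str,
        hrf: np.ndarray,
        bin_s: float = 1.0,
        dtype=np.float32,
    ):
        if model_kind not in models.MODEL_KINDS:
            raise ParameterError(f"unknown model kind {model_kind!r}")
        self.stim = stim
        self.model_kind = model_kind
        self.dt_ms = stim.dt_ms
        self.bin_frames = int(round(bin_s * 1000.0 / stim.dt_ms))
        self.hrf = np.asarray(hrf, dtype=float)
        self.dtype = np.dtype(dtype)
        self.binconv = _BinnedConv(self.hrf, self.bin_frames)

        geom = stim.geometry
        X, Y = geom.pixel_grid()
        self.xf = X.ravel()
        self.yf = Y.ravel()
        self.A = stim.apertures.reshape(len(stim.apertures), -1).astype(float)

        # per-run slot tables (start local to the run)
        self.run_slices = stim.run_slices()
        self.run_frames = [sl.stop - sl.start for sl in self.run_slices]
        self.run_bins = [nf // self.bin_frames for nf in self.run_frames]
        self.n_bins = int(sum(self.run_bins))
        self.runs = []
        for r, sl in enumerate(self.run_slices):
            slots = stim.slots[stim.slots["run"] == r]
            self.runs.append(
                (slots["start"] - sl.start, slots["aperture"], slots["profile"])
            )
        self.profiles = np.asarray(
            [p.astype(float) for p in stim.profiles]
        )                                         # (n_prof, slot_frames)
        self.slot_frames = self.profiles.shape[1]
        self.uniform_runs = len(set(self.run_frames)) == 1
        self._prof_fft: dict[int, np.ndarray] = {}
        # flat slot table for the JIT scatter path
        self._flat = tuple(
            np.ascontiguousarray(a, dtype=np.int64) for a in (
                np.concatenate([np.full(len(s), r) for r, (s, _, _)
                                in enumerate(self.runs)]),
                np.concatenate([s for s, _, _ in self.runs]),
                np.concatenate([a for _, a, _ in self.runs]),
                np.concatenate([p for _, _, p in self.runs]),
            )
        )

        self.n_regressors = 2 if model_kind == "cst" else 1

    # -- low-level pieces ---------------------------------------------------

    def overlaps(self, x: float, y: float, sigma: float) -> tuple[np.ndarray, float]:
        """Aperture overlaps of the Gaussian RF, and the RF's grid sum."""
        rf = np.exp(
            -((self.xf - x) ** 2 + (self.yf - y) ** 2) / (2.0 * sigma**2)
        )
        return self.A @ rf, float(rf.sum())

    def _cond_profiles(self, kernel: np.ndarray) -> np.ndarray:
        """kernel (*) profile for every temporal condition (full conv)."""
        L = self.slot_frames + len(kernel) - 1
        n = next_fast_len(L)
        pf = self._prof_fft.get(n)
        if pf is None:
            pf = rfft(self.profiles, n, axis=1)
            if len(self._prof_fft) < 64:
                self._prof_fft[n] = pf
        kf = rfft(kernel, n)
        return irfft(pf * kf, n, axis=1)[:, :L]

    def _assemble(self, ov_scaled: np.ndarray, kernel: np.ndarray) -> list[np.ndarray]:
        """Per-run linear responses kernel (*) drive via slot superposition.

        ``ov_scaled``: (n_apertures,) or (n_points, n_apertures).
        Returns one array per run of shape (n_frames_run,) or
        (n_points, n_frames_run).
        """
        conv = self._cond_profiles(kernel)
        L = conv.shape[1]
        batched = ov_scaled.ndim == 2
        if not batched and self.uniform_runs:
            # one (n_runs, nf + L) buffer; per-slot slice adds, tails
            # beyond each run's end land in the discarded margin
            nf = self.run_frames[0]
            R = np.zeros((len(self.runs), nf + L))
            if HAVE_NUMBA:
                _scatter_slots(R, *self._flat,
                               np.ascontiguousarray(conv),
                               np.ascontiguousarray(ov_scaled, dtype=float))
            else:
                for r, (starts, aps, profs) in enumerate(self.runs):
                    row = R[r]
                    for s0, a, p in zip(starts, aps, profs):
                        row[s0:s0 + L] += ov_scaled[a] * conv[p]
            return R[:, :nf].astype(self.dtype)
        out = []
        if batched:
            # bank building: single precision end to end
            conv = conv.astype(np.float32)
            ov_scaled = ov_scaled.astype(np.float32)
        for (starts, aps, profs), nf in zip(self.runs, self.run_frames):
            if batched:
                r = np.zeros((ov_scaled.shape[0], nf + L), dtype=np.float32)
                for s0, a, p in zip(starts, aps, profs):
                    r[:, s0:s0 + L] += ov_scaled[:, a, None] * conv[p]
                out.append(r[:, :nf])
            else:
                r = np.zeros(nf + L)
                for s0, a, p in zip(starts, aps, profs):
                    r[s0:s0 + L] += ov_scaled[a] * conv[p]
                out.append(r[:nf])
        return out

    def _drive_runs(self, ov: np.ndarray):
        """Raw spatial drive per run (no temporal filtering)."""
        if ov.ndim == 1 and self.uniform_runs:
            nf = self.run_frames[0]
            D = np.zeros((len(self.runs), nf), dtype=self.dtype)
            for r, (starts, aps, profs) in enumerate(self.runs):
                row = D[r]
                for s0, a, p in zip(starts, aps, profs):
                    row[s0:s0 + self.slot_frames] = ov[a] * self.profiles[p]
            return D
        out = []
        for (starts, aps, profs), nf in zip(self.runs, self.run_frames):
            batched = ov.ndim == 2
            shape = (ov.shape[0], nf) if batched else (nf,)
            d = np.zeros(shape, dtype=np.float32 if batched else float)
            for s0, a, p in zip(starts, aps, profs):
                prof = self.profiles[p]
                if batched:
                    d[:, s0:s0 + self.slot_frames] = ov[:, a, None] * prof
                else:
                    d[s0:s0 + self.slot_frames] = ov[a] * prof
            out.append(d)
        return out

    def _bin_concat(self, per_run) -> np.ndarray:
        if isinstance(per_run, np.ndarray):
            # (n_runs, nf) stack from the uniform-run fast path
            return self.binconv.apply(per_run).reshape(-1)
        return np.concatenate(
            [self.binconv.apply(p) for p in per_run], axis=-1
        )

    # -- model regressors ---------------------------------------------------

    def regressors(self, theta: np.ndarray) -> np.ndarray:
        """BOLD regressors at 1 s for free parameters ``theta``.

        ``theta`` follows :func:`stprf.models.free_param_names`.  Returns
        (n_regressors, n_bins).
        """
        if self.model_kind == "spatial":
            x, y, sigma = theta
            ov, _ = self.overlaps(x, y, sigma)
            out = self._bin_concat(self._drive_runs(ov))[None].reshape(1, -1)
            return out.astype(float)

        if self.model_kind == "cst":
            x, y, sigma, tau, n_exp = theta
            ov, _ = self.overlaps(x, y, sigma)
            h1 = models._gamma_kernel(tau, models.KAPPA_SUS, models.M_SUS)
            h_inh = models._gamma_kernel(tau, models.KAPPA_INH, models.M_INH)
            h2 = np.zeros(max(len(h1), len(h_inh)))
            h2[: len(h1)] += h1
            h2[: len(h_inh)] -= h_inh
            sus = self._assemble(ov, h1)
            tra = self._assemble(ov, h2)
            if isinstance(sus, np.ndarray):
                p_sus = np.maximum(sus, 0.0) ** n_exp
                # on + off channels combined: relu(r)^n + relu(-r)^n == |r|^n
                p_tra = np.abs(tra) ** n_exp
            else:
                p_sus = [np.maximum(r, 0.0) ** n_exp for r in sus]
                p_tra = [np.abs(r) ** n_exp for r in tra]
            return np.stack(
                [self._bin_concat(p_sus), self._bin_concat(p_tra)]
            ).astype(float)

        # dnst
        x, y, sigma, tau1, tau2, sigma_dn, n_dn = theta
        ov, rf_sum = self.overlaps(x, y, sigma)
        ov = ov / max(rf_sum, _EPS)
        g1 = models.dnst_irf(tau1, self.dt_ms)
        g2 = models.dnst_decay(tau2, self.dt_ms)
        g12 = fftconvolve(g1, g2)
        r_runs = self._assemble(ov, g1)
        pool_runs = self._assemble(ov, g12)
        if isinstance(r_runs, np.ndarray):
            p = (np.maximum(r_runs, 0.0) ** n_dn
                 / (sigma_dn**n_dn + np.maximum(pool_runs, 0.0) ** n_dn))
        else:
            p = [
                np.maximum(r, 0.0) ** n_dn
                / (sigma_dn**n_dn + np.maximum(q, 0.0) ** n_dn)
                for r, q in zip(r_runs, pool_runs)
            ]
        return self._bin_concat(p)[None].reshape(1, -1).astype(float)

    def predict_bold(self, params: models.PRFParams) -> np.ndarray:
        """Noiseless BOLD prediction (1 s) with the parameters' own betas."""
        kind = models.model_kind_of(params)
        if kind != self.model_kind:
            raise ParameterError(
                f"engine is for {self.model_kind!r}, got {kind!r} params"
            )
        d = models.params_to_dict(params)
        theta = np.array([d[k] for k in models.free_param_names(kind)])
        reg = self.regressors(theta)
        if kind == "cst":
            betas = np.array([params.beta_sus, params.beta_tran])
        elif kind == "dnst":
            betas = np.array([params.beta])
        else:
            betas = np.array([1.0])
        return betas @ reg

    # -- objective ----------------------------------------------------------

    def fit_betas(self, reg: np.ndarray, data: np.ndarray):
        """OLS betas and R^2 (residual SS over raw SS of the data)."""
        dd = float(data @ data)
        if dd <= _EPS:
            return np.zeros(reg.shape[0]), np.nan
        G = reg @ reg.T
        xd = reg @ data
        try:
            betas = np.linalg.solve(G, xd)
        except np.linalg.LinAlgError:
            betas, *_ = np.linalg.lstsq(reg.T, data, rcond=None)
        expl = float(betas @ xd)
        return betas, expl / dd

    def r2(self, theta: np.ndarray, data: np.ndarray) -> tuple[float, np.ndarray]:
        reg = self.regressors(theta)
        betas, r2 = self.fit_betas(reg, data)
        if not np.isfinite(r2):
            return -np.inf, betas
        return r2, betas

    # -- grid banks ---------------------------------------------------------

    def grid_bank(self, grid) -> dict:
        """Precomputed 1 s regressors for every grid point (shared by voxels).

        Returns arrays ``theta`` (n_points, n_free) and ``X``
        (n_points, n_regressors, n_bins) in float32, plus Gram matrices.
        """
        xs, ys = np.meshgrid(grid.x_values(), grid.y_values())
        xs, ys = xs.ravel(), ys.ravel()
        sigmas = grid.sigma_values()
        sp = np.array(
            [(x, y, s) for x, y in zip(xs, ys) for s in sigmas]
        )
        n_sp = len(sp)

        if self.model_kind == "cst":
            taus = [grid.cst_tau]
            n_vals = np.asarray(grid.n_grid, dtype=float)
            thetas = np.array(
                [(x, y, s, taus[0], n) for x, y, s in sp for n in n_vals]
            )
        elif self.model_kind == "dnst":
            t1, t2, ndn, sdn = grid.dnst_defaults
            thetas = np.array([(x, y, s, t1, t2, sdn, ndn) for x, y, s in sp])
        else:
            thetas = sp
        n_pts = len(thetas)
        X = np.empty((n_pts, self.n_regressors, self.n_bins), dtype=np.float32)

        chunk = max(1, int(2.5e8 // (8 * max(self.run_frames))))
        chunk = min(chunk, 512)
        if self.model_kind == "cst":
            h1 = models._gamma_kernel(grid.cst_tau, models.KAPPA_SUS, models.M_SUS)
            h_inh = models._gamma_kernel(grid.cst_tau, models.KAPPA_INH, models.M_INH)
            h2 = np.zeros(max(len(h1), len(h_inh)))
            h2[: len(h1)] += h1
            h2[: len(h_inh)] -= h_inh
        elif self.model_kind == "dnst":
            t1, t2, ndn, sdn = grid.dnst_defaults
            g1 = models.dnst_irf(t1, self.dt_ms)
            g12 = fftconvolve(g1, models.dnst_decay(t2, self.dt_ms))

        for c0 in range(0, n_sp, chunk):
            c1 = min(c0 + chunk, n_sp)
            rf = np.exp(
                -((self.xf[None] - sp[c0:c1, 0:1]) ** 2
                  + (self.yf[None] - sp[c0:c1, 1:2]) ** 2)
                / (2.0 * sp[c0:c1, 2:3] ** 2)
            )
            OV = rf @ self.A.T                           # (c, n_ap)
            if self.model_kind == "spatial":
                X[c0:c1, 0] = self._bin_concat(self._drive_runs(OV))
            elif self.model_kind == "cst":
                sus = self._assemble(OV, h1)
                tra = self._assemble(OV, h2)
                n_n = len(n_vals)
                for r_sus, r_tra, bsl in self._per_run_view(sus, tra):
                    r_sus = np.maximum(r_sus, 0.0)
                    r_tra = np.abs(r_tra)
                    for j, n_exp in enumerate(n_vals):
                        rows = slice(c0 * n_n + j, c1 * n_n, n_n)
                        X[rows, 0, bsl] = self.binconv.apply(
                            _fast_pow(r_sus, n_exp)
                        ).astype(np.float32)
                        X[rows, 1, bsl] = self.binconv.apply(
                            _fast_pow(r_tra, n_exp)
                        ).astype(np.float32)
            else:
                rsum = rf.sum(axis=1)
                OVn = OV / np.maximum(rsum, _EPS)[:, None]
                r_runs = self._assemble(OVn, g1)
                pool = self._assemble(OVn, g12)
                p = [
                    np.maximum(r, 0.0) ** ndn
                    / (sdn**ndn + np.maximum(q, 0.0) ** ndn)
                    for r, q in zip(r_runs, pool)
                ]
                X[c0:c1, 0] = self._bin_concat(p)

        G = np.einsum("prt,pst->prs", X, X)
        return {"theta": thetas, "X": X, "G": G.astype(float), "grid": grid}

    def _per_run_view(self, sus: list, tra: list):
        """Yield per-run (sustained, transient, bin-slice) triples."""
        b0 = 0
        for r_sus, r_tra, nb in zip(sus, tra, self.run_bins):
            yield r_sus, r_tra, slice(b0, b0 + nb)
            b0 += nb

    def grid_score(self, bank: dict, data: np.ndarray):
        """Best grid point per voxel.

        ``data``: (n_bins,) or (n_bins, n_voxels).  Returns (theta_best,
        r2_best) with leading voxel dimension when data is a matrix.
        """
        X = bank["X"]
        G = bank["G"]
        single = data.ndim == 1
        D = data[:, None] if single else data
        D32 = D.astype(np.float32)
        dd = np.einsum("tv,tv->v", D, D)
        n_pts = X.shape[0]
        xd = np.einsum("prt,tv->prv", X, D32).astype(float)
        if X.shape[1] == 1:
            g = np.maximum(G[:, 0, 0], _EPS)[:, None]
            expl = xd[:, 0, :] ** 2 / g
        else:
            g11 = G[:, 0, 0][:, None]
            g22 = G[:, 1, 1][:, None]
            g12 = G[:, 0, 1][:, None]
            det = g11 * g22 - g12**2
            a1, a2 = xd[:, 0, :], xd[:, 1, :]
            safe = det > _EPS * np.maximum(g11 * g22, _EPS)
            b1 = np.where(safe, (g22 * a1 - g12 * a2) / np.where(safe, det, 1.0), 0.0)
            b2 = np.where(safe, (g11 * a2 - g12 * a1) / np.where(safe, det, 1.0), 0.0)
            expl = b1 * a1 + b2 * a2
            # rank-deficient points: best single regressor
            e1 = a1**2 / np.maximum(g11, _EPS)
            expl = np.where(safe, expl, np.maximum(e1, a2**2 / np.maximum(g22, _EPS)))
        r2 = expl / np.maximum(dd[None, :], _EPS)
        best = self._argmax_tiebreak(r2, bank["theta"])
        theta = bank["theta"][best]
        r2b = r2[best, np.arange(r2.shape[1])]
        if single:
            return theta[0], float(r2b[0])
        return theta, r2b

    @staticmethod
    def _argmax_tiebreak(r2: np.ndarray, thetas: np.ndarray) -> np.ndarray:
        """Argmax over grid points; exact ties prefer small sigma, then
        small eccentricity."""
        # Stable ordering: points sorted by (sigma, ecc) once; argmax then
        # naturally returns the preferred point among ties.
        ecc = np.hypot(thetas[:, 0], thetas[:, 1])
        order = np.lexsort((ecc, thetas[:, 2]))
        best_sorted = np.argmax(r2[order], axis=0)
        return order[best_sorted]
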