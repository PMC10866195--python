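"""File I/O: BOLD time-series tables, result tables, run configuration.

The canonical on-disk formats are UTF-8 tab-separated tables:

* time series — columns ``time_s``, ``run``, then one column per voxel,
  one row per 1 s sample;
* results — one row per voxel with parameters (deg for x/y/sigma, model
  samples for CST tau plus a derived ms column, seconds for DN-ST
  tau1/tau2), betas, R^2 and exclusion flags.

4D NIfTI input (with a JSON sidecar giving run boundaries) is supported
when nibabel is installed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import models
from .exceptions import ParameterError, ShapeError
from .solver import SolveResult

RESULT_UNITS = {
    "x": "deg", "y": "deg", "sigma": "deg",
    "tau": "model_samples_10ms", "tau_peak_ms": "ms", "n_exp": "1",
    "beta_sus": "1", "beta_tran": "1",
    "tau1": "s", "tau2": "s", "sigma_dn": "1", "n_dn": "1", "beta": "1",
    "r2_train": "1", "r2_cv": "1",
}


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def write_timeseries(
    path, values: np.ndarray, run_breaks, voxel_ids=None
) -> None:
    """Write a (n_samples, n_voxels) matrix as the canonical TSV format."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1:
        values = values.T
    n, n_vox = values.shape
    ids = list(voxel_ids) if voxel_ids is not None else [
        f"v{i:04d}" for i in range(n_vox)
    ]
    run = np.zeros(n, dtype=int)
    edges = list(run_breaks) + [n]
    for r, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        run[a:b] = r
    df = pd.DataFrame({"time_s": np.arange(n, dtype=float), "run": run})
    for i, vid in enumerate(ids):
        df[vid] = values[:, i]
    df.to_csv(path, sep="\t", index=False)


def read_timeseries(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a BOLD table; returns (values, run_breaks, voxel_ids).

    Accepts the canonical TSV or a 4D NIfTI with a ``.json`` sidecar
    containing ``run_breaks``.  NaN cells are a hard error naming the
    offending voxels; sampling must be 1 s.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        return _read_nifti(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001 - report parse context
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_s", "run"):
        if col not in df.columns:
            raise ParameterError(
                f"{path}: missing required column {col!r} in header line 1"
            )
    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0):
        raise ParameterError(
            f"{path}: sampling interval is not 1 s; resample first"
        )
    voxel_ids = [c for c in df.columns if c not in ("time_s", "run")]
    values = df[voxel_ids].to_numpy(dtype=float)
    bad = [v for i, v in enumerate(voxel_ids) if np.isnan(values[:, i]).any()]
    if bad:
        raise ParameterError(f"{path}: NaN samples in voxels {bad}")
    run = df["run"].to_numpy()
    run_breaks = np.flatnonzero(np.diff(run, prepend=run[0] - 1) != 0)
    return values, run_breaks, voxel_ids


def _read_nifti(path: Path):
    try:
        import nibabel as nib
    except ImportError as exc:
        raise ParameterError(
            "NIfTI input requires the optional nibabel dependency"
        ) from exc
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ShapeError(f"{path}: expected 4D NIfTI, got {data.ndim}D")
    n_t = data.shape[3]
    values = data.reshape(-1, n_t).T
    sidecar = path.with_suffix("").with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        run_breaks = np.asarray(meta.get("run_breaks", [0]), dtype=int)
    else:
        run_breaks = np.array([0])
    if np.isnan(values).any():
        raise ParameterError(f"{path}: NaN samples present")
    ids = [f"v{i:06d}" for i in range(values.shape[1])]
    return values, run_breaks, ids


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def results_to_frame(results: list[SolveResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row = {"voxel_id": res.voxel_id,
               "model": res.model_kind}
        row.update(models.params_to_dict(res.params))
        if "tau" in row:
            row["tau_peak_ms"] = models.cst_peak_time_ms(row["tau"])
        row["r2_train"] = res.r2_train
        row["r2_cv"] = res.r2_cv if res.r2_cv is not None else np.nan
        row["converged"] = res.converged
        for flag in ("low_r2", "tau_at_bound", "degenerate_voxel"):
            row[f"flag_{flag}"] = bool(res.flags.get(flag, False))
        rows.append(row)
    if not rows:
        cols = ["voxel_id", "model", "x", "y", "sigma", "r2_train",
                "r2_cv", "converged", "flag_low_r2", "flag_tau_at_bound",
                "flag_degenerate_voxel"]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def write_results(results: list[SolveResult], path) -> None:
    """One row per voxel; a leading comment line documents column units."""
    df = results_to_frame(results)
    units = "\t".join(
        f"{c}:{RESULT_UNITS.get(c, '-')}" for c in df.columns
    )
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# units\t{units}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of a full pipeline invocation."""

    design: str = "spatiotemporal"
    model_kind: str = "cst"
    n_runs: int = 9
    hrf_mode: str = "default"            # default | per-voxel
    seed: int = 0
    target_snr_db: float = 0.1
    n_voxels: int = 300
    grid: dict = field(default_factory=dict)
    fine: dict = field(default_factory=dict)
    out_dir: str = "stprf_out"

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
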