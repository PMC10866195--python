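"""Traveling-bar stimulus designs for spatiotemporal pRF mapping.

Two experimental designs are rendered as binarized space-time movies
``I(X, Y, t)`` on a 61x61 pixel grid covering the central 24 deg of the
visual field at 10 ms temporal resolution:

* the *spatiotemporal* design: a 3 deg bar sweeping the field in 9 steps
  along 4 orientations, where each 5 s bar location carries one of nine
  temporal presentation conditions (varying stimulus duration, ISI, and
  number of flashes);
* the *toonotopy* design: a conventional traveling-bar retinotopy run
  (12 steps, 2 s per step, continuous 8 Hz image refresh).

Sequences are stored compactly as a set of bar apertures plus a per-slot
(aperture, temporal profile) schedule; full frame arrays are materialized
on demand.  This factorization is exact — every frame equals
``aperture AND profile`` — and is what makes the forward models fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    InvalidDesignError,
    InvalidScheduleError,
    ScheduleOverflowError,
)

DT_MS = 10.0
"""Temporal resolution of stimulus sequences and neural predictions (ms)."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarGeometry:
    """Spatial geometry of a traveling-bar design.

    The bar width, step size and field diameter are linked:
    ``(n_steps - 1) * (bar_width - overlap) + bar_width == 2 * field_radius``
    so that the ``n_steps`` bar positions tile the field exactly with the
    requested overlap between adjacent positions.
    """

    field_radius_deg: float = 12.0
    bar_width_deg: float = 3.0
    overlap_deg: float = 0.375
    n_steps: int = 9
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    grid_px: int = 61

    def __post_init__(self) -> None:
        d = 2.0 * self.field_radius_deg
        tiling = (self.n_steps - 1) * self.step_deg + self.bar_width_deg
        if abs(tiling - d) > 1e-9:
            raise InvalidDesignError(
                f"bar positions do not tile the field: "
                f"{self.n_steps} steps of {self.step_deg:.4f} deg cover "
                f"{tiling:.4f} deg, field diameter is {d:.4f} deg"
            )
        if self.grid_px < 2 or self.bar_width_deg <= 0:
            raise InvalidDesignError("grid_px must be >= 2 and bar width > 0")

    @property
    def diameter_deg(self) -> float:
        return 2.0 * self.field_radius_deg

    @property
    def step_deg(self) -> float:
        """Center-to-center spacing of adjacent bar positions."""
        return self.bar_width_deg - self.overlap_deg

    @property
    def pixel_size_deg(self) -> float:
        return self.diameter_deg / self.grid_px

    @property
    def pixel_centers_deg(self) -> np.ndarray:
        """Pixel-center coordinates (deg, fixation-centered), ascending."""
        ps = self.pixel_size_deg
        return -self.field_radius_deg + ps * (np.arange(self.grid_px) + 0.5)

    def pixel_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid ``(X, Y)`` of pixel-center coordinates in degrees.

        Arrays are indexed ``[iy, ix]`` with x rightward and y upward.
        """
        c = self.pixel_centers_deg
        return np.meshgrid(c, c)

    def bar_centers_deg(self) -> np.ndarray:
        """Bar band-center positions along the sweep axis, one per step."""
        start = -self.field_radius_deg + self.bar_width_deg / 2.0
        return start + self.step_deg * np.arange(self.n_steps)

    @classmethod
    def spatiotemporal(cls) -> "BarGeometry":
        return cls()

    @classmethod
    def toonotopy(cls) -> "BarGeometry":
        # Bar width follows from 12 steps tiling 24 deg with 0.27 deg overlap.
        width = (24.0 + 11 * 0.27) / 12.0
        return cls(bar_width_deg=width, overlap_deg=0.27, n_steps=12)


# ---------------------------------------------------------------------------
# Temporal conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalCondition:
    """One of the nine 5 s presentation schedules of the spatiotemporal design.

    ``n_images`` stimulus-on epochs of ``on_ms`` separated by ``isi_ms``
    fill (part of) the ``slot_ms`` bar-location slot; residual time at the
    end of the slot is off.
    """

    id: int
    on_ms: float
    isi_ms: float
    n_images: int
    slot_ms: float = 5000.0

    def __post_init__(self) -> None:
        need = self.n_images * self.on_ms + (self.n_images - 1) * self.isi_ms
        if need > self.slot_ms + 1e-9:
            raise ScheduleOverflowError(
                f"condition {self.id}: {self.n_images} x {self.on_ms} ms "
                f"with {self.isi_ms} ms ISI needs {need} ms > {self.slot_ms} ms"
            )


def default_conditions() -> dict[int, TemporalCondition]:
    """The nine temporal conditions of the spatiotemporal mapping design.

    Conditions 1-3 share a 133 ms stimulus duration with ISIs of 33, 200
    and 867 ms; conditions 4-6 share a 133 ms ISI with durations 33, 200
    and 867 ms; conditions 1, 7 and 8 share ~4 s total on-time delivered
    as 30, 15 and 5 images; condition 9 is a single uninterrupted 5 s
    presentation.
    """
    t = TemporalCondition
    return {
        1: t(1, 133.0, 33.0, 30),
        2: t(2, 133.0, 200.0, 15),
        3: t(3, 133.0, 867.0, 5),
        4: t(4, 33.0, 133.0, 30),
        5: t(5, 200.0, 133.0, 15),
        6: t(6, 867.0, 133.0, 5),
        7: t(7, 4000.0 / 15, 1000.0 / 15, 15),
        8: t(8, 800.0, 200.0, 5),
        9: t(9, 5000.0, 0.0, 1),
    }


def build_temporal_profile(cond: TemporalCondition, dt_ms: float = DT_MS) -> np.ndarray:
    """Binary on/off vector for one bar-location slot.

    Image on/off event times are laid out in continuous milliseconds and
    each boundary is rounded to the nearest frame, so cumulative rounding
    error never exceeds half a frame.
    """
    n_frames = int(round(cond.slot_ms / dt_ms))
    out = np.zeros(n_frames, dtype=np.uint8)
    period = cond.on_ms + cond.isi_ms
    for i in range(cond.n_images):
        a = int(round(i * period / dt_ms))
        b = int(round((i * period + cond.on_ms) / dt_ms))
        if b > n_frames:
            raise ScheduleOverflowError(
                f"condition {cond.id}: image {i} ends at {b * dt_ms} ms, "
                f"past the {cond.slot_ms} ms slot"
            )
        out[a:b] = 1
    return out


# ---------------------------------------------------------------------------
# Apertures
# ---------------------------------------------------------------------------

def build_bar_aperture(
    geometry: BarGeometry, angle_deg: float, step: int
) -> np.ndarray:
    """Binary bar aperture (grid_px x grid_px) for one sweep position.

    ``angle_deg`` is the sweep (motion) direction; the bar's long axis is
    perpendicular to it.  Pixels outside the circular field are always 0.
    Array is indexed ``[iy, ix]`` with y upward.
    """
    if angle_deg not in geometry.angles_deg:
        raise InvalidDesignError(
            f"angle {angle_deg} not in design angles {geometry.angles_deg}"
        )
    if not 0 <= step < geometry.n_steps:
        raise InvalidDesignError(
            f"step {step} outside [0, {geometry.n_steps})"
        )
    X, Y = geometry.pixel_grid()
    theta = np.deg2rad(angle_deg)
    proj = X * np.cos(theta) + Y * np.sin(theta)
    center = geometry.bar_centers_deg()[step]
    in_band = np.abs(proj - center) <= geometry.bar_width_deg / 2.0
    in_field = X**2 + Y**2 <= geometry.field_radius_deg**2
    return (in_band & in_field).astype(np.uint8)


# ---------------------------------------------------------------------------
# Run schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunSchedule:
    """Per-run assignment of temporal conditions to bar locations.

    ``conditions[a, s]`` is the condition id shown at sweep angle index
    ``a``, step ``s``.  ``angles_deg`` fixes the sweep order within the run.
    """

    angles_deg: tuple[float, ...]
    conditions: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.angles_deg):
            raise InvalidScheduleError("one condition row required per angle")
        n = {len(row) for row in self.conditions}
        if len(n) != 1:
            raise InvalidScheduleError("ragged condition table")

    @property
    def n_steps(self) -> int:
        return len(self.conditions[0])

    def validate(self, geometry: BarGeometry, condition_ids) -> None:
        if self.n_steps != geometry.n_steps:
            raise InvalidScheduleError(
                f"schedule has {self.n_steps} steps, geometry {geometry.n_steps}"
            )
        if tuple(self.angles_deg) != tuple(geometry.angles_deg):
            raise InvalidScheduleError("schedule angles differ from geometry")
        ids = set(condition_ids)
        for row in self.conditions:
            for c in row:
                if c not in ids:
                    raise InvalidScheduleError(f"unknown condition id {c}")


def counterbalanced_schedules(
    geometry: BarGeometry | None = None,
    n_runs: int = 9,
    seed: int | None = 0,
) -> list[RunSchedule]:
    """Latin-square-style condition assignment across runs.

    Within each angle, conditions are a seeded random permutation cycled
    by one step per run, so across ``n_runs`` (= number of conditions)
    runs each condition occurs exactly once at each bar location.
    """
    geometry = geometry or BarGeometry.spatiotemporal()
    n_cond = geometry.n_steps
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_cond) for _ in geometry.angles_deg]
    # Independent cyclic offsets per angle keep runs visually varied.
    offsets = [rng.integers(n_cond) for _ in geometry.angles_deg]
    schedules = []
    for r in range(n_runs):
        rows = tuple(
            tuple(int(perms[a][(s + r + offsets[a]) % n_cond]) + 1
                  for s in range(geometry.n_steps))
            for a in range(len(geometry.angles_deg))
        )
        schedules.append(RunSchedule(tuple(geometry.angles_deg), rows))
    return schedules


# ---------------------------------------------------------------------------
# Stimulus sequences
# ---------------------------------------------------------------------------

@dataclass
class StimulusSequence:
    """A binarized space-time stimulus movie in factored form.

    Every frame is ``apertures[slot.aperture] * profiles[slot.profile][k]``
    for the slot covering that frame (0 outside any slot).  ``slots`` is a
    structured array with fields ``start`` (frame), ``n_frames``,
    ``aperture``, ``profile``, ``condition`` and ``run``.
    """

    apertures: np.ndarray          # (n_apertures, grid_px, grid_px) uint8
    profiles: list[np.ndarray]     # binary on/off vectors, frames
    slots: np.ndarray              # structured, see above
    n_frames: int
    run_breaks: np.ndarray         # start frame of each run
    geometry: BarGeometry
    dt_ms: float = DT_MS
    design_label: str = "spatiotemporal"
    conditions: dict[int, TemporalCondition] = field(default_factory=dict)

    SLOT_DTYPE = np.dtype(
        [("start", np.int64), ("n_frames", np.int64), ("aperture", np.int64),
         ("profile", np.int64), ("condition", np.int64), ("run", np.int64)]
    )

    # -- basic properties ---------------------------------------------------

    @property
    def n_runs(self) -> int:
        return len(self.run_breaks)

    @property
    def frame_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt_ms / 1000.0

    def run_slices(self) -> list[slice]:
        edges = list(self.run_breaks) + [self.n_frames]
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    # -- materialization ----------------------------------------------------

    def frames(self, start: int = 0, stop: int | None = None) -> np.ndarray:
        """Materialize frames ``[start, stop)`` as a (t, ny, nx) uint8 array.

        The full 9-run movie is ~600 MB; materialize segments as needed.
        """
        stop = self.n_frames if stop is None else stop
        out = np.zeros((stop - start, *self.apertures.shape[1:]), dtype=np.uint8)
        for slot in self.slots:
            s0, s1 = slot["start"], slot["start"] + slot["n_frames"]
            a, b = max(s0, start), min(s1, stop)
            if a >= b:
                continue
            prof = self.profiles[slot["profile"]][a - s0:b - s0]
            out[a - start:b - start] = (
                prof[:, None, None] * self.apertures[slot["aperture"]]
            )
        return out

    def drive(self, rf: np.ndarray) -> np.ndarray:
        """Spatial drive time course: per-frame dot product of stimulus and RF.

        Exact (uses the factored representation; no frame materialization).
        """
        if rf.shape != self.apertures.shape[1:]:
            from .exceptions import ShapeError
            raise ShapeError(
                f"RF grid {rf.shape} != stimulus grid {self.apertures.shape[1:]}"
            )
        ov = self.apertures.reshape(len(self.apertures), -1) @ rf.ravel()
        out = np.zeros(self.n_frames)
        for slot in self.slots:
            s0 = slot["start"]
            prof = self.profiles[slot["profile"]]
            out[s0:s0 + slot["n_frames"]] = ov[slot["aperture"]] * prof
        return out

    def subset_runs(self, run_idx) -> "StimulusSequence":
        """New sequence containing only the given runs (re-timed from 0)."""
        run_idx = list(run_idx)
        slices = self.run_slices()
        new_slots = []
        new_breaks = []
        offset = 0
        for new_r, r in enumerate(run_idx):
            sl = slices[r]
            new_breaks.append(offset)
            for slot in self.slots[self.slots["run"] == r]:
                s = slot.copy()
                s["start"] = slot["start"] - sl.start + offset
                s["run"] = new_r
                new_slots.append(s)
            offset += sl.stop - sl.start
        return StimulusSequence(
            apertures=self.apertures,
            profiles=self.profiles,
            slots=np.array(new_slots, dtype=self.SLOT_DTYPE),
            n_frames=offset,
            run_breaks=np.array(new_breaks),
            geometry=self.geometry,
            dt_ms=self.dt_ms,
            design_label=self.design_label,
            conditions=self.conditions,
        )

    # -- export -------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write the factored movie (npz) plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "stimulus.npz",
            apertures=self.apertures,
            slots=self.slots,
            run_breaks=self.run_breaks,
            **{f"profile_{i}": p for i, p in enumerate(self.profiles)},
        )
        sidecar = {
            "design_label": self.design_label,
            "dt_ms": self.dt_ms,
            "n_frames": int(self.n_frames),
            "grid_px": self.geometry.grid_px,
            "degrees_per_pixel": self.geometry.pixel_size_deg,
            "field_radius_deg": self.geometry.field_radius_deg,
            "n_runs": self.n_runs,
        }
        (directory / "stimulus.json").write_text(json.dumps(sidecar, indent=2))


def _aperture_bank(geometry: BarGeometry) -> tuple[np.ndarray, dict]:
    """All (angle, step) apertures and an index map."""
    apertures = []
    index = {}
    for a, ang in enumerate(geometry.angles_deg):
        for s in range(geometry.n_steps):
            index[(a, s)] = len(apertures)
            apertures.append(build_bar_aperture(geometry, ang, s))
    return np.stack(apertures), index


def assemble_run(
    geometry: BarGeometry,
    schedule: RunSchedule,
    conditions: dict[int, TemporalCondition] | None = None,
    dt_ms: float = DT_MS,
) -> StimulusSequence:
    """Render a single spatiotemporal run: 4 sweeps x 9 steps x 5 s slots."""
    conditions = conditions or default_conditions()
    schedule.validate(geometry, conditions.keys())
    return _assemble(geometry, [schedule], conditions, dt_ms, "spatiotemporal")


def _assemble(geometry, schedules, conditions, dt_ms, label) -> StimulusSequence:
    apertures, ap_index = _aperture_bank(geometry)
    profiles = []
    prof_index = {}
    for cid in sorted(conditions):
        prof_index[cid] = len(profiles)
        profiles.append(build_temporal_profile(conditions[cid], dt_ms))
    slot_frames = len(profiles[0])
    slots = []
    run_breaks = []
    t = 0
    for r, sched in enumerate(schedules):
        run_breaks.append(t)
        for a in range(len(geometry.angles_deg)):
            for s in range(geometry.n_steps):
                cid = sched.conditions[a][s]
                slots.append(
                    (t, slot_frames, ap_index[(a, s)], prof_index[cid], cid, r)
                )
                t += slot_frames
    return StimulusSequence(
        apertures=apertures,
        profiles=profiles,
        slots=np.array(slots, dtype=StimulusSequence.SLOT_DTYPE),
        n_frames=t,
        run_breaks=np.array(run_breaks),
        geometry=geometry,
        dt_ms=dt_ms,
        design_label=label,
        conditions=dict(conditions),
    )


def spatiotemporal_sequence(
    geometry: BarGeometry | None = None,
    n_runs: int = 9,
    seed: int | None = 0,
    conditions: dict[int, TemporalCondition] | None = None,
    dt_ms: float = DT_MS,
) -> StimulusSequence:
    """The full counterbalanced spatiotemporal mapping experiment."""
    geometry = geometry or BarGeometry.spatiotemporal()
    conditions = conditions or default_conditions()
    schedules = counterbalanced_schedules(geometry, n_runs, seed)
    for sched in schedules:
        sched.validate(geometry, conditions.keys())
    return _assemble(geometry, schedules, conditions, dt_ms, "spatiotemporal")


def toonotopy_sequence(
    geometry: BarGeometry | None = None,
    n_runs: int = 4,
    step_s: float = 2.0,
    refresh_hz: float = 8.0,
    refresh_transients: bool = True,
    dt_ms: float = DT_MS,
) -> StimulusSequence:
    """The conventional traveling-bar (toonotopy) design.

    Each 2 s step shows a bar whose image content refreshes at 8 Hz.  The
    default rendering inserts a one-frame off gap at each 125 ms refresh,
    so image changes drive transient channels — the binarized movie of a
    stimulus whose content changes at 8 Hz is itself time varying.  With
    ``refresh_transients=False`` the bar is a solid on-block instead; that
    rendering makes the compressive spatiotemporal model's size and
    exponent parameters mutually unidentifiable (distinct parameters give
    identical BOLD), so it is not the default.
    """
    geometry = geometry or BarGeometry.toonotopy()
    slot_ms = step_s * 1000.0
    refresh_ms = 1000.0 / refresh_hz
    n_images = int(round(slot_ms / refresh_ms))
    if refresh_transients:
        cond = TemporalCondition(1, on_ms=refresh_ms - dt_ms, isi_ms=dt_ms,
                                 n_images=n_images, slot_ms=slot_ms)
    else:
        cond = TemporalCondition(1, on_ms=slot_ms, isi_ms=0.0, n_images=1,
                                 slot_ms=slot_ms)
    conditions = {1: cond}
    rows = tuple(
        tuple(1 for _ in range(geometry.n_steps))
        for _ in geometry.angles_deg
    )
    schedules = [RunSchedule(tuple(geometry.angles_deg), rows)] * n_runs
    seq = _assemble(geometry, schedules, conditions, dt_ms, "toonotopy")
    if refresh_transients:
        # one-frame off gap at each refresh boundary; 125 ms is 12.5
        # frames, so boundaries are rounded per event (epochs alternate
        # 12/13 frames) rather than built from a fixed on/ISI pair
        prof = np.ones(int(round(slot_ms / dt_ms)), dtype=np.uint8)
        bounds = np.round(
            np.arange(1, n_images) * refresh_ms / dt_ms
        ).astype(int)
        prof[bounds - 1] = 0
        seq.profiles[0] = prof
    return seq
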