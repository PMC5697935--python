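"""Domain containers and session I/O for trial-structured ephys recordings.

A *session* binds a trial/event table, a set of spike trains (with region and
waveform metadata), and one LFP trace per region.  Timestamps are seconds from
session start (64-bit floats, 0-based); intervals are half-open ``[start, end)``.

On disk a session is a directory::

    trials.tsv    per-trial events (TrialTable columns)
    spikes.tsv    one row per spike: unit_id, region, width, spike_time
    lfp.h5        one group per region with a ``samples`` dataset and
                  ``fs`` / ``t0`` attributes
    session.json  task configuration, RNG seed, unit registry, optional
                  ground-truth record for synthetic sessions
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

REGIONS = ("mPFC", "VTA")

TRIAL_COLUMNS = [
    "trial_id", "block", "cue_time", "action_time", "reward_time",
    "shock_flag", "rt", "immobile_rt", "reward_rt",
]

#: default baseline epoch: 2 s window beginning 2.5 s before cue onset
BASELINE_WINDOW = (-2.5, -0.5)


class SessionLoadError(IOError):
    """A session file is missing or unreadable."""


class ValidationError(ValueError):
    """A session invariant is violated; the message names the offender."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class TrialTable:
    """Per-trial events, block labels, shock flags and derived latencies.

    ``df`` columns: trial_id, block (1..n_blocks), cue_time, action_time,
    reward_time (s), shock_flag (bool), rt (action-cue), immobile_rt,
    reward_rt (reward-retrieval latency).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"trial table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def blocks(self) -> np.ndarray:
        return self.df["block"].to_numpy()

    def event_times(self, align: str) -> np.ndarray:
        """Timestamps of the alignment event (cue/action/reward); ``baseline``
        maps to cue (baseline windows are cue-relative)."""
        col = {"cue": "cue_time", "action": "action_time",
               "reward": "reward_time", "baseline": "cue_time"}.get(align)
        if col is None:
            raise ValueError(f"unknown alignment event {align!r}")
        return self.df[col].to_numpy(float)

    def validate(self, trials_per_block: int | None = None) -> None:
        df = self.df
        for _, row in df.iterrows():
            tid = int(row.trial_id)
            if not (row.cue_time < row.action_time < row.reward_time):
                raise ValidationError(
                    f"trial {tid}: events out of order "
                    f"(cue {row.cue_time}, action {row.action_time}, "
                    f"reward {row.reward_time})")
            if abs(row.rt - (row.action_time - row.cue_time)) > 1e-9:
                raise ValidationError(
                    f"trial {tid}: rt {row.rt} != action-cue "
                    f"{row.action_time - row.cue_time}")
            if row.immobile_rt > row.rt + 1e-9:
                raise ValidationError(
                    f"trial {tid}: immobile_rt {row.immobile_rt} > rt {row.rt}")
            if row.shock_flag and row.block == 1:
                raise ValidationError(f"trial {tid}: shock flagged in block 1")
        if trials_per_block is not None:
            counts = df.groupby("block").size()
            bad = counts[counts != trials_per_block]
            if len(bad):
                raise ValidationError(
                    f"block sizes {dict(counts)} != configured "
                    f"{trials_per_block} trials per block")

    def copy(self) -> "TrialTable":
        return TrialTable(self.df.copy())


@dataclass
class SpikeTrain:
    """One sorted unit: strictly increasing spike times plus metadata."""

    unit_id: str
    region: str
    spike_times: np.ndarray
    waveform_width: float  # ms
    baseline_rate: float | None = None  # Hz, computed and cached

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)

    def validate(self, duration: float | None = None) -> None:
        t = self.spike_times
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if t.size and t[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if duration is not None and t.size and t[-1] > duration:
            raise ValidationError(
                f"unit {self.unit_id}: spike at {t[-1]:.3f}s beyond session "
                f"duration {duration:.3f}s")
        if self.waveform_width <= 0:
            raise ValidationError(f"unit {self.unit_id}: non-positive width")
        if self.region not in REGIONS:
            raise ValidationError(
                f"unit {self.unit_id}: unknown region {self.region!r}")

    def n_spikes_in(self, windows: np.ndarray) -> int:
        """Count spikes falling in any of the (start, end) rows of `windows`."""
        lo = np.searchsorted(self.spike_times, windows[:, 0], "left")
        hi = np.searchsorted(self.spike_times, windows[:, 1], "left")
        return int(np.sum(hi - lo))


@dataclass
class LFPChannel:
    """Continuous field potential from one region."""

    region: str
    samples: np.ndarray  # microvolts
    fs: float  # Hz
    t0: float = 0.0  # session time of samples[0]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def validate(self, min_fs: float = 250.0) -> None:
        if self.fs < min_fs:
            raise ValidationError(
                f"LFP {self.region}: fs {self.fs} Hz below required {min_fs}")

    def segment(self, start: float, end: float) -> np.ndarray:
        """Samples in session-time [start, end)."""
        i0 = int(np.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((end - self.t0) * self.fs - 1e-9))
        if i0 < 0 or i1 > self.samples.size:
            raise ValidationError(
                f"LFP {self.region}: segment [{start:.3f},{end:.3f})s outside "
                f"recording")
        return self.samples[i0:i1]


@dataclass
class PeriEventTensor:
    """unit x trial x bin spike counts (or rates) with explicit bin geometry.

    ``data[u, t, b]`` counts spikes in ``[event_t + starts[b],
    event_t + starts[b] + bin_width)``.  Bin *starts* advance by ``bin_step``
    (bins overlap when step < width).
    """

    data: np.ndarray
    align_event: str
    window: tuple[float, float]
    bin_width: float
    bin_step: float
    included_trials: np.ndarray
    unit_ids: list[str]
    is_rate: bool = False

    @property
    def n_bins(self) -> int:
        return self.data.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.window[0] + self.bin_step * np.arange(self.n_bins)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_starts + self.bin_width / 2.0


@dataclass
class Session:
    """A complete recording: trials + spike trains + per-region LFP."""

    trials: TrialTable
    units: list[SpikeTrain]
    lfp: dict[str, LFPChannel]
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        d = self.meta.get("duration")
        if d is not None:
            return float(d)
        return max(ch.t0 + ch.duration for ch in self.lfp.values())

    def units_in(self, region: str) -> list[SpikeTrain]:
        return [u for u in self.units if u.region == region]

    def unit(self, unit_id: str) -> SpikeTrain:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def validate(self) -> None:
        self.trials.validate(self.meta.get("trials_per_block"))
        dur = self.duration
        for u in self.units:
            u.validate(duration=dur)
        for ch in self.lfp.values():
            ch.validate()


# ---------------------------------------------------------------------------
# operations


def exclude_shock_trials(trials: TrialTable) -> TrialTable:
    """Drop trials on which a foot shock was delivered.

    Shock-delivery trials carry electrical artifacts and are removed from all
    neural analyses; the input table is left untouched and trial ordering is
    preserved.
    """
    df = trials.df
    kept = df.loc[~df["shock_flag"].astype(bool)].copy()
    for b in df["block"].unique():
        if not (kept["block"] == b).any():
            warnings.warn(f"block {b} has no trials left after shock exclusion")
    return TrialTable(kept.reset_index(drop=True))


def baseline_windows(trials: TrialTable,
                     window: tuple[float, float] = BASELINE_WINDOW) -> np.ndarray:
    """(n_trials, 2) array of absolute baseline (start, end) times."""
    cue = trials.event_times("cue")
    return np.column_stack([cue + window[0], cue + window[1]])


def compute_baseline_rates(session: Session,
                           window: tuple[float, float] = BASELINE_WINDOW) -> None:
    """Fill ``baseline_rate`` on every unit from the pre-cue baseline epoch."""
    wins = baseline_windows(session.trials, window)
    total = wins.shape[0] * (window[1] - window[0])
    for u in session.units:
        u.baseline_rate = u.n_spikes_in(wins) / total


# ---------------------------------------------------------------------------
# I/O


def write_session(session: Session, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.df.to_csv(path / "trials.tsv", sep="\t", index=False)

    rows = []
    for u in session.units:
        for t in u.spike_times:
            rows.append((u.unit_id, u.region, u.waveform_width, t))
    pd.DataFrame(rows, columns=["unit_id", "region", "width", "spike_time"]) \
        .to_csv(path / "spikes.tsv", sep="\t", index=False)

    with h5py.File(path / "lfp.h5", "w") as f:
        for region, ch in session.lfp.items():
            g = f.create_group(region)
            g.create_dataset("samples", data=ch.samples)
            g.attrs["fs"] = ch.fs
            g.attrs["t0"] = ch.t0

    meta = dict(session.meta)
    meta["units"] = [
        {"unit_id": u.unit_id, "region": u.region, "width": u.waveform_width}
        for u in session.units
    ]
    meta.setdefault("duration", session.duration)
    (path / "session.json").write_text(json.dumps(meta, indent=1, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_session(path: str | Path, validate: bool = True) -> Session:
    """Load a session directory, recompute derived fields, and validate.

    ``rt`` is recomputed as action-cue; a mismatch with the stored column is a
    validation error (strict by default, pass ``validate=False`` to skip).
    """
    path = Path(path)
    for fname in ("trials.tsv", "spikes.tsv", "lfp.h5", "session.json"):
        if not (path / fname).exists():
            raise SessionLoadError(f"missing session file: {path / fname}")

    trials_df = pd.read_csv(path / "trials.tsv", sep="\t")
    trials_df["shock_flag"] = trials_df["shock_flag"].astype(bool)
    rt = trials_df["action_time"] - trials_df["cue_time"]
    if validate and np.any(np.abs(rt - trials_df["rt"]) > 1e-9):
        bad = int(trials_df.loc[np.abs(rt - trials_df["rt"]) > 1e-9,
                                "trial_id"].iloc[0])
        raise ValidationError(f"trial {bad}: stored rt != action-cue")
    trials_df["rt"] = rt
    trials = TrialTable(trials_df)

    meta = json.loads((path / "session.json").read_text())
    registry = {u["unit_id"]: u for u in meta.get("units", [])}

    spikes_df = pd.read_csv(path / "spikes.tsv", sep="\t")
    units: list[SpikeTrain] = []
    seen = set()
    for uid, sub in spikes_df.groupby("unit_id", sort=False):
        uid = str(uid)
        seen.add(uid)
        units.append(SpikeTrain(
            unit_id=uid,
            region=str(sub["region"].iloc[0]),
            spike_times=np.sort(sub["spike_time"].to_numpy(float)),
            waveform_width=float(sub["width"].iloc[0]),
        ))
    for uid, info in registry.items():  # units with zero spikes
        if uid not in seen:
            units.append(SpikeTrain(uid, info["region"], np.empty(0),
                                    float(info["width"])))
    order = {uid: i for i, uid in enumerate(registry)}
    units.sort(key=lambda u: order.get(u.unit_id, len(order)))

    lfp: dict[str, LFPChannel] = {}
    with h5py.File(path / "lfp.h5", "r") as f:
        for region in f:
            g = f[region]
            lfp[region] = LFPChannel(region=region,
                                     samples=g["samples"][:],
                                     fs=float(g.attrs["fs"]),
                                     t0=float(g.attrs["t0"]))

    session = Session(trials=trials, units=units, lfp=lfp, meta=meta)
    compute_baseline_rates(session)
    if validate:
        session.validate()
    return session


def sessions_equal(a: Session, b: Session, atol: float = 1e-9) -> bool:
    """Field-wise equality of two sessions at declared precision."""
    if len(a.trials) != len(b.trials):
        return False
    for col in TRIAL_COLUMNS:
        x, y = a.trials.df[col].to_numpy(), b.trials.df[col].to_numpy()
        if col in ("trial_id", "block", "shock_flag"):
            if not np.array_equal(x, y):
                return False
        elif not np.allclose(x.astype(float), y.astype(float), atol=atol):
            return False
    if {u.unit_id for u in a.units} != {u.unit_id for u in b.units}:
        return False
    for u in a.units:
        v = b.unit(u.unit_id)
        if u.region != v.region or abs(u.waveform_width - v.waveform_width) > atol:
            return False
        if u.spike_times.size != v.spike_times.size:
            return False
        if u.spike_times.size and not np.allclose(u.spike_times, v.spike_times,
                                                  atol=atol):
            return False
    if set(a.lfp) != set(b.lfp):
        return False
    for region, ch in a.lfp.items():
        d = b.lfp[region]
        if ch.fs != d.fs or abs(ch.t0 - d.t0) > atol:
            return False
        if not np.allclose(ch.samples, d.samples, atol=1e-6):
            return False
    return True
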