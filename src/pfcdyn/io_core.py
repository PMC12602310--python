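"""Validated in-memory containers and file round-trips for LFP, spikes and block schedules.

Time base: all times are seconds (float64) on the recording clock, zero at file
start; the injection time is stored absolutely. Bins and block intervals are
half-open ``[t, t + dt)``.

On-disk layout:

* LFP: HDF5 with ``/lfp`` (samples x channels ``int16``), attrs ``fs`` and
  ``uv_per_bit``, and a ``/channels`` table (``index``, ``depth_um``,
  ``region``).
* Spikes: ``spikes.csv`` (``unit_id``, ``spike_time_s``) plus ``units.csv``
  metadata and an optional ``waveforms.csv`` (one row per unit).
* Schedule: YAML mirroring :class:`BlockSchedule` field-for-field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pfcdyn")

REGIONS = ("IL", "PL", "CG")
#: ventral-to-dorsal region order used for the normalised-depth axis
REGION_INDEX = {"IL": 0, "PL": 1, "CG": 2}
DRUGS = ("saline", "psi_0.3", "psi_1.0")
BLOCK_KINDS = ("rest", "task")
PHASES = ("pre", "post")
CELL_CLASSES = ("RS", "NS", "WS", "unclassified")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(ValueError):
    """An in-memory object violates a container invariant."""


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """One 15-min (or scaled) behavioural epoch of the session."""

    kind: str          # rest | task
    phase: str         # pre | post (relative to injection)
    t_start: float     # s, recording clock
    t_end: float       # s

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValidationError(f"unknown block kind {self.kind!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown block phase {self.phase!r}")
        if not (np.isfinite(self.t_start) and np.isfinite(self.t_end)):
            raise ValidationError("block times must be finite")
        if self.t_end <= self.t_start:
            raise ValidationError(
                f"block duration must be positive ({self.t_start}..{self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class BlockSchedule:
    """The temporal skeleton of one session: typed blocks anchored to an injection.

    Day-0 sessions interleave pre-injection baseline rest/task blocks with
    post-injection blocks; days 1/2/6 are drug-free follow-ups whose blocks are
    all ``phase='post'``.
    """

    subject_id: str
    drug: str                  # saline | psi_0.3 | psi_1.0
    injection_time: float      # s, absolute on the recording clock
    day: int                   # 0, 1, 2 or 6
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug condition {self.drug!r}")
        if self.day not in (0, 1, 2, 6):
            raise ValidationError(f"day must be one of 0,1,2,6, got {self.day}")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if not self.blocks:
            raise ValidationError("schedule has no blocks")
        prev_end = -np.inf
        for b in self.blocks:
            if b.t_start < prev_end:
                raise ValidationError(
                    f"blocks overlap or are out of order near t={b.t_start}"
                )
            prev_end = b.t_end
        if self.day == 0:
            for b in self.blocks:
                if b.phase == "post" and b.t_start < self.injection_time:
                    raise ValidationError(
                        "post block starts before injection on day 0"
                    )
            combos = {(b.kind, b.phase) for b in self.blocks}
            missing = {(k, p) for k in BLOCK_KINDS for p in PHASES} - combos
            if missing:
                raise ValidationError(
                    f"day-0 schedule missing (kind, phase) combinations: {sorted(missing)}"
                )

    def select(self, kind: str | None = None, phase: str | None = None) -> tuple[Block, ...]:
        """Blocks filtered by kind and/or phase, in temporal order."""
        return tuple(
            b for b in self.blocks
            if (kind is None or b.kind == kind) and (phase is None or b.phase == phase)
        )

    @property
    def t_end(self) -> float:
        return self.blocks[-1].t_end


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def normalized_depths(channels: pd.DataFrame,
                      region_extents_um: dict[str, float] | None = None) -> np.ndarray:
    """Map per-channel (region, depth) to a common [0, 3) axis.

    Depth is measured upward from the ventral boundary of each region; the
    three regions are concatenated ventral-to-dorsal as IL=[0,1), PL=[1,2),
    CG=[2,3), each normalised by its own dorsoventral extent so probes with
    different region coverage are comparable.
    """
    if region_extents_um is None:
        region_extents_um = {}
        for r in REGIONS:
            d = channels.loc[channels["region"] == r, "depth_um"]
            if len(d):
                region_extents_um[r] = max(float(d.max()) * 1.0001, 1.0)
    out = np.full(len(channels), np.nan)
    for i, (reg, depth) in enumerate(zip(channels["region"], channels["depth_um"])):
        if reg in REGION_INDEX:
            ext = region_extents_um.get(reg, np.nan)
            out[i] = REGION_INDEX[reg] + min(float(depth) / ext, 0.999999)
    return out


@dataclass
class LfpRecording:
    """Continuous multi-channel LFP in microvolts with channel geometry.

    ``channels`` is a DataFrame with columns ``index``, ``depth_um`` (µm above
    the ventral boundary of the channel's region), ``region`` (IL/PL/CG/other)
    and ``normalized_depth``.
    """

    data: np.ndarray           # samples x channels, µV
    fs: float                  # Hz
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("LFP data must be samples x channels")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[1]:
            raise ValidationError(
                f"channel metadata ({len(self.channels)}) does not match "
                f"channel count ({self.data.shape[1]})"
            )
        if not np.all(np.isfinite(self.channels["depth_um"].to_numpy(float))):
            raise ValidationError("channel depths must be finite")
        if "normalized_depth" not in self.channels:
            self.channels = self.channels.assign(
                normalized_depth=normalized_depths(self.channels)
            )
        nd = self.channels["normalized_depth"].to_numpy(float)
        known = ~np.isnan(nd)
        if known.sum() >= 2 and not (np.diff(nd[known]) != 0).all():
            raise ValidationError("normalized_depth must be strictly monotone along the probe")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def segment(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples in the half-open window [t_start, t_end)."""
        i0 = int(np.ceil(t_start * self.fs - 1e-9))
        i1 = int(np.ceil(t_end * self.fs - 1e-9))
        return self.data[max(i0, 0):min(i1, self.n_samples)]

    def region_channels(self, region: str) -> np.ndarray:
        return np.flatnonzero((self.channels["region"] == region).to_numpy())


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

@dataclass
class UnitQcMetrics:
    """Spike-sorting quality triple (refractory contamination, missed-spike
    fraction, epoch coverage)."""

    isi_violations: float      # rate-ratio, >= 0
    amplitude_cutoff: float    # estimated missed-spike fraction in [0, 0.5]
    presence_ratio: float      # fraction of epochs with >= 1 spike, in [0, 1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.isi_violations, self.amplitude_cutoff,
                                   self.presence_ratio])):
            raise ValidationError("QC metrics must be finite")
        if not 0.0 <= self.presence_ratio <= 1.0:
            raise ValidationError("presence_ratio must lie in [0, 1]")
        if not 0.0 <= self.amplitude_cutoff <= 0.5:
            raise ValidationError("amplitude_cutoff must lie in [0, 0.5]")


@dataclass
class Unit:
    """Spike times plus metadata for a single sorted unit."""

    unit_id: str
    spike_times: np.ndarray            # s, sorted ascending
    region: str                        # IL | PL | CG
    depth_um: float
    waveform: np.ndarray | None = None  # mean waveform, µV
    waveform_fs: float = 30000.0
    amplitudes: np.ndarray | None = None  # per-spike amplitude, arbitrary units
    qc: UnitQcMetrics | None = None
    cell_class: str = "unclassified"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)
        if self.spike_times.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if len(self.spike_times) and np.any(np.diff(self.spike_times) < 0):
            raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
        if len(self.spike_times) and self.spike_times[0] < 0:
            raise ValidationError(f"unit {self.unit_id}: negative spike time")
        if self.region not in REGIONS:
            raise ValidationError(f"unit {self.unit_id}: unknown region {self.region!r}")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"unknown cell class {self.cell_class!r}")
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def spikes_in(self, t_start: float, t_end: float) -> np.ndarray:
        """Spike times within the half-open window [t_start, t_end)."""
        i0 = np.searchsorted(self.spike_times, t_start, side="left")
        i1 = np.searchsorted(self.spike_times, t_end, side="left")
        return self.spike_times[i0:i1]

    def rate(self, t_start: float, t_end: float) -> float:
        return len(self.spikes_in(t_start, t_end)) / (t_end - t_start)


@dataclass
class UnitSet:
    """An ordered collection of units with unique ids."""

    units: list[Unit] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValidationError("unit ids must be unique")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def __getitem__(self, key: int | str) -> Unit:
        if isinstance(key, str):
            for u in self.units:
                if u.unit_id == key:
                    return u
            raise KeyError(key)
        return self.units[key]

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def by_region(self, region: str) -> "UnitSet":
        return UnitSet([u for u in self.units if u.region == region])

    def by_class(self, cell_class: str) -> "UnitSet":
        return UnitSet([u for u in self.units if u.cell_class == cell_class])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for u in self.units:
            rows.append({
                "unit_id": u.unit_id, "region": u.region, "depth_um": u.depth_um,
                "n_spikes": u.n_spikes, "cell_class": u.cell_class,
                "isi_violations": u.qc.isi_violations if u.qc else np.nan,
                "amplitude_cutoff": u.qc.amplitude_cutoff if u.qc else np.nan,
                "presence_ratio": u.qc.presence_ratio if u.qc else np.nan,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the study's defaults.

    Welch spectra use 4-s windows with no overlap (0.25 Hz bins at 2.5 kHz);
    the HFO band is 80-110 Hz with 1/f-interpolation flanks at 60-80 and
    110-130 Hz; network-state MSD uses 20-ms bins and lags 1..50 (1 s ahead);
    LZC uses 10-ms bins.
    """

    welch_window_s: float = 4.0
    welch_overlap: float = 0.0          # fraction of window
    freq_resolution_hz: float = 0.25
    hfo_band: tuple[float, float] = (80.0, 110.0)
    hfo_flanks: tuple[tuple[float, float], ...] = ((60.0, 80.0), (110.0, 130.0))
    msd_bin_s: float = 0.020
    msd_n_range: tuple[int, int] = (1, 50)
    lzc_bin_s: float = 0.010
    rate_window_s: float = 60.0
    rate_change_bin_s: float = 10.0
    rate_change_alpha: float = 0.05
    timecourse_window_s: float = 60.0
    peak_smooth_hz: float = 1.0         # Gaussian smoothing of the HFO difference curve
    rng_seed: int = 0
    block_length_s: float = 900.0

    def __post_init__(self) -> None:
        for name in ("welch_window_s", "freq_resolution_hz", "msd_bin_s",
                     "lzc_bin_s", "rate_window_s", "rate_change_bin_s",
                     "timecourse_window_s", "block_length_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        f1, f2 = self.hfo_band
        if not 0 < f1 < f2:
            raise ValidationError("hfo_band must be an increasing positive pair")
        for lo, hi in self.hfo_flanks:
            if not lo < hi:
                raise ValidationError("flank bands must be increasing")
            if lo < f2 and hi > f1:
                raise ValidationError("flank bands must be disjoint from hfo_band")
        n0, n1 = self.msd_n_range
        if not 1 <= n0 <= n1:
            raise ValidationError("msd_n_range must satisfy 1 <= n0 <= n1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_lfp(path: str | Path, lfp: LfpRecording, uv_per_bit: float | None = None) -> None:
    """Write an LFP recording as int16 + scale factor."""
    peak = float(np.abs(lfp.data).max()) if lfp.data.size else 1.0
    if uv_per_bit is None:
        uv_per_bit = max(peak / 32000.0, 1e-12)
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "lfp", data=np.round(lfp.data / uv_per_bit).astype(np.int16)
        )
        d.attrs["fs"] = float(lfp.fs)
        d.attrs["uv_per_bit"] = float(uv_per_bit)
        ch = lfp.channels
        f.create_dataset("channels/index", data=np.asarray(ch["index"], dtype=np.int64))
        f.create_dataset("channels/depth_um", data=np.asarray(ch["depth_um"], dtype=np.float64))
        f.create_dataset(
            "channels/region",
            data=np.asarray([r.encode() for r in ch["region"]]),
        )


def read_lfp(path: str | Path) -> LfpRecording:
    """Read a validated LFP recording; int16 data are scaled by the stored µV/bit."""
    with h5py.File(path, "r") as f:
        if "lfp" not in f:
            raise FormatError(f"{path}: missing dataset 'lfp'")
        d = f["lfp"]
        if "fs" not in d.attrs:
            raise FormatError(f"{path}: /lfp missing required attribute 'fs'")
        fs = float(d.attrs["fs"])
        raw = d[()]
        if np.issubdtype(raw.dtype, np.integer):
            if "uv_per_bit" not in d.attrs:
                raise FormatError(f"{path}: integer LFP missing 'uv_per_bit' attribute")
            data = raw.astype(np.float64) * float(d.attrs["uv_per_bit"])
        else:
            data = raw.astype(np.float64)
        if "channels" not in f:
            raise FormatError(f"{path}: missing '/channels' table")
        ch = pd.DataFrame({
            "index": f["channels/index"][()],
            "depth_um": f["channels/depth_um"][()],
            "region": [r.decode() for r in f["channels/region"][()]],
        })
    return LfpRecording(data=data, fs=fs, channels=ch)


def write_spikes(directory: str | Path, units: UnitSet) -> None:
    """Write spikes.csv + units.csv (+ waveforms.csv when waveforms exist)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [
        pd.DataFrame({"unit_id": u.unit_id, "spike_time_s": u.spike_times})
        for u in units if u.n_spikes
    ]
    spikes = (pd.concat(rows, ignore_index=True) if rows
              else pd.DataFrame(columns=["unit_id", "spike_time_s"]))
    spikes.to_csv(directory / "spikes.csv", index=False)
    meta = pd.DataFrame([
        {"unit_id": u.unit_id, "region": u.region, "depth_um": u.depth_um,
         "cell_class": u.cell_class, "waveform_fs": u.waveform_fs}
        for u in units
    ])
    meta.to_csv(directory / "units.csv", index=False)
    wf_units = [u for u in units if u.waveform is not None]
    if wf_units:
        n = max(len(u.waveform) for u in wf_units)
        wf = pd.DataFrame(
            [np.pad(u.waveform, (0, n - len(u.waveform)), constant_values=np.nan)
             for u in wf_units],
        )
        wf.insert(0, "unit_id", [u.unit_id for u in wf_units])
        wf.to_csv(directory / "waveforms.csv", index=False)


def read_spikes(directory: str | Path) -> UnitSet:
    """Read the spikes/units CSV pair; spike times are grouped per unit and sorted.

    A metadata row with no spikes is retained as an empty unit (with a logged
    warning); a spike row whose unit_id has no metadata is an error.
    """
    directory = Path(directory)
    spikes = pd.read_csv(directory / "spikes.csv")
    meta = pd.read_csv(directory / "units.csv", dtype={"unit_id": str})
    for col in ("unit_id", "spike_time_s"):
        if col not in spikes.columns:
            raise FormatError(f"spikes.csv missing column {col!r}")
    spikes["unit_id"] = spikes["unit_id"].astype(str)
    if len(spikes) and (spikes["spike_time_s"] < 0).any():
        raise ValidationError("negative spike times in spikes.csv")
    known = set(meta["unit_id"])
    orphans = set(spikes["unit_id"]) - known
    if orphans:
        raise ValidationError(f"spike rows reference unknown unit ids: {sorted(orphans)[:5]}")
    waveforms: dict[str, tuple[np.ndarray, float]] = {}
    wf_path = directory / "waveforms.csv"
    if wf_path.exists():
        wf = pd.read_csv(wf_path, dtype={"unit_id": str})
        for _, row in wf.iterrows():
            v = row.drop("unit_id").to_numpy(float)
            waveforms[row["unit_id"]] = v[~np.isnan(v)]
    grouped = {uid: g["spike_time_s"].to_numpy() for uid, g in spikes.groupby("unit_id")}
    units = []
    for _, m in meta.iterrows():
        uid = m["unit_id"]
        st = np.sort(grouped.get(uid, np.empty(0)))
        if uid not in grouped:
            logger.warning("unit %s has metadata but no spikes; kept empty", uid)
        units.append(Unit(
            unit_id=uid, spike_times=st, region=m["region"],
            depth_um=float(m["depth_um"]),
            waveform=waveforms.get(uid),
            waveform_fs=float(m.get("waveform_fs", 30000.0)),
            cell_class=m.get("cell_class", "unclassified"),
        ))
    return UnitSet(units)


def write_schedule(path: str | Path, schedule: BlockSchedule) -> None:
    doc = {
        "subject_id": schedule.subject_id,
        "drug": schedule.drug,
        "injection_time": float(schedule.injection_time),
        "day": int(schedule.day),
        "blocks": [
            {"kind": b.kind, "phase": b.phase,
             "t_start": float(b.t_start), "t_end": float(b.t_end)}
            for b in schedule.blocks
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schedule(path: str | Path) -> BlockSchedule:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        blocks = tuple(
            Block(kind=b["kind"], phase=b["phase"],
                  t_start=float(b["t_start"]), t_end=float(b["t_end"]))
            for b in doc["blocks"]
        )
        return BlockSchedule(
            subject_id=str(doc["subject_id"]), drug=doc["drug"],
            injection_time=float(doc["injection_time"]), day=int(doc["day"]),
            blocks=blocks,
        )
    except KeyError as e:
        raise FormatError(f"{path}: missing schedule field {e}") from e
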