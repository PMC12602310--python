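"""Unit quality control, putative cell-type classification and firing-rate change analysis.

QC follows the standard sorted-unit triple: a Hill-style inter-spike-interval
(ISI) violation ratio (refractory contamination relative to a Poisson process
at the unit's rate), an amplitude-cutoff estimate of the missed-spike
fraction (symmetric-tail argument on the amplitude histogram), and a presence
ratio (fraction of equal-length epochs containing at least one spike).  Units
are retained only when ISI violations < 0.5, amplitude cutoff < 0.1 and
presence ratio > 0.9.

Putative cell types: narrow-spiking interneurons (NS) have trough-to-peak
waveform width < 425 µs; among broad units, wide-slow cells (WS) show a slow
autocorrelogram rise (tau_rise > 6 ms, from a least-squares fit of
``a*(1 - exp(-(t - t0)/tau_rise))*exp(-t/tau_decay) + c``); the remainder are
regular-spiking (RS, putative pyramidal) cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import stats as sp_stats
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .io_core import (AnalysisConfig, Block, BlockSchedule, Unit, UnitQcMetrics,
                      UnitSet, ValidationError, logger)

__all__ = [
    "QcThresholds", "CellClassParams", "RateTimecourse", "RateChangeClass",
    "qc_metrics", "filter_units", "classify_cell", "classify_units",
    "rate_timecourse", "classify_rate_change", "change_proportions",
]


@dataclass(frozen=True)
class QcThresholds:
    """Strict-inequality retention thresholds for sorted units."""

    max_isi_violations: float = 0.5
    max_amplitude_cutoff: float = 0.1
    min_presence_ratio: float = 0.9


@dataclass(frozen=True)
class CellClassParams:
    """Waveform / autocorrelogram classification parameters."""

    narrow_width_us: float = 425.0
    wide_tau_rise_ms: float = 6.0
    acg_bin_ms: float = 0.5
    acg_window_ms: float = 50.0
    min_spikes_for_acg: int = 100

    def __post_init__(self) -> None:
        if self.narrow_width_us <= 0 or self.wide_tau_rise_ms <= 0:
            raise ValidationError("classification thresholds must be positive")


@dataclass
class RateTimecourse:
    """Windowed firing rates per unit, expressed relative to the pre-injection baseline."""

    times: np.ndarray          # window centres, s relative to injection
    rates: np.ndarray          # (n_units, n_windows), Hz
    baseline_mean: np.ndarray  # per-unit Hz over the pre-injection period
    delta: np.ndarray          # rates - baseline_mean[:, None]
    unit_ids: list[str]
    window_kind: list[str]     # block kind annotation per window ('' when outside blocks)


@dataclass
class RateChangeClass:
    """Per-unit post-vs-pre firing-rate change label with the twofold gate."""

    label: str                 # decrease | no_change | increase
    fold_change: float         # post_rate / pre_rate
    p_value: float
    flags: list[str]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_metrics(unit: Unit, recording_span: float,
               isi_threshold_s: float = 0.0015,
               n_epochs: int = 100,
               n_amp_bins: int = 500) -> UnitQcMetrics:
    """Compute the QC triple for one unit.

    * ``isi_violations``: Hill-style ratio — the rate of ISIs below the
      refractory threshold (1.5 ms, censored at 0) divided by the rate
      expected for a Poisson process firing at the unit's overall rate.
    * ``presence_ratio``: fraction of ``n_epochs`` equal subdivisions of the
      recording span containing at least one spike.
    * ``amplitude_cutoff``: estimated missed-spike fraction from the
      amplitude histogram under a symmetric (truncated-Gaussian) assumption;
      0 when no per-spike amplitudes are available.
    """
    if recording_span <= 0:
        raise ValidationError("recording span must be positive")
    t = unit.spike_times
    n = len(t)
    if n < 2:
        return UnitQcMetrics(isi_violations=0.0, amplitude_cutoff=0.0,
                             presence_ratio=float(n > 0) / n_epochs if n else 0.0)
    isis = np.diff(t)
    n_viol = int(np.sum(isis < isi_threshold_s))
    # expected violations for a Poisson process at the same mean rate:
    # each spike exposes a 2*threshold window at rate n/span
    violation_time = 2.0 * n * isi_threshold_s
    total_rate = n / recording_span
    violation_rate = n_viol / violation_time
    isi_ratio = violation_rate / total_rate

    edges = np.linspace(0.0, recording_span, n_epochs + 1)
    counts, _ = np.histogram(t, bins=edges)
    presence = float(np.mean(counts > 0))

    if unit.amplitudes is None or len(unit.amplitudes) < 10:
        amp_cut = 0.0
    else:
        amp_cut = _amplitude_cutoff(unit.amplitudes, n_amp_bins)
    return UnitQcMetrics(isi_violations=float(isi_ratio),
                         amplitude_cutoff=amp_cut,
                         presence_ratio=presence)


def _amplitude_cutoff(amplitudes: np.ndarray, n_bins: int = 500) -> float:
    """Missed-spike fraction from the low-amplitude truncation of the histogram.

    The amplitude distribution of a fully captured unit is roughly symmetric;
    detection thresholds clip its low tail.  The histogram is smoothed, the
    mode located, and the mass above the point on the high side whose density
    matches the low edge's density estimates the clipped fraction (capped at
    0.5 — beyond that the mode itself is unreliable).
    """
    h, edges = np.histogram(amplitudes, bins=n_bins, density=True)
    pdf = gaussian_filter1d(h.astype(float), sigma=3.0, mode="reflect")
    peak = int(np.argmax(pdf))
    if peak == len(pdf) - 1:
        return 0.5
    above = pdf[peak:]
    g = peak + int(np.argmin(np.abs(above - pdf[0])))
    width = edges[1] - edges[0]
    tail = float(pdf[g:].sum() * width)  # mirrored mass, relative to observed spikes
    # convert to a fraction of the full (observed + missed) distribution:
    # missed/observed = tail  =>  missed/(observed + missed) = tail/(1 + tail)
    return min(tail / (1.0 + tail), 0.5)


def filter_units(units: UnitSet, thresholds: QcThresholds | None = None,
                 recording_span: float | None = None) -> UnitSet:
    """Retain units passing all three QC criteria (strict inequalities).

    QC metrics are computed on demand when a unit does not carry them yet
    (``recording_span`` is then required).  Idempotent by construction.
    """
    thresholds = thresholds or QcThresholds()
    kept = []
    for u in units:
        qc = u.qc
        if qc is None:
            if recording_span is None:
                raise ValidationError(
                    f"unit {u.unit_id} has no QC metrics and no recording_span given"
                )
            qc = qc_metrics(u, recording_span)
            u = replace(u, qc=qc)
        if (qc.isi_violations < thresholds.max_isi_violations
                and qc.amplitude_cutoff < thresholds.max_amplitude_cutoff
                and qc.presence_ratio > thresholds.min_presence_ratio):
            kept.append(u)
    logger.info("QC retained %d / %d units", len(kept), len(units))
    return UnitSet(kept)


# ---------------------------------------------------------------------------
# cell-type classification
# ---------------------------------------------------------------------------

def waveform_width_us(waveform: np.ndarray, waveform_fs: float,
                      upsample: int = 10) -> float:
    """Trough-to-peak width in µs, with cubic interpolation for sub-sample resolution.

    The spike trough is the global minimum; the peak is the subsequent
    maximum.  Scale-invariant by construction.
    """
    w = np.asarray(waveform, dtype=float)
    if len(w) < 4 or np.ptp(w) == 0:
        raise ValidationError("waveform is flat or too short")
    x = np.arange(len(w))
    xs = np.linspace(0, len(w) - 1, (len(w) - 1) * upsample + 1)
    ws = CubicSpline(x, w)(xs)
    trough = int(np.argmin(ws))
    if trough >= len(ws) - 2:
        raise ValidationError("waveform trough at edge; cannot measure width")
    peak = trough + int(np.argmax(ws[trough:]))
    dt_us = (xs[peak] - xs[trough]) / waveform_fs * 1e6
    return float(dt_us)


def autocorrelogram(spike_times: np.ndarray, bin_ms: float = 0.5,
                    window_ms: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided spike-train autocorrelogram (counts per bin, lags > 0)."""
    t = np.asarray(spike_times, dtype=float)
    window_s = window_ms / 1000.0
    bin_s = bin_ms / 1000.0
    n_bins = int(round(window_ms / bin_ms))
    counts = np.zeros(n_bins)
    # accumulate forward lags only; the ACG is symmetric
    j0 = 0
    for i in range(len(t)):
        j = i + 1
        while j < len(t) and t[j] - t[i] < window_s:
            k = int((t[j] - t[i]) / bin_s)
            counts[k] += 1
            j += 1
    lags_ms = (np.arange(n_bins) + 0.5) * bin_ms
    return lags_ms, counts


def fit_acg_tau_rise(lags_ms: np.ndarray, counts: np.ndarray) -> float:
    """Least-squares fit of ``a*(1 - exp(-(t - t0)/tau_rise))*exp(-t/tau_decay) + c``.

    Returns tau_rise in ms; 0 when the fit fails or the ACG is empty (a flat
    Poisson-like ACG has no rise).
    """
    y = gaussian_filter1d(counts.astype(float), sigma=2.0)
    plateau = float(np.mean(y[lags_ms > lags_ms.max() / 2.0]))
    if plateau <= 0:
        return 0.0
    y = y / plateau

    def model(t, a, tau_rise, tau_decay, t0, c):
        rise = 1.0 - np.exp(-np.clip(t - t0, 0.0, None) / tau_rise)
        return a * rise * np.exp(-t / tau_decay) + c

    # tau_decay bounded away from the rise timescale and t0/c kept small:
    # the five-parameter form is otherwise degenerate on a noisy short-lag ACG
    bounds = ([0.0, 0.05, 200.0, 0.0, 0.0], [10.0, 50.0, 1e4, 2.0, 0.5])
    best: tuple[float, np.ndarray] | None = None
    for tr0 in (1.0, 4.0, 15.0):  # multi-start against local minima
        try:
            popt, _ = sp_optimize.curve_fit(
                model, lags_ms, y, p0=(1.0, tr0, 1e3, 0.5, 0.0),
                bounds=bounds, maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((model(lags_ms, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    return 0.0 if best is None else float(best[1][1])


def classify_cell(waveform: np.ndarray | None, spike_times: np.ndarray,
                  waveform_fs: float = 30000.0,
                  params: CellClassParams | None = None) -> str:
    """Assign NS / WS / RS from waveform width and ACG tau-rise.

    Width below the narrow threshold -> NS.  Broad units with fewer than
    ``min_spikes_for_acg`` spikes are unclassifiable; otherwise a slow ACG
    rise marks WS, the rest RS.
    """
    params = params or CellClassParams()
    if waveform is None:
        return "unclassified"
    try:
        width = waveform_width_us(waveform, waveform_fs)
    except ValidationError:
        logger.warning("flat or degenerate waveform; unit left unclassified")
        return "unclassified"
    if width < params.narrow_width_us:
        return "NS"
    if len(spike_times) < params.min_spikes_for_acg:
        return "unclassified"
    lags, counts = autocorrelogram(spike_times, params.acg_bin_ms,
                                   params.acg_window_ms)
    tau_rise = fit_acg_tau_rise(lags, counts)
    return "WS" if tau_rise > params.wide_tau_rise_ms else "RS"


def classify_units(units: UnitSet, params: CellClassParams | None = None) -> UnitSet:
    """Classify every unit, returning a new UnitSet with cell_class filled in."""
    out = []
    for u in units:
        cls = classify_cell(u.waveform, u.spike_times, u.waveform_fs, params)
        out.append(replace(u, cell_class=cls))
    return UnitSet(out)


# ---------------------------------------------------------------------------
# firing-rate analyses
# ---------------------------------------------------------------------------

def _block_of(t: float, schedule: BlockSchedule) -> str:
    for b in schedule.blocks:
        if b.t_start <= t < b.t_end:
            return b.kind
    return ""


def rate_timecourse(units: UnitSet, schedule: BlockSchedule,
                    window_s: float = 60.0) -> RateTimecourse:
    """Windowed firing rates with the pre-injection baseline subtracted.

    The window grid spans the schedule from the first block start; a partial
    trailing window is dropped.  ``baseline_mean`` is each unit's mean rate
    over all pre-phase blocks (rest and task pooled).
    """
    pre_blocks = schedule.select(phase="pre")
    if not pre_blocks:
        raise ValidationError("schedule has no pre-injection baseline blocks")
    t0 = schedule.blocks[0].t_start
    t1 = schedule.t_end
    n_win = int(np.floor((t1 - t0) / window_s + 1e-9))
    if n_win < 1:
        raise ValidationError("schedule shorter than one rate window")
    edges = t0 + np.arange(n_win + 1) * window_s
    rates = np.empty((len(units), n_win))
    for i, u in enumerate(units):
        counts, _ = np.histogram(u.spike_times, bins=edges)
        rates[i] = counts / window_s
    base_dur = sum(b.duration for b in pre_blocks)
    baseline = np.array([
        sum(len(u.spikes_in(b.t_start, b.t_end)) for b in pre_blocks) / base_dur
        for u in units
    ])
    centres = (edges[:-1] + edges[1:]) / 2.0
    kinds = [_block_of(c, schedule) for c in centres]
    return RateTimecourse(
        times=centres - schedule.injection_time,
        rates=rates, baseline_mean=baseline,
        delta=rates - baseline[:, None],
        unit_ids=units.unit_ids, window_kind=kinds,
    )


def classify_rate_change(unit: Unit, pre_blocks, post_blocks,
                         alpha: float = 0.05, bin_s: float = 10.0,
                         min_bins: int = 5, eps_rate: float = 1e-3) -> RateChangeClass:
    """Label a unit's post-vs-pre rate change with a significance + twofold gate.

    Spike counts in consecutive ``bin_s`` bins of each phase are compared with
    a two-sided Wilcoxon rank-sum test; the unit is an *increase* only when
    p < alpha and the fold change (post rate / pre rate) is >= 2, a *decrease*
    only when p < alpha and fold <= 0.5, otherwise *no_change*.
    """
    def phase_counts(blocks):
        counts = []
        for b in blocks:
            n_bins = int(np.floor(b.duration / bin_s + 1e-9))
            edges = b.t_start + np.arange(n_bins + 1) * bin_s
            c, _ = np.histogram(unit.spikes_in(b.t_start, b.t_end), bins=edges)
            counts.append(c)
        return np.concatenate(counts) if counts else np.empty(0)

    pre_c = phase_counts(pre_blocks)
    post_c = phase_counts(post_blocks)
    if len(pre_c) < min_bins or len(post_c) < min_bins:
        raise ValidationError(
            f"need >= {min_bins} analysis bins per phase "
            f"(got {len(pre_c)} pre, {len(post_c)} post)"
        )
    flags = []
    pre_rate = pre_c.mean() / bin_s
    post_rate = post_c.mean() / bin_s
    if pre_rate == 0:
        flags.append("zero baseline rate; fold change regularised")
    fold = (post_rate + eps_rate) / (pre_rate + eps_rate) if pre_rate == 0 \
        else post_rate / pre_rate
    if np.all(pre_c == pre_c[0]) and np.all(post_c == post_c[0]) \
            and pre_c[0] == post_c[0]:
        p = 1.0
    else:
        _, p = sp_stats.ranksums(pre_c, post_c)
    if p < alpha and fold >= 2.0:
        label = "increase"
    elif p < alpha and fold <= 0.5:
        label = "decrease"
    else:
        label = "no_change"
    return RateChangeClass(label=label, fold_change=float(fold),
                           p_value=float(p), flags=flags)


def change_proportions(change_classes: dict[str, RateChangeClass],
                       units: UnitSet,
                       group_by: tuple[str, ...] = ("region", "cell_class")) -> pd.DataFrame:
    """Counts and proportions of decrease / no_change / increase per stratum.

    Returns a tidy frame with one row per stratum x label; degenerate strata
    (all units in one label) are flagged in the ``degenerate`` column, empty
    strata are simply absent.
    """
    rows = []
    for u in units:
        if u.unit_id not in change_classes:
            continue
        rows.append({
            "region": u.region, "cell_class": u.cell_class,
            "label": change_classes[u.unit_id].label,
        })
    if not rows:
        raise ValidationError("no classified units to tabulate")
    df = pd.DataFrame(rows)
    out = []
    for key, g in df.groupby(list(group_by)):
        key = key if isinstance(key, tuple) else (key,)
        counts = g["label"].value_counts()
        total = len(g)
        degenerate = len(counts) == 1
        if degenerate:
            logger.info("stratum %s has a single change label (%s)",
                        key, counts.index[0])
        for label in ("decrease", "no_change", "increase"):
            out.append({
                **dict(zip(group_by, key)),
                "label": label,
                "count": int(counts.get(label, 0)),
                "proportion": counts.get(label, 0) / total,
                "n_units": total,
                "degenerate": degenerate,
            })
    return pd.DataFrame(out)
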