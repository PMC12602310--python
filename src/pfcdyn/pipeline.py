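"""Session-level orchestration of the full analysis.

``run_day0`` walks one session triple (LFP, units, schedule) through channel
selection, HFO unmasking and its time course, pre/post spectral and coherence
contrasts, unit QC + classification, firing-rate analyses, and the
network-state MSD / LZC contrasts, separately for rest and task blocks (the
two behavioural states are never pooled).  ``run_longitudinal`` compares
post-injection days 1/2/6 against the shared day-0 baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import lfp_spectral, network_state, stats as pstats, units as punits
from .io_core import (AnalysisConfig, Block, BlockSchedule, LfpRecording,
                      UnitSet, ValidationError, logger)

__all__ = ["SessionResult", "run_day0", "run_longitudinal"]


@dataclass
class SessionResult:
    """All per-session outputs, keyed so each row traces to (subject, drug, day, block)."""

    subject_id: str
    drug: str
    day: int
    region_channels: dict = field(default_factory=dict)
    hfo_profile: object | None = None
    hfo_timecourse: pd.DataFrame | None = None
    spectra: dict = field(default_factory=dict)          # (kind, phase) -> PowerSpectrum
    coherence: dict = field(default_factory=dict)        # (pair, kind, phase) -> CoherenceSpectrum
    unit_table: pd.DataFrame | None = None
    change_classes: dict = field(default_factory=dict)   # unit_id -> RateChangeClass
    change_proportions: pd.DataFrame | None = None
    rate_timecourse: object | None = None
    msd: dict = field(default_factory=dict)              # kind -> contrast dict
    lzc: dict = field(default_factory=dict)              # kind -> contrast dict
    flags: list = field(default_factory=list)

    def msd_frame(self) -> pd.DataFrame:
        rows = []
        for kind, c in self.msd.items():
            for phase, vals in (("pre", c["pre_z"]), ("post", c["post_z"])):
                for t, v in enumerate(vals):
                    rows.append({"subject": self.subject_id, "drug": self.drug,
                                 "kind": kind, "phase": phase, "t": t, "msd_z": v})
        return pd.DataFrame(rows)


def _phase_spectra(lfp: LfpRecording, schedule: BlockSchedule, kind: str,
                   phase: str, cfg: AnalysisConfig):
    blocks = schedule.select(kind=kind, phase=phase)
    if not blocks:
        return None
    return lfp_spectral.average_power(
        [lfp_spectral.welch_psd(lfp, b, cfg) for b in blocks])


def run_day0(lfp: LfpRecording, units: UnitSet, schedule: BlockSchedule,
             cfg: AnalysisConfig | None = None,
             rng: np.random.Generator | None = None) -> SessionResult:
    """Full day-0 analysis of one session, deterministic given the RNG."""
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(rng if rng is not None else cfg.rng_seed)
    res = SessionResult(subject_id=schedule.subject_id, drug=schedule.drug,
                        day=schedule.day)

    # --- spectra per (kind, phase), averaged over each phase's blocks
    for kind in ("rest", "task"):
        for phase in ("pre", "post"):
            ps = _phase_spectra(lfp, schedule, kind, phase, cfg)
            if ps is not None:
                res.spectra[(kind, phase)] = ps

    # --- HFO topography on post-injection rest spectra
    post_rest = res.spectra.get(("rest", "post"))
    if post_rest is not None:
        res.hfo_profile = lfp_spectral.hfo_power_difference(post_rest, cfg)

    # --- per-region channel selection (IL missing -> flagged, not fatal)
    try:
        res.region_channels = lfp_spectral.select_region_channels(
            post_rest if post_rest is not None else res.spectra[("rest", "pre")], cfg)
    except ValidationError as e:
        res.flags.append(str(e))
        logger.warning("channel selection incomplete: %s", e)

    # --- HFO time course on the IL channel (or the overall peak channel)
    if res.hfo_profile is not None:
        ch = res.region_channels.get("IL", res.hfo_profile.peak_channel)
        res.hfo_timecourse = lfp_spectral.band_power_timecourse(
            lfp, ch, cfg, injection_time=schedule.injection_time)

    # --- inter-regional coherence per (pair, kind, phase)
    if {"IL", "PL", "CG"} <= set(res.region_channels):
        pairs = (("IL", "PL"), ("IL", "CG"), ("PL", "CG"))
        for ra, rb in pairs:
            for kind in ("rest", "task"):
                for phase in ("pre", "post"):
                    blocks = schedule.select(kind=kind, phase=phase)
                    if not blocks:
                        continue
                    cohs = [lfp_spectral.coherence_spectrum(
                        lfp, res.region_channels[ra], res.region_channels[rb],
                        b, cfg) for b in blocks]
                    mean_coh = np.mean([c.coherence for c in cohs], axis=0)
                    res.coherence[(f"{ra}-{rb}", kind, phase)] = \
                        lfp_spectral.CoherenceSpectrum(
                            freqs=cohs[0].freqs, coherence=mean_coh,
                            meta={"pair": f"{ra}-{rb}", "kind": kind, "phase": phase})

    # --- unit QC and classification
    span = schedule.t_end
    qc_units = punits.filter_units(units, recording_span=span)
    needs_class = any(u.cell_class == "unclassified" for u in qc_units)
    if needs_class:
        qc_units = punits.classify_units(qc_units)

    # --- firing-rate time course and per-unit change classification (rest blocks)
    res.rate_timecourse = punits.rate_timecourse(qc_units, schedule,
                                                 cfg.rate_window_s)
    pre_rest = schedule.select(kind="rest", phase="pre")
    post_rest_blocks = schedule.select(kind="rest", phase="post")
    for u in qc_units:
        try:
            res.change_classes[u.unit_id] = punits.classify_rate_change(
                u, pre_rest, post_rest_blocks,
                alpha=cfg.rate_change_alpha, bin_s=cfg.rate_change_bin_s)
        except ValidationError as e:
            res.flags.append(f"{u.unit_id}: {e}")
    if res.change_classes:
        res.change_proportions = punits.change_proportions(
            res.change_classes, qc_units)
    meta = qc_units.metadata_frame()
    meta["change_label"] = [
        res.change_classes[u].label if u in res.change_classes else ""
        for u in meta["unit_id"]
    ]
    meta["fold_change"] = [
        res.change_classes[u].fold_change if u in res.change_classes else np.nan
        for u in meta["unit_id"]
    ]
    res.unit_table = meta

    # --- network-state MSD and unit-wise LZC contrasts, per block kind
    for kind in ("rest", "task"):
        pre_blocks = schedule.select(kind=kind, phase="pre")
        post_blocks = schedule.select(kind=kind, phase="post")
        if not pre_blocks or not post_blocks:
            continue
        pre_msd = [network_state.msd(network_state.binarize(qc_units, b, cfg.msd_bin_s),
                                     cfg.msd_n_range) for b in pre_blocks]
        post_msd = [network_state.msd(network_state.binarize(qc_units, b, cfg.msd_bin_s),
                                      cfg.msd_n_range) for b in post_blocks[:2]]
        res.msd[kind] = network_state.msd_contrast(pre_msd, post_msd)
        pre_lzc = [network_state.lzc_block(qc_units, b, cfg.lzc_bin_s)
                   for b in pre_blocks]
        post_lzc = [network_state.lzc_block(qc_units, b, cfg.lzc_bin_s)
                    for b in post_blocks[:2]]
        res.lzc[kind] = network_state.lzc_contrast(pre_lzc, post_lzc, rng=rng)
    return res


def run_longitudinal(sessions: dict[int, tuple[LfpRecording, BlockSchedule]],
                     region_channels: dict[str, int],
                     cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-day power and coherence change versus the shared day-0 baseline.

    ``sessions`` maps day -> (lfp, schedule); day 0 must be present and its
    pre-phase blocks define the baseline.  Returns a tidy frame with one row
    per (day, kind, channel-or-pair, frequency) holding the log10 power ratio
    to baseline and the coherence difference.  Missing days yield a partial
    result with a log message.
    """
    cfg = cfg or AnalysisConfig()
    if 0 not in sessions:
        raise ValidationError("longitudinal contrast requires a day-0 session")
    lfp0, sched0 = sessions[0]
    rows = []
    il, pl = region_channels["IL"], region_channels["PL"]

    def phase_power(lfp, sched, kind, phase, ch):
        blocks = sched.select(kind=kind, phase=phase)
        if not blocks:
            return None, None
        ps = lfp_spectral.average_power(
            [lfp_spectral.welch_psd(lfp, b, cfg, channels=np.array([ch]))
             for b in blocks])
        return ps.freqs, ps.power[:, 0]

    def phase_coherence(lfp, sched, kind, phase):
        blocks = sched.select(kind=kind, phase=phase)
        if not blocks:
            return None, None
        cohs = [lfp_spectral.coherence_spectrum(lfp, il, pl, b, cfg)
                for b in blocks]
        return cohs[0].freqs, np.mean([c.coherence for c in cohs], axis=0)

    for kind in ("rest", "task"):
        f_base, p_base = phase_power(lfp0, sched0, kind, "pre", il)
        _, c_base = phase_coherence(lfp0, sched0, kind, "pre")
        if p_base is None:
            continue
        for day in (0, 1, 2, 6):
            if day not in sessions:
                logger.info("day %d missing; longitudinal result is partial", day)
                continue
            lfp_d, sched_d = sessions[day]
            _, p_day = phase_power(lfp_d, sched_d, kind, "post", il)
            _, c_day = phase_coherence(lfp_d, sched_d, kind, "post")
            if p_day is None:
                continue
            log_ratio = np.log10(p_day / p_base)
            coh_diff = (c_day - c_base) if c_day is not None else np.full_like(p_day, np.nan)
            for fi, f in enumerate(f_base):
                rows.append({"day": day, "kind": kind, "freq_hz": f,
                             "log10_power_ratio": log_ratio[fi],
                             "coherence_diff": coh_diff[fi]})
    return pd.DataFrame(rows)
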