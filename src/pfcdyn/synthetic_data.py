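"""Synthetic sessions with the statistical structure the analysis assumes.

The generator emulates one recording session of the block design: a
pre-injection baseline rest + task block, an injection, then three rest and
two task blocks (15 min each in the study; 60 s by default here so a full
synthetic experiment runs in seconds, with every analysis parameter
unchanged).

* **LFP** — per channel, coloured noise with PSD proportional to ``1/f^beta``
  (synthesised in the frequency domain with random phases for exact spectral
  control) plus optional stationary band components.  Post-injection, drug
  sessions gain an additive narrowband component (Gaussian spectral bump)
  whose amplitude peaks in IL and decays toward CG, at ~100 Hz for the low
  dose and ~93 Hz for the high dose.
* **Spikes** — per unit, an inhomogeneous Poisson train with a 2-ms absolute
  refractory period.  Baseline rates are log-normal; task blocks scale rates
  by ``task_rate_factor``; post-injection, each unit draws a persistent drug
  response (decrease / no change / increase) with dose-dependent proportions,
  applied fully in rest blocks and attenuated in task blocks.
* **Entropy drop** — post-drug spike trains are additionally modulated by a
  slow common telegraph process (mean-preserving rate gating shared across
  units).  Slow shared modulation makes binarized states stickier, lowering
  both network-state MSD and unit-wise LZC, which is the phenomenology the
  downstream contrasts must recover; it is a generative stand-in, not a
  biophysical mechanism.

All outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_core
from .io_core import (Block, BlockSchedule, LfpRecording, Unit, UnitSet,
                      ValidationError, normalized_depths)

__all__ = [
    "DrugEffect", "HfoParams", "SimParams", "default_channel_map",
    "default_day0_schedule", "default_followup_schedule",
    "simulate_lfp", "simulate_spikes", "make_experiment",
]


@dataclass(frozen=True)
class DrugEffect:
    """Mixture of persistent per-unit rate responses for one dose."""

    frac_decrease: float = 0.0
    frac_increase: float = 0.0
    decrease_factor: float = 1.0
    increase_factor: float = 1.0
    #: fraction of the (log) rest-block effect retained in task blocks;
    #: < 1 emulates effects that are more prominent at rest
    task_attenuation: float = 0.5
    #: depth of the slow common rate modulation applied post-drug (0..1);
    #: larger values lower MSD / LZC more
    entropy_drop: float = 0.0

    @property
    def frac_nochange(self) -> float:
        return 1.0 - self.frac_decrease - self.frac_increase

    def __post_init__(self) -> None:
        for f in (self.frac_decrease, self.frac_increase):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("response fractions must lie in [0, 1]")
        if self.frac_decrease + self.frac_increase > 1.0 + 1e-12:
            raise ValidationError("response fractions must sum to <= 1")
        if self.decrease_factor <= 0 or self.increase_factor <= 0:
            raise ValidationError("rate factors must be positive")
        if not 0.0 <= self.entropy_drop < 1.0:
            raise ValidationError("entropy_drop must lie in [0, 1)")


@dataclass(frozen=True)
class HfoParams:
    """Narrowband post-injection spectral bump."""

    center_hz: float = 100.0
    bandwidth_hz: float = 1.5         # Gaussian sigma of the bump, Hz
    amplitude_db: float = 6.0         # peak elevation above the 1/f background
    onset_s: float = 10.0             # ramp after injection
    #: multiplicative amplitude per region, peak in IL decaying toward CG
    depth_profile: dict = field(default_factory=lambda: {"IL": 1.0, "PL": 0.45, "CG": 0.15})


@dataclass(frozen=True)
class SimParams:
    """Generator configuration; defaults emulate the study's drug conditions."""

    n_units_per_region: dict = field(default_factory=lambda: {"IL": 25, "PL": 60, "CG": 25})
    baseline_rate_lognormal: tuple[float, float] = (np.log(2.5), 0.7)  # (mu, sigma) of log-rate, Hz
    task_rate_factor: float = 0.8
    drug_effect: dict = field(default_factory=lambda: {
        "saline": DrugEffect(),
        "psi_0.3": DrugEffect(frac_decrease=0.40, frac_increase=0.08,
                              decrease_factor=0.35, increase_factor=2.5,
                              entropy_drop=0.45),
        "psi_1.0": DrugEffect(frac_decrease=0.55, frac_increase=0.05,
                              decrease_factor=0.30, increase_factor=2.5,
                              entropy_drop=0.65),
    })
    hfo: dict = field(default_factory=lambda: {
        "saline": None,
        "psi_0.3": HfoParams(center_hz=100.0),
        "psi_1.0": HfoParams(center_hz=93.0),
    })
    lfp_beta: float = 2.0                     # 1/f^beta background exponent
    lfp_background_power: float = 1e5         # µV²/Hz at 1 Hz
    #: fraction of background power shared across channels (volume-conduction
    #: stand-in); baseline inter-channel coherence ~ common_fraction^2
    lfp_common_fraction: float = 0.5
    band_components: tuple = ()               # optional (center, sigma, power) triples
    entropy_timescale_s: float = 0.5          # telegraph switching timescale
    refractory_s: float = 0.002
    block_length_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        mu, sigma = self.baseline_rate_lognormal
        if sigma < 0:
            raise ValidationError("log-rate sigma must be non-negative")
        if self.task_rate_factor <= 0:
            raise ValidationError("task_rate_factor must be positive")
        for d, h in self.hfo.items():
            if h is not None and h.center_hz <= 0:
                raise ValidationError(f"HFO centre must be positive ({d})")


def default_channel_map(n_per_region: dict[str, int] | None = None,
                        region_extent_um: float = 1200.0) -> pd.DataFrame:
    """A probe-like channel table: IL (ventral) -> PL -> CG (dorsal)."""
    n_per_region = n_per_region or {"IL": 4, "PL": 4, "CG": 4}
    rows = []
    idx = 0
    for region in ("IL", "PL", "CG"):
        n = n_per_region[region]
        depths = (np.arange(n) + 0.5) / n * region_extent_um
        for d in depths:
            rows.append({"index": idx, "depth_um": float(d), "region": region})
            idx += 1
    ch = pd.DataFrame(rows)
    ch["normalized_depth"] = normalized_depths(
        ch, {r: region_extent_um for r in ("IL", "PL", "CG")})
    return ch


def default_day0_schedule(subject_id: str = "sim", drug: str = "psi_0.3",
                          block_length_s: float = 60.0,
                          gap_s: float = 5.0) -> BlockSchedule:
    """Baseline rest + task, injection, then rest/task/rest/task/rest."""
    plan = [("rest", "pre"), ("task", "pre"),
            ("rest", "post"), ("task", "post"), ("rest", "post"),
            ("task", "post"), ("rest", "post")]
    blocks = []
    t = 0.0
    injection = None
    for kind, phase in plan:
        if phase == "post" and injection is None:
            injection = t + gap_s / 2.0
            t += gap_s
        blocks.append(Block(kind=kind, phase=phase, t_start=t, t_end=t + block_length_s))
        t += block_length_s
    return BlockSchedule(subject_id=subject_id, drug=drug,
                         injection_time=float(injection), day=0,
                         blocks=tuple(blocks))


def default_followup_schedule(day: int, subject_id: str = "sim",
                              drug: str = "psi_0.3",
                              block_length_s: float = 60.0) -> BlockSchedule:
    """Drug-free follow-up day: 2 rest + 2 task blocks, all phase 'post'."""
    blocks = []
    t = 0.0
    for kind in ("rest", "task", "rest", "task"):
        blocks.append(Block(kind=kind, phase="post", t_start=t, t_end=t + block_length_s))
        t += block_length_s
    return BlockSchedule(subject_id=subject_id, drug=drug, injection_time=0.0,
                         day=day, blocks=tuple(blocks))


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _colored_noise_spectrum(n: int, fs: float, beta: float, power_1hz: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Frequency-domain amplitudes for 1/f^beta noise (rfft layout)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    psd = np.zeros_like(freqs)
    psd[1:] = power_1hz / freqs[1:] ** beta
    return psd


def _synthesise_from_psd(psd: np.ndarray, n: int, fs: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Gaussian time series with the given one-sided PSD (µV²/Hz)."""
    # one-sided density -> rfft coefficient variance
    scale = np.sqrt(psd * fs * n / 2.0)
    re = rng.standard_normal(len(psd))
    im = rng.standard_normal(len(psd))
    coeff = scale * (re + 1j * im) / np.sqrt(2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = scale[-1] * re[-1]
    return np.fft.irfft(coeff, n=n)


def simulate_lfp(params: SimParams, schedule: BlockSchedule,
                 channels: pd.DataFrame | None = None, fs: float = 2500.0,
                 rng: np.random.Generator | None = None) -> LfpRecording:
    """Coloured-noise LFP with a post-injection narrowband HFO on drug days.

    The HFO is narrowband Gaussian noise (spectral bump of sigma
    ``bandwidth_hz``) generated for the whole recording and gated in time:
    zero before the injection, ramping to full amplitude over ``onset_s``
    after it.  Its peak one-sided density is set so the raw-over-background
    ratio at the centre frequency equals ``amplitude_db`` on the IL channels,
    scaled per region by ``depth_profile``.
    """
    hfo = params.hfo.get(schedule.drug)
    if hfo is not None and hfo.center_hz >= fs / 2.0:
        raise ValidationError("HFO centre frequency must be below Nyquist")
    channels = channels if channels is not None else default_channel_map()
    rng = np.random.default_rng(rng if rng is not None else params.seed)
    n = int(np.ceil(schedule.t_end * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    base_psd = _colored_noise_spectrum(n, fs, params.lfp_beta,
                                       params.lfp_background_power, rng)
    for fc, sig, pw in params.band_components:
        base_psd += pw * np.exp(-0.5 * ((freqs - fc) / sig) ** 2)

    data = np.empty((n, len(channels)))
    rho = params.lfp_common_fraction
    if not 0.0 <= rho < 1.0:
        raise ValidationError("lfp_common_fraction must lie in [0, 1)")
    shared = (_synthesise_from_psd(base_psd * rho, n, fs, rng)
              if rho > 0 else 0.0)
    if hfo is not None and schedule.day == 0:
        bg_at_center = params.lfp_background_power / hfo.center_hz ** params.lfp_beta
        bump_peak = bg_at_center * (10.0 ** (hfo.amplitude_db / 10.0) - 1.0)
        bump_psd = bump_peak * np.exp(
            -0.5 * ((freqs - hfo.center_hz) / hfo.bandwidth_hz) ** 2)
        t_axis = np.arange(n) / fs
        envelope = np.clip((t_axis - schedule.injection_time) / max(hfo.onset_s, 1e-9),
                           0.0, 1.0)
    else:
        bump_psd = None

    for i, (_, ch) in enumerate(channels.iterrows()):
        x = shared + _synthesise_from_psd(base_psd * (1.0 - rho), n, fs, rng)
        if bump_psd is not None:
            gain = hfo.depth_profile.get(ch["region"], 0.0)
            if gain > 0:
                narrow = _synthesise_from_psd(bump_psd * gain, n, fs, rng)
                x = x + narrow * envelope
            else:
                rng.standard_normal(2 * len(bump_psd))  # keep stream aligned
        data[:, i] = x
    return LfpRecording(data=data, fs=fs, channels=channels.copy())


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

_NARROW_WIDTH_US = 300.0
_WIDE_WIDTH_US = 550.0


def _make_waveform(width_us: float, waveform_fs: float = 30000.0,
                   n_samples: int = 90, rng: np.random.Generator | None = None) -> np.ndarray:
    """Biphasic spike template with the requested trough-to-peak width."""
    t = (np.arange(n_samples) - n_samples // 3) / waveform_fs * 1e6  # µs
    # component widths chosen so the measured trough-to-peak time equals width_us
    trough = -np.exp(-0.5 * (t / (width_us * 0.2)) ** 2)
    peak = 0.45 * np.exp(-0.5 * ((t - width_us) / (width_us * 0.35)) ** 2)
    w = trough + peak
    if rng is not None:
        w = w + 0.01 * rng.standard_normal(n_samples)
    return 100.0 * w


def _telegraph(n_bins: int, dt: float, timescale_s: float,
               rng: np.random.Generator) -> np.ndarray:
    """+/-1 telegraph process with the given mean switching timescale."""
    p_switch = dt / timescale_s
    flips = rng.random(n_bins) < p_switch
    state = np.where(np.cumsum(flips) % 2 == 0, 1.0, -1.0)
    return state * (1.0 if rng.random() < 0.5 else -1.0)


def recovery_thin(times: np.ndarray, tau_rise_s: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sequentially thin a spike train with an exponential recovery function.

    A spike at interval ``d`` after the last accepted spike survives with
    probability ``1 - exp(-d / tau_rise_s)``, turning a Poisson train into a
    renewal-like process whose autocorrelogram rises with time constant
    ``tau_rise_s`` — the feature the WS-cell classifier fits.
    """
    if tau_rise_s <= 0 or len(times) == 0:
        return times
    u = rng.random(len(times))
    keep = np.zeros(len(times), dtype=bool)
    last = -np.inf
    for i, t in enumerate(times):
        if u[i] < 1.0 - np.exp(-(t - last) / tau_rise_s):
            keep[i] = True
            last = t
    return times[keep]


def _poisson_train(rate_fn_bins: np.ndarray, dt: float, t0: float,
                   refractory_s: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson spikes on a piecewise-constant rate grid,
    thinned by an absolute refractory period."""
    counts = rng.poisson(rate_fn_bins * dt)
    idx = np.repeat(np.arange(len(counts)), counts)
    times = t0 + (idx + rng.random(len(idx))) * dt
    times.sort()
    if refractory_s > 0 and len(times) > 1:
        keep = np.ones(len(times), dtype=bool)
        last = -np.inf
        for i, t in enumerate(times):
            if t - last < refractory_s:
                keep[i] = False
            else:
                last = t
        times = times[keep]
    return times


def simulate_spikes(params: SimParams, schedule: BlockSchedule,
                    rng: np.random.Generator | None = None) -> UnitSet:
    """Per-unit inhomogeneous Poisson spike trains with drug and task modulation.

    Cell classes are assigned (75% RS, 15% NS, 10% WS) with matching waveform
    templates; drug responses are drawn per unit from the dose's mixture and
    applied in post blocks (attenuated in task blocks); the entropy drop adds
    a mean-preserving slow common modulation to all units post-injection.
    """
    rng = np.random.default_rng(rng if rng is not None else params.seed + 1)
    effect = params.drug_effect[schedule.drug]
    mu, sigma = params.baseline_rate_lognormal
    dt = 0.005
    n_bins_total = int(np.ceil(schedule.t_end / dt))
    common = _telegraph(n_bins_total, dt, params.entropy_timescale_s, rng)

    units = []
    uid = 0
    for region, n_units in params.n_units_per_region.items():
        depths = rng.uniform(50.0, 1150.0, size=n_units)
        for k in range(n_units):
            base_rate = float(np.exp(mu + sigma * rng.standard_normal()))
            u_class = str(rng.choice(["RS", "NS", "WS"], p=[0.75, 0.15, 0.10]))
            r = rng.random()
            if r < effect.frac_decrease:
                drug_factor = effect.decrease_factor
            elif r < effect.frac_decrease + effect.frac_increase:
                drug_factor = effect.increase_factor
            else:
                drug_factor = 1.0
            spike_chunks = []
            for b in schedule.blocks:
                i0 = int(round(b.t_start / dt))
                i1 = int(round(b.t_end / dt))
                rate = np.full(i1 - i0, base_rate)
                if b.kind == "task":
                    rate *= params.task_rate_factor
                post_drug = (b.phase == "post" and schedule.day == 0
                             and schedule.drug != "saline")
                if post_drug:
                    f = drug_factor
                    depth = effect.entropy_drop
                    if b.kind == "task":
                        # drug effects are attenuated during task engagement
                        if f != 1.0:
                            f = float(np.exp(np.log(f) * effect.task_attenuation))
                        depth *= effect.task_attenuation
                    rate *= f
                    if depth > 0:
                        rate = rate * (1.0 + depth * common[i0:i1])
                spike_chunks.append(_poisson_train(rate, dt, b.t_start,
                                                   params.refractory_s, rng))
            spikes = np.concatenate(spike_chunks) if spike_chunks else np.empty(0)
            # class-specific ACG rise: WS cells recover slowly (12 ms),
            # NS/RS quickly (2 ms, well under the 6-ms WS threshold)
            tau_rise = 0.012 if u_class == "WS" else 0.002
            spikes = recovery_thin(spikes, tau_rise, rng)
            width = _NARROW_WIDTH_US if u_class == "NS" else _WIDE_WIDTH_US
            wf = _make_waveform(width, rng=rng)
            amps = 100.0 + 15.0 * rng.standard_normal(len(spikes))
            units.append(Unit(
                unit_id=f"u{uid:04d}", spike_times=spikes, region=region,
                depth_um=float(depths[k]), waveform=wf, waveform_fs=30000.0,
                amplitudes=amps, cell_class=u_class,
            ))
            uid += 1
    return UnitSet(units)


def make_experiment(params: SimParams, drug: str = "psi_0.3",
                    subject_id: str = "sim", day: int = 0,
                    out_dir: str | Path | None = None,
                    with_lfp: bool = True,
                    seed: int | None = None):
    """Compose the simulators into one session triple (LFP, units, schedule).

    With ``out_dir`` set, the triple is also written through
    :mod:`pfcdyn.io_core` (``lfp.h5``, ``spikes.csv``/``units.csv``,
    ``schedule.yaml``).
    """
    seed = params.seed if seed is None else seed
    if day == 0:
        schedule = default_day0_schedule(subject_id, drug, params.block_length_s)
    else:
        schedule = default_followup_schedule(day, subject_id, drug,
                                             params.block_length_s)
    rng = np.random.default_rng(seed)
    lfp = simulate_lfp(params, schedule, rng=rng) if with_lfp else None
    units = simulate_spikes(params, schedule, rng=rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if lfp is not None:
            io_core.write_lfp(out_dir / "lfp.h5", lfp)
        io_core.write_spikes(out_dir, units)
        io_core.write_schedule(out_dir / "schedule.yaml", schedule)
    return lfp, units, schedule
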