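"""Binarized network-state dynamics: mean-squared displacement and Lempel-Ziv complexity.

The instantaneous network state is the N-bit vector ``S_t = [s_t^1 .. s_t^N]``
where ``s_t^i`` is 1 iff unit *i* spiked at least once in the half-open time
bin ``[t, t + dt)``.  Two complementary statistics are computed on these
states:

* **MSD** — the mean-squared displacement of the state across a lag of
  ``n`` bins, ``MSD_{n,t} = <|S_{t+n*dt} - S_t|^2>_N`` (the Hamming distance
  divided by N, so bounded in [0, 1]), averaged over lags ``n = 1..50``.
  With 20-ms bins this spans the next second of network dynamics; lower
  values mean stickier, more restricted state transitions.
* **LZC** — the Lempel-Ziv (LZ76) phrase count of each unit's binarized
  train at 10-ms bins, an entropy-rate proxy; reported raw and normalised
  as ``c * log2(L) / L`` so blocks of unequal length compare fairly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .io_core import AnalysisConfig, Block, UnitSet, ValidationError

__all__ = [
    "BinaryStateMatrix", "MsdSeries", "LzcResult",
    "binarize", "msd", "msd_contrast", "lz76_phrase_count", "lzc", "lzc_contrast",
]


@dataclass
class BinaryStateMatrix:
    """Units x time-bins 0/1 matrix at a stated bin width."""

    states: np.ndarray        # (N, T), uint8 in {0, 1}
    bin_s: float
    unit_ids: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2:
            raise ValidationError("states must be 2-D (units x bins)")
        if not np.isin(self.states, (0, 1)).all():
            raise ValidationError("states must be binary")
        if not self.bin_s > 0:
            raise ValidationError("bin width must be positive")
        self.states = self.states.astype(np.uint8)

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]


@dataclass
class MsdSeries:
    """Lag-averaged MSD per time bin, with optional pre-baseline standardisation."""

    msd_t: np.ndarray
    n_range: tuple[int, int]
    bin_s: float
    pre_mean: float | None = None   # set when z-transformed against a baseline
    pre_sd: float | None = None


@dataclass
class LzcResult:
    """Per-unit LZ76 phrase counts for one block."""

    unit_ids: list[str]
    c_raw: np.ndarray        # phrase counts
    c_norm: np.ndarray       # c_raw * log2(L) / L
    L: int                   # sequence length, bins


def binarize(units: UnitSet, block: Block, bin_s: float) -> BinaryStateMatrix:
    """Binarize spike trains over a block: 1 iff >= 1 spike in the bin.

    Bins are half-open ``[t0 + k*bin_s, t0 + (k+1)*bin_s)``; a spike exactly on
    a bin edge belongs to the later bin. A trailing partial bin is dropped.
    """
    if len(units) == 0:
        raise ValidationError("cannot binarize an empty unit set")
    if not bin_s > 0:
        raise ValidationError("bin width must be positive")
    n_bins = int(np.floor((block.t_end - block.t_start) / bin_s + 1e-9))
    states = np.zeros((len(units), n_bins), dtype=np.uint8)
    for i, u in enumerate(units):
        t = u.spikes_in(block.t_start, block.t_start + n_bins * bin_s)
        k = np.floor((t - block.t_start) / bin_s).astype(np.int64)
        k = k[(k >= 0) & (k < n_bins)]
        states[i, k] = 1
    return BinaryStateMatrix(states=states, bin_s=bin_s,
                             unit_ids=units.unit_ids, t0=block.t_start)


def msd(states: BinaryStateMatrix,
        n_range: tuple[int, int] = (1, 50)) -> MsdSeries:
    """Lag-averaged mean-squared displacement of the binary network state.

    For each start bin t, ``MSD_{n,t}`` is the per-unit mean of
    ``(s_{t+n} - s_t)^2`` (identical to Hamming distance / N for binary
    states), then averaged over lags ``n`` in ``n_range``.  Only start bins
    with all lags available are kept (the tail is truncated), so the series
    has length ``n_bins - n_max``.
    """
    n0, n1 = int(n_range[0]), int(n_range[1])
    if not 1 <= n0 <= n1:
        raise ValidationError("n_range must satisfy 1 <= n0 <= n1")
    S = states.states
    N, T = S.shape
    if T <= n1:
        raise ValidationError(
            f"need more than {n1} bins for lags up to {n1}, got {T}"
        )
    n_t = T - n1
    acc = np.zeros(n_t)
    for n in range(n0, n1 + 1):
        # for binary states the squared difference is the XOR, and the
        # per-unit mean is an exact integer sum / N
        acc += (S[:, n:n + n_t] ^ S[:, :n_t]).mean(axis=0, dtype=np.float64)
    return MsdSeries(msd_t=acc / (n1 - n0 + 1), n_range=(n0, n1), bin_s=states.bin_s)


def _pool_block_pair(series: list[np.ndarray]) -> np.ndarray:
    """Pairwise-average matched blocks pointwise (truncating to the shorter),
    or pass a single block through unchanged."""
    if len(series) == 1:
        return series[0]
    m = min(len(s) for s in series)
    return np.mean([s[:m] for s in series], axis=0)


def msd_contrast(pre: list[MsdSeries] | MsdSeries,
                 post: list[MsdSeries] | MsdSeries,
                 scale_post: bool = True) -> dict:
    """Standardise pre/post MSD distributions against the pre baseline.

    The pre-drug distribution is z-scored; the post-drug distribution has the
    pre mean subtracted and (by default) is divided by the pre SD as well so
    both phases share units.  ``scale_post=False`` reproduces pure
    mean-subtraction of the post distribution.  Multiple blocks per phase are
    pairwise averaged pointwise before standardisation.

    Returns a dict with ``pre_z``, ``post_z``, ``delta`` (mean(post') -
    mean(pre')), and the baseline ``pre_mean``/``pre_sd``.
    """
    pre_list = [pre] if isinstance(pre, MsdSeries) else list(pre)
    post_list = [post] if isinstance(post, MsdSeries) else list(post)
    if not pre_list or not post_list:
        raise ValidationError("both phases must contain at least one MSD series")
    pre_v = _pool_block_pair([s.msd_t for s in pre_list])
    post_v = _pool_block_pair([s.msd_t for s in post_list])
    mu, sd = float(np.mean(pre_v)), float(np.std(pre_v, ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mu)):
        raise ValidationError("pre-drug MSD has zero variance; cannot standardise")
    pre_z = (pre_v - mu) / sd
    post_z = (post_v - mu) / (sd if scale_post else 1.0)
    return {
        "pre_z": pre_z, "post_z": post_z,
        "delta": float(np.mean(post_z) - np.mean(pre_z)),
        "pre_mean": mu, "pre_sd": sd,
    }


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _lz76_scan(s):  # pragma: no cover - exercised via lz76_phrase_count
        n = s.size
        if n == 1:
            return 1
        c = 1
        l = 1
        i = 0
        k = 1
        kmax = 1
        while True:
            if s[i + k - 1] == s[l + k - 1]:
                k += 1
                if l + k > n:
                    c += 1
                    break
            else:
                if k > kmax:
                    kmax = k
                i += 1
                if i == l:
                    c += 1
                    l += kmax
                    if l + 1 > n:
                        break
                    i = 0
                    k = 1
                    kmax = 1
                else:
                    k = 1
        return c
except ImportError:  # pragma: no cover
    _lz76_scan = None


def lz76_phrase_count(bits: np.ndarray) -> int:
    """LZ76 exhaustive-history phrase count of a binary sequence.

    Parses the sequence left to right; each phrase is the shortest prefix of
    the remainder that cannot be reproduced from the history (copying from any
    earlier start, overlap allowed). The final, possibly reproducible, phrase
    counts as one.  Uses a compiled linear scan when numba is available and a
    ``bytes.find`` bisection otherwise; both implement the same exhaustive
    parse.
    """
    bits = np.asarray(bits)
    if bits.size == 0:
        raise ValidationError("sequence must be non-empty")
    if not np.isin(bits, (0, 1)).all():
        raise ValidationError("sequence must be binary")
    if _lz76_scan is not None:
        return int(_lz76_scan(np.ascontiguousarray(bits, dtype=np.uint8)))
    return _lz76_find(bits)


def _lz76_find(bits: np.ndarray) -> int:
    """Pure-Python LZ76 via substring search with bisection on phrase length."""
    s = bits.astype(np.uint8).tobytes()
    n = len(s)
    i, c = 0, 0
    # A prefix s[i:i+l] is "reproducible" when it occurs starting before i
    # (i.e. within s[0:i+l-1]; overlap with itself is allowed).
    # Reproducibility is monotone non-increasing in l, so the maximal
    # reproducible extension is located by exponential probing + bisection.
    while i < n:
        hi = n - i
        lo, probe = 0, 1
        while probe <= hi and s.find(s[i:i + probe], 0, i + probe - 1) != -1:
            lo = probe
            probe *= 2
        a, b = lo, min(probe - 1, hi)
        while a < b:
            m = (a + b + 1) // 2
            if s.find(s[i:i + m], 0, i + m - 1) != -1:
                a = m
            else:
                b = m - 1
        # phrase = maximal reproducible part plus one terminating symbol
        # (the final phrase may end at the sequence boundary instead)
        i += a + 1
        c += 1
    return c


def lzc(bits: np.ndarray, unit_id: str = "") -> tuple[int, float]:
    """LZ76 phrase count and its length-normalised value ``c * log2(L) / L``."""
    bits = np.asarray(bits)
    if bits.size < 2:
        raise ValidationError("LZC requires sequence length >= 2")
    c = lz76_phrase_count(bits)
    L = bits.size
    return c, c * np.log2(L) / L


def lzc_block(units: UnitSet, block: Block, bin_s: float = 0.010) -> LzcResult:
    """Unit-wise LZC of binarized spiking over one block (10-ms bins by default)."""
    bsm = binarize(units, block, bin_s)
    c_raw = np.empty(bsm.n_units)
    c_norm = np.empty(bsm.n_units)
    for i in range(bsm.n_units):
        c_raw[i], c_norm[i] = lzc(bsm.states[i])
    return LzcResult(unit_ids=bsm.unit_ids, c_raw=c_raw, c_norm=c_norm, L=bsm.n_bins)


def lzc_contrast(pre: list[LzcResult] | LzcResult,
                 post: list[LzcResult] | LzcResult,
                 n_permutations: int = 10000,
                 tail: str = "two",
                 rng: np.random.Generator | None = None) -> dict:
    """Per-unit paired LZC change with a sign-flip permutation test and Cohen's d.

    LZC values are pairwise averaged across the blocks of each phase (matched
    by unit id), then differenced post - pre per unit.  The group-level test
    and effect size come from :mod:`pfcdyn.stats`.
    """
    from . import stats as pstats  # local import to avoid a cycle

    pre_list = [pre] if isinstance(pre, LzcResult) else list(pre)
    post_list = [post] if isinstance(post, LzcResult) else list(post)

    def per_unit_mean(results: list[LzcResult]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for r in results:
            for uid, v in zip(r.unit_ids, r.c_norm):
                acc.setdefault(uid, []).append(float(v))
        return {uid: float(np.mean(v)) for uid, v in acc.items()}

    pre_m = per_unit_mean(pre_list)
    post_m = per_unit_mean(post_list)
    shared = [uid for uid in pre_m if uid in post_m]
    if not shared:
        raise ValidationError("no units matched across phases")
    deltas = np.array([post_m[u] - pre_m[u] for u in shared])
    report = pstats.permutation_test(deltas, n_permutations=n_permutations,
                                     tail=tail, rng=rng)
    pre_vals = np.array([pre_m[u] for u in shared])
    post_vals = np.array([post_m[u] for u in shared])
    d = (float(np.mean(deltas)) / float(np.std(deltas, ddof=1))
         if len(deltas) > 1 and np.std(deltas, ddof=1) > 0 else 0.0)
    return {
        "unit_ids": shared, "delta": deltas,
        "mean_delta": float(np.mean(deltas)),
        "p_value": report.p_value, "cohens_d": d,
        "pre": pre_vals, "post": post_vals,
    }
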