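"""Filtering, respiratory-burst detection, adaptive threshold and spike
extraction for cuff-electrode recordings."""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .types import BurstIntervals, SpikeEvents

__all__ = [
    "bandpass",
    "detect_bursts",
    "adaptive_threshold",
    "detect_spikes",
    "robust_sd",
]

#: scale factor turning median(|x|) into an SD estimate for Gaussian noise
_MAD_SCALE = 0.6745


def robust_sd(x: np.ndarray) -> float:
    """Robust noise SD estimate: median(|x|) / 0.6745."""
    x = np.asarray(x)
    if x.size == 0:
        return 0.0
    return float(np.median(np.abs(x)) / _MAD_SCALE)


def bandpass(
    signal: np.ndarray, fs: float, low: float = 160.0, high: float = 3000.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward), default 160-3000 Hz."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({fs / 2} Hz at fs={fs})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(signal)
    if x.dtype == np.float32:  # float32 recordings stay float32 (half the
        sos = sos.astype(np.float32)  # memory traffic; ~1e-4 relative error)
    else:
        x = x.astype(np.float64)
    return sps.sosfiltfilt(sos, x)


def detect_bursts(
    filtered: np.ndarray,
    fs: float,
    envelope_ms: float = 20.0,
    k: float = 2.0,
    merge_gap_ms: float = 30.0,
    min_duration_ms: float = 40.0,
) -> BurstIntervals:
    """Respiratory-burst intervals from a robust amplitude envelope.

    The envelope is the sliding-window median of |x| over ``envelope_ms``
    (evaluated on a 1-ms grid).  A rank statistic is used instead of an RMS
    so that brief CAP and cardiac transients — which occupy only a small
    fraction of any window but would dominate its power — do not register;
    the envelope tracks the background-noise amplitude, which is what rises
    during respiratory bursts.  Bursts are maximal runs where the envelope
    exceeds ``k`` times its session median; runs separated by gaps shorter
    than ``merge_gap_ms`` are merged and runs shorter than
    ``min_duration_ms`` discarded.
    """
    x = np.asarray(filtered, dtype=np.float64)
    if x.size == 0:
        return BurstIntervals(np.empty((0, 2)))
    hop = max(int(round(1e-3 * fs)), 1)  # 1-ms evaluation grid
    n_blocks = x.size // hop
    if n_blocks < 1:
        return BurstIntervals(np.empty((0, 2)))
    # per-block median of |x|, then sliding median across blocks
    block_med = np.median(
        np.abs(x[: n_blocks * hop]).reshape(n_blocks, hop), axis=1
    )
    win_blocks = max(int(round(envelope_ms)), 1) | 1
    env = (
        ndimage.median_filter(block_med, size=win_blocks, mode="nearest")
        if n_blocks > win_blocks else block_med
    )
    above = env > k * np.median(env)
    if not above.any():
        return BurstIntervals(np.empty((0, 2)))
    d = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    merged = [[starts[0], ends[0]]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    keep = [
        ((s * hop + hop // 2) / fs, (e * hop + hop // 2) / fs)
        for s, e in merged
        if (e - s) >= min_duration_ms
    ]
    return BurstIntervals(np.array(keep, dtype=float).reshape(-1, 2))


def adaptive_threshold(
    filtered: np.ndarray,
    bursts: BurstIntervals,
    fs: float,
    multiplier: float = 4.75,
    window_s: float = 1.0,
    pad_ms: float = 12.0,
) -> np.ndarray:
    """Per-sample detection threshold: ``multiplier`` times the robust noise
    SD, estimated separately inside and outside respiratory bursts.

    Within each regime the robust SD (median(|x|)/0.6745) is tracked over
    consecutive windows holding ``window_s`` seconds of in-regime samples
    and interpolated over time, so the threshold rises during bursts
    whenever burst noise is higher.  The in-burst threshold is *applied*
    to burst intervals dilated by ``pad_ms`` (detected burst edges are
    only accurate to a few ms, and applying the low out-of-burst
    threshold to edge samples with still-elevated noise would spray
    spurious events around every burst), while the noise of each regime
    is *estimated* from the undilated masks so the pad zone cannot dilute
    the in-burst estimate.
    """
    x = np.asarray(filtered)
    n = x.size
    if n == 0:
        return np.zeros(0)
    # work on 1-ms blocks: the robust SD inside each block, then regime-wise
    # aggregation over windows holding window_s of in-regime blocks
    hop = max(int(round(1e-3 * fs)), 1)
    n_blocks = max(n // hop, 1)
    tail = x[n_blocks * hop:]
    block_med = np.median(
        np.abs(x[: n_blocks * hop]).reshape(n_blocks, hop), axis=1
    )
    block_centers = (np.arange(n_blocks) + 0.5) * hop
    in_core = bursts.contains(block_centers / fs)
    if pad_ms > 0 and len(bursts):
        pad = pad_ms * 1e-3
        padded = BurstIntervals(_merge_intervals(
            np.column_stack([
                np.maximum(bursts.starts - pad, 0.0),
                bursts.ends + pad,
            ])
        ))
        in_apply = padded.contains(block_centers / fs)
    else:
        in_apply = in_core
    win_blocks = max(int(round(window_s * 1e3)), 1)
    block_thr = np.zeros(n_blocks)
    for est_mask, apply_mask in ((in_core, in_apply), (~in_apply, ~in_apply)):
        target = np.flatnonzero(apply_mask)
        if target.size == 0:
            continue
        idx = np.flatnonzero(est_mask)
        if idx.size == 0:
            idx = target  # no core blocks (degenerate): estimate in place
        n_chunks = max(int(np.ceil(idx.size / win_blocks)), 1)
        centers = np.empty(n_chunks)
        sds = np.empty(n_chunks)
        for c in range(n_chunks):
            sl = idx[c * win_blocks: (c + 1) * win_blocks]
            centers[c] = sl.mean()
            sds[c] = np.median(block_med[sl]) / _MAD_SCALE
        block_thr[target] = np.interp(target, centers, sds)
    thr = np.repeat(block_thr, hop)
    if tail.size:
        thr = np.concatenate([thr, np.full(tail.size, block_thr[-1])])
    return multiplier * thr


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    """Merge overlapping sorted intervals."""
    if not len(arr):
        return arr
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _group_crossings(crossings: np.ndarray, refractory_samples: int) -> list[np.ndarray]:
    """Chain-group supra-threshold sample indices: a new event starts when
    the gap from the previous crossing exceeds the refractory window."""
    if crossings.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(crossings) > refractory_samples)
    return np.split(crossings, breaks + 1)


def supra_threshold_peaks(
    x: np.ndarray, thr: np.ndarray, refractory_samples: int,
) -> np.ndarray:
    """Sample indices of |x| local maxima above threshold, no two closer
    than the refractory window (larger magnitude wins; ties: earlier).

    This is the event definition used by :func:`detect_spikes`: each
    retained peak is the absolute extremum of its refractory
    neighbourhood, so the two lobes of one biphasic waveform yield a
    single event while distinct events just a few samples apart on the
    flank of a larger deflection are kept separate.
    """
    mag = np.abs(x)
    above = mag >= thr
    # leftmost sample of any plateau counts as the peak
    prev = np.empty_like(mag)
    prev[0], prev[1:] = -np.inf, mag[:-1]
    nxt = np.empty_like(mag)
    nxt[-1], nxt[:-1] = -np.inf, mag[1:]
    peaks = np.flatnonzero(above & (mag > prev) & (mag >= nxt))
    if peaks.size == 0:
        return peaks
    # greedy suppression, loudest first (stable: earlier wins ties)
    order = np.argsort(-mag[peaks], kind="stable")
    keep = np.ones(peaks.size, dtype=bool)
    alive = np.ones(peaks.size, dtype=bool)
    for i in order:
        if not alive[i]:
            keep[i] = False
            continue
        lo = np.searchsorted(peaks, peaks[i] - refractory_samples)
        hi = np.searchsorted(peaks, peaks[i] + refractory_samples, side="right")
        alive[lo:hi] = False
        alive[i] = True  # the winner stays
    return peaks[keep]


def detect_spikes(
    filtered: np.ndarray,
    threshold: np.ndarray,
    fs: float,
    snippet_ms: float = 3.0,
    refractory_ms: float = 1.0,
) -> SpikeEvents:
    """Detect CAP events as threshold crossings of either polarity.

    Supra-threshold extrema closer than the refractory window are grouped
    into a single event aligned at the absolute extremum (ties: earliest
    sample).  Snippets are centered on the alignment sample; events too
    close to the session edges for a full snippet are dropped.
    """
    x = np.asarray(filtered, dtype=np.float64)
    thr = np.asarray(threshold, dtype=np.float64)
    if thr.shape != x.shape:
        raise ValueError("threshold must have the same length as the signal")
    snip_len = int(round(snippet_ms * 1e-3 * fs))
    half = snip_len // 2
    refr = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    peaks = supra_threshold_peaks(x, thr, refr)
    ok = (peaks >= half) & (peaks + snip_len - half <= x.size)
    peaks = peaks[ok]
    offsets = np.arange(snip_len) - half
    snippets = (
        x[peaks[:, None] + offsets[None, :]]
        if peaks.size else np.empty((0, snip_len))
    )
    return SpikeEvents(
        times=peaks / fs,
        snippets=snippets,
        polarities=np.sign(x[peaks]) if peaks.size else np.empty(0),
        fs=fs,
    )
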