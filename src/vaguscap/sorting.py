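"""Spike sorting: t-SNE embedding, DBSCAN clustering, cardiac-cluster
flagging against the ECG channel, and waveform metrics.

Sorting operates on waveform snippets.  For large recordings an
amplitude-stratified subsample of snippets is embedded and clustered;
every snippet (including the subsample) is then assigned to the nearest
cluster template in snippet space, so detected spike counts are
preserved.
"""
from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .signal import robust_sd, _group_crossings
from .types import SpikeEvents, UnitCluster

__all__ = [
    "embed_snippets",
    "cluster_points",
    "detect_r_peaks",
    "flag_cardiac",
    "waveform_metrics",
    "sort_recording",
]

logger = logging.getLogger(__name__)


def embed_snippets(
    snippets: np.ndarray, seed: int, perplexity: float = 30.0, n_pca: int = 10,
    max_iter: int = 500,
) -> np.ndarray:
    """2-D t-SNE embedding of waveform snippets.

    Snippets are mean-centered and reduced to their top ``n_pca`` principal
    components before the embedding: only ~20 of the snippet samples carry
    waveform signal, so distances in the raw (or per-sample standardized)
    96-dimensional space are dominated by noise in the flat tails, while
    the leading PCs concentrate the waveform differences.  Deterministic
    for a fixed seed.  Fewer than 10 snippets cannot be embedded
    meaningfully; assign such events directly by template instead.
    """
    snippets = np.asarray(snippets, dtype=np.float64)
    n = snippets.shape[0]
    if n < 10:
        raise ValueError(
            "need at least 10 snippets for embedding; assign snippets "
            "directly to templates instead"
        )
    z = snippets - snippets.mean(axis=0)
    if np.allclose(z, 0.0):
        # all snippets identical: a single point, no structure to embed
        return np.zeros((n, 2))
    k = min(n_pca, z.shape[1], n - 1)
    if k < z.shape[1]:
        pca = PCA(n_components=k, random_state=int(seed))
        z = pca.fit_transform(z)
    perp = min(perplexity, (n - 1) / 3)
    tsne = TSNE(
        n_components=2, perplexity=perp, random_state=int(seed), init="pca",
        max_iter=max_iter,
    )
    return tsne.fit_transform(z)


def cluster_points(points: np.ndarray, eps: float = 2.5, min_pts: int = 10) -> np.ndarray:
    """DBSCAN cluster labels for embedded points (-1 marks noise)."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(np.asarray(points, dtype=float))


def detect_r_peaks(
    ecg: np.ndarray, fs: float, multiplier: float = 5.0, refractory_ms: float = 50.0,
) -> np.ndarray:
    """Times (s) of ECG deflection peaks.

    Thresholds |ECG| at ``multiplier`` times the robust SD and groups
    crossings within the refractory window, aligning at the extremum.
    """
    x = np.asarray(ecg, dtype=np.float64)
    if x.size == 0:
        return np.empty(0)
    # strided subsample is ample for a global noise estimate
    thr = multiplier * robust_sd(x[::16] if x.size > 1 << 20 else x)
    if thr <= 0:
        # noiseless channel: fall back to half the largest deflection
        peak = float(np.abs(x).max())
        if peak == 0:
            return np.empty(0)
        thr = 0.5 * peak
    crossings = np.flatnonzero(np.abs(x) >= thr)
    refr = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    return np.array(
        [g[np.argmax(np.abs(x[g]))] / fs for g in _group_crossings(crossings, refr)]
    )


def flag_cardiac(
    spike_times: np.ndarray, r_peaks: np.ndarray, tol_ms: float = 2.0, frac: float = 0.8,
) -> bool:
    """True iff >= ``frac`` of the spikes fall within ±``tol_ms`` of an R-peak."""
    spike_times = np.asarray(spike_times, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=float)
    if spike_times.size == 0 or r_peaks.size == 0:
        return False
    idx = np.searchsorted(r_peaks, spike_times)
    left = r_peaks[np.clip(idx - 1, 0, len(r_peaks) - 1)]
    right = r_peaks[np.clip(idx, 0, len(r_peaks) - 1)]
    dist = np.minimum(np.abs(spike_times - left), np.abs(spike_times - right))
    return bool(np.mean(dist <= tol_ms * 1e-3) >= frac)


def waveform_metrics(snippets: np.ndarray, fs: float) -> tuple[float, float]:
    """(peak-to-peak amplitude uV, half-height width ms) of the mean waveform.

    The width is measured on the dominant phase (the lobe with the larger
    absolute extremum, relative to zero baseline) as the time span over
    which that lobe's excursion exceeds half its peak, with linear
    interpolation at the half-height crossings.
    """
    snippets = np.atleast_2d(np.asarray(snippets, dtype=np.float64))
    if snippets.shape[0] < 1:
        raise ValueError("need at least one snippet")
    mean_wf = snippets.mean(axis=0)
    amp = float(mean_wf.max() - mean_wf.min())
    if amp == 0:
        raise ValueError("degenerate waveform (flat)")
    # dominant phase
    if abs(mean_wf.min()) >= abs(mean_wf.max()):
        w = -mean_wf
    else:
        w = mean_wf.copy()
    peak_idx = int(np.argmax(w))
    half = w[peak_idx] / 2.0
    # walk outward from the peak to the half-height crossings
    i = peak_idx
    while i > 0 and w[i - 1] > half:
        i -= 1
    if i > 0:  # interpolate the crossing between i-1 and i
        left = (i - 1) + (half - w[i - 1]) / (w[i] - w[i - 1])
    else:
        left = 0.0
    j = peak_idx
    while j < len(w) - 1 and w[j + 1] > half:
        j += 1
    if j < len(w) - 1:
        right = j + (w[j] - half) / (w[j] - w[j + 1])
    else:
        right = float(j)
    width_ms = (right - left) / fs * 1e3
    return amp, float(width_ms)


def flag_shadow(
    spike_times: np.ndarray,
    larger_cluster_times: np.ndarray,
    lag_ms: float = 4.0,
    frac: float = 0.8,
) -> bool:
    """True iff >= ``frac`` of the spikes lie within ±``lag_ms`` of a
    larger cluster's spikes.

    Large waveforms leave zero-phase filter-ringing lobes on both sides of
    the main deflection; when these cross the detection threshold they
    cluster separately (consistent low-amplitude waveforms at a fixed
    short latency around a larger cluster).  This rule is the automated
    stand-in for discarding such clusters by visual inspection.
    Independent units coincide only at the Poisson chance level
    (~2 * lag * rate), far below ``frac``.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    larger = np.sort(np.asarray(larger_cluster_times, dtype=float))
    if spike_times.size == 0 or larger.size == 0:
        return False
    idx = np.searchsorted(larger, spike_times)
    left = larger[np.clip(idx - 1, 0, len(larger) - 1)]
    right = larger[np.clip(idx, 0, len(larger) - 1)]
    dist = np.minimum(np.abs(spike_times - left), np.abs(spike_times - right))
    return bool(np.mean(dist <= lag_ms * 1e-3) >= frac)


def _assign_to_templates(snippets: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Nearest-template (Euclidean) label for every snippet."""
    d2 = (
        np.sum(snippets ** 2, axis=1)[:, None]
        - 2.0 * snippets @ templates.T
        + np.sum(templates ** 2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def _stratified_subsample(
    amplitudes: np.ndarray, size: int, rng: np.random.Generator,
) -> np.ndarray:
    """Evenly spaced ranks of the amplitude ordering (plus jitter).

    A uniform random subsample is dominated by whichever event type is most
    frequent (typically cardiac deflections), which squeezes the remaining
    waveform clusters into a corner of the embedding; sampling evenly
    across amplitude ranks balances the strata instead.
    """
    n = amplitudes.size
    order = np.argsort(amplitudes, kind="stable")
    pos = (np.arange(size) + rng.uniform(0.0, 1.0, size)) * (n / size)
    return np.sort(order[np.clip(pos.astype(int), 0, n - 1)])


def _merge_fragments(
    labels: np.ndarray, features: np.ndarray,
    cos_thresh: float = 0.95, amp_ratio_thresh: float = 1.3,
) -> np.ndarray:
    """Merge clusters whose mean waveforms are near-identical.

    DBSCAN occasionally splits one unit into a main cluster and a smaller
    fragment (e.g. in-burst vs out-of-burst snippets); fragments share the
    template, so their cluster means are nearly collinear with almost the
    same peak-to-peak amplitude.  Distinct units never are: same-amplitude
    units differ in shape (cosine) and same-shape units differ in
    amplitude by construction of any resolvable recording.
    """
    ids = [c for c in np.unique(labels) if c >= 0]
    means = {c: features[labels == c].mean(axis=0) for c in ids}
    parent = {c: c for c in ids}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            wa, wb = means[a], means[b]
            cos = float(wa @ wb / (np.linalg.norm(wa) * np.linalg.norm(wb) + 1e-12))
            pa, pb = np.ptp(wa), np.ptp(wb)
            ratio = max(pa, pb) / max(min(pa, pb), 1e-12)
            if cos > cos_thresh and ratio < amp_ratio_thresh:
                parent[find(b)] = find(a)
    out = labels.copy()
    for c in ids:
        out[labels == c] = find(c)
    return out


def sort_recording(
    spikes: SpikeEvents,
    ecg: np.ndarray,
    fs: float,
    seed: int = 0,
    eps: float = 4.0,
    min_pts: int = 10,
    max_embed: int = 1500,
    cardiac_tol_ms: float = 2.0,
    cardiac_frac: float = 0.8,
    feature_ms: float = 2.0,
) -> list[UnitCluster]:
    """Full sorting chain: embed -> DBSCAN -> assign -> metrics -> cardiac flags.

    Embedding and cluster assignment operate on the central ``feature_ms``
    of each snippet: the waveform core carries all template differences,
    while the outer snippet samples mostly carry the flanks of neighbouring
    events (superimposed spikes, cardiac deflections), which smear clusters
    together at high event rates.  Waveform metrics still use the full
    snippet.  Cardiac-flagged clusters are retained in the output but
    marked for exclusion from firing analysis.  Returns an empty list
    (with a logged exclusion flag) when no spikes were detected.
    """
    if len(spikes) == 0:
        logger.warning("recording excluded: no spikes detected")
        return []
    snippets = np.asarray(spikes.snippets, dtype=np.float64)
    n = snippets.shape[0]
    core_len = min(max(int(round(feature_ms * 1e-3 * fs)), 8), snippets.shape[1])
    lo = (snippets.shape[1] - core_len) // 2
    features = snippets[:, lo:lo + core_len]
    rng = np.random.default_rng(int(seed))
    if n < 10:
        # too few events to embed: one provisional cluster
        labels = np.zeros(n, dtype=int)
    else:
        if n > max_embed:
            amps = np.ptp(features, axis=1)
            sub = _stratified_subsample(amps, max_embed, rng)
        else:
            sub = np.arange(n)
        emb = embed_snippets(features[sub], seed=seed)
        sub_labels = cluster_points(emb, eps=eps, min_pts=min_pts)
        sub_labels = _merge_fragments(sub_labels, features[sub])
        good = sub_labels >= 0
        if not good.any():
            logger.warning("all embedded snippets labeled noise by DBSCAN")
            return []
        templates = np.stack([
            features[sub[sub_labels == c]].mean(axis=0)
            for c in np.unique(sub_labels[good])
        ])
        if n > max_embed:
            labels = _assign_to_templates(features, templates)
        else:
            labels = np.full(n, -1, dtype=int)
            for new, c in enumerate(np.unique(sub_labels[good])):
                labels[sub[sub_labels == c]] = new

    r_peaks = detect_r_peaks(ecg, fs)
    clusters: list[UnitCluster] = []
    for c in np.unique(labels[labels >= 0]):
        mask = labels == c
        snips = snippets[mask]
        mean_wf = snips.mean(axis=0)
        sem = snips.std(axis=0, ddof=1) / np.sqrt(mask.sum()) if mask.sum() > 1 \
            else np.zeros_like(mean_wf)
        amp, width = waveform_metrics(snips, fs)
        times = spikes.times[mask]
        clusters.append(
            UnitCluster(
                unit_id=int(c),
                spike_times=times,
                mean_waveform=mean_wf,
                waveform_sem=sem,
                peak_to_peak_amplitude=amp,
                half_height_width_ms=width,
                cardiac_flag=flag_cardiac(times, r_peaks, cardiac_tol_ms, cardiac_frac),
                fs=fs,
            )
        )
    # artifact pass: ringing echoes of louder clusters and clusters locked
    # to the cardiac cycle beyond the strict cardiac window (both are
    # duplicate detections of events already counted elsewhere)
    core = slice(lo, lo + core_len)
    unstable: list[UnitCluster] = []
    for c in clusters:
        if c.cardiac_flag:
            continue
        others = [o.spike_times for o in clusters if o is not c]
        if others and flag_shadow(c.spike_times, np.concatenate(others)):
            c.artifact_flag = True
        elif flag_cardiac(c.spike_times, r_peaks, tol_ms=10.0, frac=cardiac_frac):
            c.artifact_flag = True
        elif c.n_spikes > 1:
            # unstable cluster: within-cluster waveform spread comparable
            # to the waveform itself.  These arise from overlapping events
            # whose superposition flipped the alignment extremum; clean
            # units sit at spread/amplitude ~ noise/amplitude (< ~0.1).
            spread = float(
                np.mean(c.waveform_sem[core]) * np.sqrt(c.n_spikes)
            )
            if spread > 0.115 * c.peak_to_peak_amplitude:
                unstable.append(c)
    # unlike echoes, unstable clusters hold *unique* events (one per real
    # spike whose extremum was displaced by an overlap); fold their events
    # into the nearest clean cluster so spike counts are preserved
    clean = [c for c in clusters if c.include_in_analysis and c not in unstable]
    if unstable and clean:
        templates = np.stack([
            features[np.isin(spikes.times, c.spike_times)].mean(axis=0)
            for c in clean
        ])
        for c in unstable:
            mask = np.isin(spikes.times, c.spike_times)
            tgt = _assign_to_templates(features[mask], templates)
            for k, cl in enumerate(clean):
                add = spikes.times[mask][tgt == k]
                if add.size:
                    cl.spike_times = np.sort(np.concatenate([cl.spike_times, add]))
            logger.info(
                "absorbed unstable cluster %d (%d events) into clean clusters",
                c.unit_id, c.n_spikes,
            )
        clusters = [c for c in clusters if c not in unstable]
    elif unstable:
        for c in unstable:
            c.artifact_flag = True
    return clusters
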