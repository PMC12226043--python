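"""Firing-rate statistics: baseline rates, burst/inter-burst analysis,
peri-event histograms, inclusion criteria, cytokine ratios, unit
categorization, normalized peak-ordered heatmaps and group comparisons.

Baseline quantification uses only the second 10 minutes of the 20-min
baseline; cytokine periods are summarized over the last 10 minutes of each
20-min period.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BurstIntervals,
    CytokineSummary,
    PeriEventHistogram,
    RateSeries,
    SessionPlan,
    UnitCategory,
    UnitCluster,
)

__all__ = [
    "bin_rates",
    "baseline_rate",
    "baseline_stats",
    "apply_inclusion",
    "burst_interburst_rates",
    "peri_event_hist",
    "cytokine_ratio",
    "period_means",
    "categorize_unit",
    "category_fractions",
    "heatmap_matrix",
    "rebin",
    "summarize_mouse",
    "group_compare",
]

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("increasing", "mixed", "decreasing")


def _spike_times_of(unit) -> np.ndarray:
    if isinstance(unit, UnitCluster):
        return np.asarray(unit.spike_times, dtype=float)
    return np.asarray(unit, dtype=float)


def bin_rates(
    unit: UnitCluster | np.ndarray,
    plan: SessionPlan,
    bin_s: float = 60.0,
    duration_s: float | None = None,
    unit_id: int | None = None,
) -> RateSeries:
    """Binned firing rates (spike count / bin width) with period labels."""
    times = _spike_times_of(unit)
    total = float(duration_s) if duration_s is not None else plan.total_s
    edges = np.arange(0.0, total + 0.5 * bin_s, bin_s)
    if edges[-1] < total:  # pragma: no cover - guard for odd bin sizes
        edges = np.append(edges, total)
    counts, _ = np.histogram(times, bins=edges)
    rates = counts / np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    uid = unit_id if unit_id is not None else (
        unit.unit_id if isinstance(unit, UnitCluster) else -1
    )
    return RateSeries(
        unit_id=int(uid), bin_edges=edges, rates=rates,
        period_labels=plan.period_of(centers), plan=plan,
    )


def baseline_rate(
    spike_times: np.ndarray, window: tuple[float, float] = (600.0, 1200.0),
) -> float:
    """Mean CAPs/s over the baseline window (default second 10 min of BL)."""
    t = np.asarray(spike_times, dtype=float)
    lo, hi = window
    return float(np.sum((t >= lo) & (t < hi)) / (hi - lo))


def baseline_stats(
    units_per_mouse: Mapping[str, Sequence[np.ndarray] | Sequence[UnitCluster]],
    session_s: float,
    window: tuple[float, float] = (600.0, 1200.0),
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-unit and per-mouse (summed) baseline rates over the window.

    Returns a per-unit table (mouse_id, unit_index, rate) and the per-mouse
    sums.  Errors if the session does not cover the baseline window.
    """
    if session_s < window[1]:
        raise ValueError(
            f"session of {session_s} s does not cover the baseline window {window}"
        )
    rows = []
    for mouse_id, units in units_per_mouse.items():
        for k, unit in enumerate(units):
            rows.append(
                {
                    "mouse_id": mouse_id,
                    "unit_index": k,
                    "rate": baseline_rate(_spike_times_of(unit), window),
                }
            )
    per_unit = pd.DataFrame(rows, columns=["mouse_id", "unit_index", "rate"])
    per_mouse = per_unit.groupby("mouse_id")["rate"].sum()
    return per_unit, per_mouse


def apply_inclusion(
    series: Sequence[RateSeries],
    baseline_window: tuple[float, float] = (600.0, 1200.0),
    max_zero_min: int = 5,
) -> tuple[list[RateSeries], pd.DataFrame]:
    """Strict inclusion criterion for cytokine-response analysis.

    A unit is excluded iff its baseline rate is *higher than* one standard
    deviation above the population average, or iff it has zero firing for
    more than ``max_zero_min`` consecutive minutes after the first
    injection (i.e. at least ``max_zero_min + 1`` consecutive zero 1-min
    bins).  Returns the included series and an exclusion log.
    """
    bl = np.array([_window_mean(s, baseline_window) for s in series])
    mean, sd = bl.mean(), bl.std(ddof=0)
    included: list[RateSeries] = []
    log_rows = []
    for s, b in zip(series, bl):
        if b > mean + sd:
            log_rows.append({"unit_id": s.unit_id, "reason": "baseline>mean+1sd",
                             "baseline_rate": b})
            continue
        if _has_zero_run(s, s.plan.injection_s[0], max_zero_min):
            log_rows.append({"unit_id": s.unit_id, "reason": "zero-firing-run",
                             "baseline_rate": b})
            continue
        included.append(s)
    log = pd.DataFrame(log_rows, columns=["unit_id", "reason", "baseline_rate"])
    return included, log


def _has_zero_run(series: RateSeries, after_s: float, max_zero_min: int) -> bool:
    one_min = rebin(series, 60.0)
    post = one_min.rates[one_min.bin_edges[:-1] >= after_s]
    run = longest = 0
    for r in post:
        run = run + 1 if r == 0 else 0
        longest = max(longest, run)
    return longest > max_zero_min


def burst_interburst_rates(
    unit: UnitCluster | np.ndarray,
    bursts: BurstIntervals,
    observation: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """CAP frequency inside respiratory bursts and in the complement.

    ``observation`` restricts the analysis window (default: from 0 to the
    end of the last burst-covered period known to the caller is not needed;
    the window spans [0, max(spike, burst end)]).
    """
    times = _spike_times_of(unit)
    arr = bursts.array
    if observation is None:
        hi = max(arr[:, 1].max() if len(arr) else 0.0,
                 times.max() if times.size else 0.0)
        observation = (0.0, float(hi))
    lo, hi = observation
    arr = np.clip(arr, lo, hi) if len(arr) else arr
    burst_time = float(np.sum(arr[:, 1] - arr[:, 0])) if len(arr) else 0.0
    if burst_time <= 0:
        raise ValueError("zero total burst time in the observation window")
    total_time = hi - lo
    sel = (times >= lo) & (times < hi)
    times = times[sel]
    inside = bursts.contains(times)
    burst_rate = float(inside.sum() / burst_time)
    inter_time = total_time - burst_time
    inter_rate = float((~inside).sum() / inter_time) if inter_time > 0 else float("nan")
    return burst_rate, inter_rate


def peri_event_hist(
    units: Iterable[np.ndarray] | Iterable[UnitCluster],
    bursts: BurstIntervals,
    window_ms: tuple[float, float] = (-200.0, 600.0),
    bin_ms: float = 10.0,
) -> PeriEventHistogram:
    """Summed CAP counts in lag bins relative to each burst onset."""
    if not len(bursts):
        raise ValueError("need at least one burst onset")
    edges = np.arange(window_ms[0], window_ms[1] + 0.5 * bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    onsets = bursts.starts
    for unit in units:
        times = np.sort(_spike_times_of(unit))
        if not times.size:
            continue
        lo = np.searchsorted(times, onsets + window_ms[0] * 1e-3, side="left")
        hi = np.searchsorted(times, onsets + window_ms[1] * 1e-3, side="left")
        for onset, a, b in zip(onsets, lo, hi):
            if b > a:
                c, _ = np.histogram((times[a:b] - onset) * 1e3, bins=edges)
                counts += c
    duration_ms = float(np.mean(bursts.ends - bursts.starts) * 1e3)
    return PeriEventHistogram(lag_edges_ms=edges, counts=counts,
                              burst_duration_ms=duration_ms)


def cytokine_ratio(f_bl: float, f_cyt: float) -> float | None:
    """Normalized rate change (f_cyt - f_bl)/(f_cyt + f_bl) in [-1, 1].

    Undefined (None) when both rates are zero.
    """
    if f_bl < 0 or f_cyt < 0:
        raise ValueError("rates must be >= 0")
    denom = f_cyt + f_bl
    if denom == 0:
        return None
    return (f_cyt - f_bl) / denom


def _window_mean(series: RateSeries, window: tuple[float, float]) -> float:
    lo, hi = window
    left = series.bin_edges[:-1]
    sel = (left >= lo) & (left < hi)
    if not sel.any():
        raise ValueError(f"rate series does not cover window {window}")
    return float(series.rates[sel].mean())


def period_means(series: RateSeries) -> tuple[float, float, float]:
    """Mean rate over the last 10 min of BL and of each cytokine period."""
    plan = series.plan
    inj1, inj2 = plan.injection_s
    total = plan.total_s
    windows = [(inj1 - 600.0, inj1), (inj2 - 600.0, inj2), (total - 600.0, total)]
    names = ["BL", "C1", "C2"]
    out = []
    for name, win in zip(names, windows):
        if series.bin_edges[-1] < win[1] - 1e-9:
            raise ValueError(f"rate series truncated before the {name} window {win}")
        out.append(_window_mean(series, win))
    return tuple(out)  # type: ignore[return-value]


def categorize_unit(
    m_bl: float, m_c1: float, m_c2: float, unit_id: int = -1,
) -> UnitCategory:
    """Category from the sign pattern of the per-period rate changes.

    (+,+) -> increasing, (-,-) -> decreasing, opposite signs -> mixed.
    An exactly zero delta (measure-zero on real data) is assigned to
    'mixed' and logged.
    """
    d1, d2 = m_c1 - m_bl, m_c2 - m_bl
    if d1 == 0 or d2 == 0:
        logger.info("unit %s has an exactly zero period delta; assigning 'mixed'", unit_id)
        cat = "mixed"
    elif d1 > 0 and d2 > 0:
        cat = "increasing"
    elif d1 < 0 and d2 < 0:
        cat = "decreasing"
    else:
        cat = "mixed"
    return UnitCategory(unit_id=unit_id, category=cat, delta_c1=d1, delta_c2=d2)


def category_fractions(
    categories: Sequence[UnitCategory | str],
    mouse_of: Mapping[int, str] | None = None,
    decimals: int = 2,
) -> pd.Series | pd.DataFrame:
    """Percentage of units per category (rounded; sums to 100 within rounding).

    With ``mouse_of`` (unit_id -> mouse) a per-mouse stacked table is
    returned instead.
    """
    cats = [c.category if isinstance(c, UnitCategory) else str(c) for c in categories]
    if not cats:
        raise ValueError("need at least one categorized unit")
    if mouse_of is not None:
        ids = [c.unit_id for c in categories]  # type: ignore[union-attr]
        df = pd.DataFrame({"mouse": [mouse_of[i] for i in ids], "category": cats})
        table = (
            df.groupby("mouse")["category"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
            .reindex(columns=CATEGORY_ORDER, fill_value=0.0)
            * 100.0
        )
        return table.round(decimals)
    counts = pd.Series(cats).value_counts().reindex(CATEGORY_ORDER, fill_value=0)
    return (100.0 * counts / counts.sum()).round(decimals)


def rebin(series: RateSeries, bin_s: float) -> RateSeries:
    """Aggregate a rate series into coarser uniform bins (rate-preserving)."""
    factor = bin_s / series.bin_s
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError("new bin width must be an integer multiple of the old")
    factor = int(round(factor))
    n = len(series.rates) // factor
    rates = series.rates[: n * factor].reshape(n, factor).mean(axis=1)
    edges = series.bin_edges[:: factor][: n + 1]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RateSeries(
        unit_id=series.unit_id, bin_edges=edges, rates=rates,
        period_labels=series.plan.period_of(centers), plan=series.plan,
    )


def heatmap_matrix(
    series: Sequence[RateSeries], bin_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Peak-normalized rate matrix with rows ordered by peak-firing time.

    Each row is one unit scaled to [0, 1] by its own peak; rows are sorted
    ascending by the bin of the peak firing rate (ties broken by unit_id);
    all-zero units are placed last.  Returns (matrix, unit_id row order).
    """
    if not len(series):
        raise ValueError("need at least one unit")
    rows, ids, argmaxes, zero = [], [], [], []
    for s in series:
        r = rebin(s, bin_s).rates if abs(s.bin_s - bin_s) > 1e-9 else s.rates
        peak = r.max()
        if peak == 0:
            rows.append(np.zeros_like(r))
            argmaxes.append(np.inf)  # all-zero rows sort last
        else:
            rows.append(r / peak)
            argmaxes.append(int(np.argmax(r)))
        ids.append(s.unit_id)
        zero.append(peak == 0)
    order = sorted(range(len(rows)), key=lambda i: (argmaxes[i], ids[i]))
    matrix = np.stack([rows[i] for i in order])
    return matrix, np.array([ids[i] for i in order])


def summarize_mouse(
    mouse_id: str, series: Sequence[RateSeries], plan: SessionPlan,
) -> CytokineSummary:
    """Per-mouse summed rates over the last 10 min of BL/TNF/IL-1β and the
    cytokine ratios (summing over the mouse's included units)."""
    if not len(series):
        raise ValueError("need at least one unit")
    sums = {"BL": 0.0, "C1": 0.0, "C2": 0.0}
    for s in series:
        m_bl, m_c1, m_c2 = period_means(s)
        sums["BL"] += m_bl
        sums["C1"] += m_c1
        sums["C2"] += m_c2
    by_cyt = {plan.cytokine_of(p): sums[p] for p in ("C1", "C2")}
    return CytokineSummary(
        mouse_id=mouse_id,
        f_bl=sums["BL"],
        f_tnf=by_cyt["TNF"],
        f_il1=by_cyt["IL1B"],
        ratio_tnf=cytokine_ratio(sums["BL"], by_cyt["TNF"]),
        ratio_il1=cytokine_ratio(sums["BL"], by_cyt["IL1B"]),
    )


def group_compare(
    sample_a: np.ndarray, sample_b: np.ndarray, test: str = "auto",
) -> tuple[float, float, str]:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    ``auto``: two-tailed t-test if both samples pass Shapiro-Wilk at
    alpha = 0.05, otherwise Mann-Whitney U.  ``KS`` only on request for
    distribution comparisons.  Returns (statistic, p-value, test used).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if test == "auto":
        normal = (
            stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        )
        test = "t" if normal else "MW"
    if test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "MW":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "KS":
        res = stats.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue), test
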