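"""Synthetic cuff-electrode recordings with ground truth.

Generates seedable cohorts of simulated two-channel (vagus cuff + ECG)
recordings that emulate the statistical structure of control (CON) and
long-sepsis (LS) mice: per-unit biphasic CAP templates riding on Gaussian
noise whose variance rises during recurring respiratory bursts, cardiac
deflections shared with the ECG channel, group-dependent baseline firing,
and step-like per-unit rate changes after each of two cytokine injections.

The rate law for every unit is an inhomogeneous Poisson process

    lambda(t) = r_base * burst(t) * response(t) * jitter(t)

where ``burst(t)`` equals ``burst_gain`` inside respiratory bursts and the
complementary factor (keeping the time average at ``r_base``) outside,
``response(t)`` is 1 during baseline and ``1 + c1`` / ``1 + c2`` after the
first / second injection (changes are expressed relative to baseline), and
``jitter(t)`` is a mean-one Gamma multiplier redrawn every second
(physiological overdispersion beyond Poisson counting noise).
"""
from __future__ import annotations

import numpy as np

from .types import (
    CYTOKINES,
    GroundTruth,
    RateSeries,
    RecordingBundle,
    SessionPlan,
    SimConfig,
    UnitProfile,
)

__all__ = [
    "FIXTURE_NAMES",
    "make_fixture_config",
    "simulate_recording",
    "simulate_rate_series",
    "cap_template",
    "cardiac_template_vagus",
    "cardiac_template_ecg",
]

FIXTURE_NAMES = ("paper-CON", "paper-LS")

# Template bank: (negative-lobe amplitude uV, width scale, positive/negative
# lobe ratio).  Amplitudes sit well above the adaptive threshold even inside
# respiratory bursts (4 * 3 * noise SD after filtering).
TEMPLATE_BANK: tuple[tuple[float, float, float], ...] = tuple(
    (amp, ws, pf)
    for amp in (28.0, 44.0, 60.0)
    for ws in (0.6, 1.45)
    for pf in (0.3, 0.75)
)

# Expected respiratory-burst time fractions for the two groups follow from
# the planted duration/period means; the within-burst rate multiplier g and
# its out-of-burst complement h = (1 - p*g)/(1 - p) preserve the session
# average.  The within/between contrast g/h ~ 3.36 reproduces the CON
# within-burst group rate; see docs/methods.md for why the contrast and the
# overall rate cannot be chosen independently of the inter-burst rate.
_BURST_CONTRAST = 13.09 / 5.79  # within-burst multiplier for CON


#: burst-time fraction of the CON fixture, used to fix the local
#: within/between-burst rate ratio implied by the CON calibration
_P_CON = 133.73 / 649.75
_LOCAL_RATIO = _BURST_CONTRAST / ((1.0 - _P_CON * _BURST_CONTRAST) / (1.0 - _P_CON))


def _burst_gain(duration_ms: float, period_ms: float) -> float:
    """Within-burst rate multiplier g solving p*g + (1-p)*(g/C) = 1 for the
    calibrated local contrast C, so the session average stays at r_base."""
    p = duration_ms / period_ms
    return float(_LOCAL_RATIO / (p * _LOCAL_RATIO + (1.0 - p)))


def _out_gain(g: float, duration_ms: float, period_ms: float) -> float:
    p = duration_ms / period_ms
    return float((1.0 - p * g) / (1.0 - p))


def _min_response_magnitude(rate: float, jitter_shape: float) -> float:
    """Smallest fractional response reliably detectable from 10-min means.

    The SE of a last-10-min period mean difference at rate r is about
    sqrt(2 * (r + r^2/k + 0.036 r^2) / 600) (Poisson + Gamma jitter + burst
    coverage); the floor keeps planted deltas >= ~4 SE so that sign-based
    categorization recovers every planted category.
    """
    var_1s = rate + (rate ** 2) / jitter_shape + 0.036 * rate ** 2
    se_delta = np.sqrt(2.0 * var_1s / 600.0)
    return float(4.0 * se_delta / max(rate, 1e-9) + 0.02)


def _draw_rates(
    rng: np.random.Generator, n: int, mean: float, sigma_log: float,
    lo: float, hi: float,
) -> np.ndarray:
    mu = np.log(mean) - 0.5 * sigma_log ** 2
    r = rng.lognormal(mu, sigma_log, size=n)
    r = np.clip(r, lo, hi)
    # rescale to the exact target mean, then re-clip once (negligible drift)
    r = np.clip(r * (mean / r.mean()), lo, hi)
    return r * (mean / r.mean())


def _draw_responses(
    rng: np.random.Generator,
    categories: np.ndarray,
    rates: np.ndarray,
    pos_range: tuple[float, float],
    neg_range: tuple[float, float],
    jitter_shape: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(categories)
    c1 = np.zeros(n)
    c2 = np.zeros(n)
    mixed_flip = False
    for i, cat in enumerate(categories):
        floor = _min_response_magnitude(rates[i], jitter_shape)
        pos = max(rng.uniform(*pos_range), floor)
        neg = -min(max(rng.uniform(*neg_range), floor), 0.9)
        pos2 = max(rng.uniform(*pos_range), floor)
        neg2 = -min(max(rng.uniform(*neg_range), floor), 0.9)
        if cat == "increasing":
            c1[i], c2[i] = pos, pos2
        elif cat == "decreasing":
            c1[i], c2[i] = neg, neg2
        else:  # mixed: alternate (+,-) and (-,+) patterns
            c1[i], c2[i] = (pos, neg2) if not mixed_flip else (neg, pos2)
            mixed_flip = not mixed_flip
    return c1, c2


def make_fixture_config(name: str, seed: int) -> SimConfig:
    """Build one of the packaged cohort fixtures.

    ``paper-CON``: 15 mice, 49 units (3-4 per mouse), planted per-unit
    baseline rates with mean 5.79 CAPs/s and category counts 33 increasing /
    13 mixed / 3 decreasing; respiratory bursts of 133.73 ms every 649.75 ms.

    ``paper-LS``: 20 mice, 51 units, per-unit baseline mean 14.22 CAPs/s
    with a right tail reaching the 20-70 CAPs/s range, category counts
    14 increasing / 22 mixed / 15 decreasing; bursts of 138.2 ms every
    694.87 ms.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; known fixtures: {FIXTURE_NAMES}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), FIXTURE_NAMES.index(name)]))
    jitter_shape = 4.0
    if name == "paper-CON":
        n_mice = 15
        units_per_mouse = (4,) * 4 + (3,) * 11          # 49 units
        duration = (133.73, 10.0)
        period = (649.75, 60.0)
        rates = _draw_rates(rng, 49, 5.79, 0.6, 1.0, 18.0)
        categories = np.array(
            ["increasing"] * 33 + ["mixed"] * 13 + ["decreasing"] * 3
        )
        pos_range, neg_range = (0.45, 1.2), (0.35, 0.7)
        group = "CON"
    else:
        n_mice = 20
        units_per_mouse = (3,) * 11 + (2,) * 9          # 51 units
        duration = (138.2, 10.0)
        period = (694.87, 60.0)
        rates = _draw_rates(rng, 51, 14.22, 0.8, 2.0, 70.0)
        categories = np.array(
            ["increasing"] * 14 + ["mixed"] * 22 + ["decreasing"] * 15
        )
        # weak modulation relative to the per-second rate noise at the
        # high LS baselines: detectable in 10-min means yet barely above
        # the smoothed per-second noise floor the decoder sees
        pos_range, neg_range = (0.15, 0.3), (0.15, 0.3)
        group = "LS"

    categories = categories[rng.permutation(len(categories))]
    c1, c2 = _draw_responses(rng, categories, rates, pos_range, neg_range, jitter_shape)
    g = _burst_gain(duration[0], period[0])

    profiles = []
    k = 0
    for m in range(n_mice):
        # Within one mouse every unit gets a distinct shape comb (width x
        # lobe ratio), and the only same-amplitude pair (units 0 and 3)
        # differs in both shape factors: no two units of a mouse are left
        # separable by amplitude alone or by a single shape factor alone.
        s0 = m % 4
        s3 = s0 ^ 3
        s1 = (m + 1) % 4 if (m + 1) % 4 != s3 else (m + 2) % 4
        combs = (s0, s1, s1 ^ 3, s3)
        for j in range(units_per_mouse[m]):
            amp_idx = j % 3
            template_id = 4 * amp_idx + combs[j]
            profiles.append(
                UnitProfile(
                    baseline_rate=float(rates[k]),
                    burst_gain=g,
                    response_c1=float(c1[k]),
                    response_c2=float(c2[k]),
                    template_id=template_id,
                )
            )
            k += 1

    return SimConfig(
        group_label=group,
        n_mice=n_mice,
        units_per_mouse=units_per_mouse,
        unit_profiles=tuple(profiles),
        resp_burst_duration_ms=duration,
        resp_burst_period_ms=period,
        rate_jitter_shape=jitter_shape,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# waveform templates

def cap_template(
    fs: float, amp_neg_uv: float, width_scale: float = 1.0, pos_frac: float = 0.5,
) -> tuple[np.ndarray, int]:
    """Biphasic (negative-then-positive) CAP template, ~1.5 ms support.

    Returns the sample array and the index of the negative peak (the
    alignment point used when planting spikes).
    """
    t = np.arange(int(round(1.5e-3 * fs))) / fs * 1e3  # ms
    neg = -amp_neg_uv * np.exp(-0.5 * ((t - 0.55) / (0.13 * width_scale)) ** 2)
    pos = pos_frac * amp_neg_uv * np.exp(-0.5 * ((t - 1.0) / (0.16 * width_scale)) ** 2)
    w = (neg + pos).astype(np.float32)
    return w, int(np.argmin(w))


def cardiac_template_vagus(fs: float) -> tuple[np.ndarray, int]:
    """Wide triphasic cardiac deflection as picked up by the cuff."""
    t = np.arange(int(round(5e-3 * fs))) / fs * 1e3  # ms
    w = (
        22.0 * np.exp(-0.5 * ((t - 2.5) / 0.55) ** 2)
        - 8.0 * np.exp(-0.5 * ((t - 1.1) / 0.7) ** 2)
        - 8.0 * np.exp(-0.5 * ((t - 3.9) / 0.7) ** 2)
    ).astype(np.float32)
    return w, int(np.argmax(w))


def cardiac_template_ecg(fs: float) -> tuple[np.ndarray, int]:
    """Sharp R-like deflection on the ECG channel."""
    t = np.arange(int(round(8e-3 * fs))) / fs * 1e3  # ms
    w = (
        200.0 * np.exp(-0.5 * ((t - 3.0) / 0.8) ** 2)
        - 40.0 * np.exp(-0.5 * ((t - 5.5) / 1.2) ** 2)
    ).astype(np.float32)
    return w, int(np.argmax(w))


# ---------------------------------------------------------------------------
# burst / cardiac event processes

def _draw_bursts(rng: np.random.Generator, total_s: float, config: SimConfig) -> np.ndarray:
    """Renewal process of respiratory bursts: truncated-normal duration and
    onset-to-onset period (period floored at duration + 50 ms)."""
    dur_m, dur_sd = config.resp_burst_duration_ms
    per_m, per_sd = config.resp_burst_period_ms
    onset = rng.uniform(0.0, per_m / 1e3)
    out = []
    while onset < total_s:
        dur = max(rng.normal(dur_m, dur_sd), 20.0) / 1e3
        end = min(onset + dur, total_s)
        if end > onset:
            out.append((onset, end))
        period = max(rng.normal(per_m, per_sd), dur * 1e3 + 50.0) / 1e3
        onset += period
    return np.array(out, dtype=float).reshape(-1, 2)


def _draw_cardiac(rng: np.random.Generator, total_s: float, rate_hz: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    t = rng.uniform(0.0, 1.0 / rate_hz)
    out = []
    while t < total_s:
        out.append(t)
        t += max(1.0 / rate_hz + rng.normal(0.0, 0.002), 0.02)
    return np.asarray(out)


def _response_multiplier_ms(
    n_ms: int, plan: SessionPlan, c1: float, c2: float, ramp_min: float,
) -> np.ndarray:
    """Per-millisecond response factor: 1 in BL, 1+c1 in C1, 1+c2 in C2."""
    t = (np.arange(n_ms) + 0.5) / 1e3
    inj1, inj2 = plan.injection_s
    mult = np.ones(n_ms)
    if ramp_min > 0:
        ramp = ramp_min * 60.0
        f1 = np.clip((t - inj1) / ramp, 0.0, 1.0)
        f2 = np.clip((t - inj2) / ramp, 0.0, 1.0)
        mult = (1.0 + c1 * f1) * (t < inj2) + (1.0 + c1 + (c2 - c1) * f2) * (t >= inj2)
    else:
        mult[t >= inj1] = 1.0 + c1
        mult[t >= inj2] = 1.0 + c2
    return mult


def _unit_spike_times(
    rng: np.random.Generator,
    profile: UnitProfile,
    total_s: float,
    burst_mask_ms: np.ndarray,
    jitter_s: np.ndarray,
    plan: SessionPlan,
    config: SimConfig,
) -> np.ndarray:
    """Draw spike times on a 1-ms grid from the inhomogeneous Poisson law."""
    n_ms = len(burst_mask_ms)
    h = _out_gain(profile.burst_gain, *_dur_per(config))
    mult = np.where(burst_mask_ms, profile.burst_gain, h)
    mult = mult * _response_multiplier_ms(
        n_ms, plan, profile.response_c1, profile.response_c2, config.response_ramp_min
    )
    mult = mult * np.repeat(jitter_s, 1000)[:n_ms]
    lam = profile.baseline_rate * mult * 1e-3
    counts = rng.poisson(lam)
    idx = np.nonzero(counts)[0]
    reps = counts[idx]
    times = np.repeat(idx, reps) * 1e-3 + rng.uniform(0.0, 1e-3, int(reps.sum()))
    times = np.sort(times)
    return times[times < total_s]


def _dur_per(config: SimConfig) -> tuple[float, float]:
    return config.resp_burst_duration_ms[0], config.resp_burst_period_ms[0]


def _ms_mask_from_intervals(intervals: np.ndarray, n_ms: int) -> np.ndarray:
    mask = np.zeros(n_ms, dtype=bool)
    for s, e in intervals:
        i0, i1 = int(np.ceil(s * 1e3)), min(n_ms, int(np.ceil(e * 1e3)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def _add_waveform(signal: np.ndarray, template: np.ndarray, peak_idx: int,
                  times: np.ndarray, fs: float) -> None:
    n = len(signal)
    L = len(template)
    for t in times:
        i0 = int(round(t * fs)) - peak_idx
        a, b = max(i0, 0), min(i0 + L, n)
        if b > a:
            signal[a:b] += template[a - i0:b - i0]


def _mouse_rng(config: SimConfig, mouse_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 9176, int(mouse_index)])
    )


def simulate_recording(
    config: SimConfig, mouse_index: int, duration_s: float | None = None,
) -> tuple[RecordingBundle, GroundTruth]:
    """Simulate the two-channel continuous recording of one mouse.

    ``duration_s`` truncates the session (e.g. baseline-only excerpts);
    by default the full session plan is simulated.  Identical
    ``(config, mouse_index)`` give bit-identical output.
    """
    profiles = config.profiles_of_mouse(mouse_index)  # validates index
    plan = config.plan_of_mouse(mouse_index)
    total_s = float(duration_s) if duration_s is not None else plan.total_s
    if total_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = _mouse_rng(config, mouse_index)
    fs = config.fs
    n = int(round(total_s * fs))
    n_ms = int(round(total_s * 1e3))
    n_sec = int(np.ceil(total_s))

    bursts = _draw_bursts(rng, total_s, config)
    cardiac = _draw_cardiac(rng, total_s, config.cardiac_rate_hz)
    burst_mask_ms = _ms_mask_from_intervals(bursts, n_ms)

    unit_offset = sum(config.units_per_mouse[:mouse_index])
    spike_times: dict[int, np.ndarray] = {}
    for j, prof in enumerate(profiles):
        jitter = rng.gamma(config.rate_jitter_shape, 1.0 / config.rate_jitter_shape, n_sec)
        spike_times[unit_offset + j] = _unit_spike_times(
            rng, prof, total_s, burst_mask_ms, jitter, plan, config
        )

    # vagus channel: noise (burst-scaled) + CAP templates + cardiac deflections
    vagus = rng.standard_normal(n, dtype=np.float32) * np.float32(config.noise_sd_base_uv)
    for s, e in bursts:
        i0, i1 = int(np.ceil(s * fs)), min(n, int(np.ceil(e * fs)))
        if i1 > i0:
            vagus[i0:i1] *= np.float32(config.noise_burst_multiplier)
    for j, prof in enumerate(profiles):
        tpl, peak = cap_template(fs, *TEMPLATE_BANK[prof.template_id])
        _add_waveform(vagus, tpl, peak, spike_times[unit_offset + j], fs)
    card_v, peak_v = cardiac_template_vagus(fs)
    card_jitter = cardiac + rng.uniform(-5e-4, 5e-4, len(cardiac))
    _add_waveform(vagus, card_v, peak_v, card_jitter, fs)

    # ECG channel: cardiac deflections + noise, no CAP templates
    ecg = rng.standard_normal(n, dtype=np.float32) * np.float32(config.ecg_noise_sd_uv)
    card_e, peak_e = cardiac_template_ecg(fs)
    _add_waveform(ecg, card_e, peak_e, cardiac, fs)

    events = [
        (plan.cytokine_of(p), t)
        for p, t in zip(("C1", "C2"), plan.injection_s)
        if t < total_s
    ]
    bundle = RecordingBundle(
        vagus_signal=vagus, ecg_signal=ecg, fs=fs, events=events,
        group=config.group_label, mouse_id=f"{config.group_label}-{mouse_index:02d}",
    )
    base = np.array([p.baseline_rate for p in profiles])
    truth = GroundTruth(
        spike_times=spike_times,
        categories={unit_offset + j: p.category for j, p in enumerate(profiles)},
        baseline_rates={unit_offset + j: p.baseline_rate for j, p in enumerate(profiles)},
        f_bl=float(base.sum()),
        f_c1=float(np.sum(base * (1.0 + np.array([p.response_c1 for p in profiles])))),
        f_c2=float(np.sum(base * (1.0 + np.array([p.response_c2 for p in profiles])))),
        burst_intervals=bursts,
        cardiac_times=cardiac,
    )
    return bundle, truth


def simulate_rate_series(
    config: SimConfig,
) -> tuple[list[RateSeries], list[GroundTruth]]:
    """Stage-level shortcut: per-unit 1-s binned rates from the same rate
    law as :func:`simulate_recording`, with no waveform or noise layer.

    Returns the flat list of per-unit series (cohort order) and one
    ground-truth record per mouse.
    """
    series: list[RateSeries] = []
    truths: list[GroundTruth] = []
    for m in range(config.n_mice):
        profiles = config.profiles_of_mouse(m)
        plan = config.plan_of_mouse(m)
        total_s = plan.total_s
        n_sec = int(round(total_s))
        rng = _mouse_rng(config, m)
        bursts = _draw_bursts(rng, total_s, config)
        # per-second burst coverage fraction
        cover = np.zeros(n_sec)
        for s, e in bursts:
            lo, hi = int(np.floor(s)), int(np.ceil(e))
            for b in range(lo, min(hi, n_sec)):
                cover[b] += min(e, b + 1) - max(s, b)
        edges = np.arange(n_sec + 1, dtype=float)
        centers = edges[:-1] + 0.5
        labels = plan.period_of(centers)
        inj1, inj2 = plan.injection_s
        unit_offset = sum(config.units_per_mouse[:m])
        base = np.array([p.baseline_rate for p in profiles])
        for j, prof in enumerate(profiles):
            h = _out_gain(prof.burst_gain, *_dur_per(config))
            mult = cover * prof.burst_gain + (1.0 - cover) * h
            resp = np.ones(n_sec)
            if config.response_ramp_min > 0:
                ramp = config.response_ramp_min * 60.0
                f1 = np.clip((centers - inj1) / ramp, 0.0, 1.0)
                f2 = np.clip((centers - inj2) / ramp, 0.0, 1.0)
                resp = np.where(
                    centers < inj2,
                    1.0 + prof.response_c1 * f1,
                    1.0 + prof.response_c1 + (prof.response_c2 - prof.response_c1) * f2,
                )
            else:
                resp[centers >= inj1] = 1.0 + prof.response_c1
                resp[centers >= inj2] = 1.0 + prof.response_c2
            jitter = rng.gamma(
                config.rate_jitter_shape, 1.0 / config.rate_jitter_shape, n_sec
            )
            lam = prof.baseline_rate * mult * resp * jitter
            rates = rng.poisson(lam).astype(float)
            series.append(
                RateSeries(
                    unit_id=unit_offset + j,
                    bin_edges=edges,
                    rates=rates,
                    period_labels=labels,
                    plan=plan,
                )
            )
        truths.append(
            GroundTruth(
                spike_times={},
                categories={unit_offset + j: p.category for j, p in enumerate(profiles)},
                baseline_rates={unit_offset + j: p.baseline_rate for j, p in enumerate(profiles)},
                f_bl=float(base.sum()),
                f_c1=float(np.sum(base * (1.0 + np.array([p.response_c1 for p in profiles])))),
                f_c2=float(np.sum(base * (1.0 + np.array([p.response_c2 for p in profiles])))),
                burst_intervals=bursts,
                cardiac_times=np.empty(0),
            )
        )
    return series, truths
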