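"""Domain containers shared across the pipeline.

Conventions used throughout the package: time in seconds, voltages in
microvolts, firing rates in CAPs/s, 0-based sample indices, half-open
intervals ``[start, end)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed class order used by the decoder and for tie-breaking.
CLASS_ORDER = ("BL", "C1", "C2")

CYTOKINES = ("TNF", "IL1B")


@dataclass(frozen=True)
class SessionPlan:
    """Timeline of one recording session.

    A session is a baseline period followed by two intraperitoneal cytokine
    injections; the cytokine order is counterbalanced across mice.
    """

    bl_min: float = 20.0
    injection_min: tuple[float, float] = (20.0, 40.0)
    total_min: float = 60.0
    cytokine_order: tuple[str, str] = ("TNF", "IL1B")

    def __post_init__(self) -> None:
        if not (0 < self.bl_min <= self.injection_min[0] < self.injection_min[1] < self.total_min):
            raise ValueError("session plan times must satisfy 0 < BL <= inj1 < inj2 < total")
        if sorted(self.cytokine_order) != sorted(CYTOKINES):
            raise ValueError(f"cytokine_order must be a permutation of {CYTOKINES}")

    @property
    def total_s(self) -> float:
        return self.total_min * 60.0

    @property
    def injection_s(self) -> tuple[float, float]:
        return (self.injection_min[0] * 60.0, self.injection_min[1] * 60.0)

    def period_of(self, t: np.ndarray | float) -> np.ndarray:
        """Map time(s) in seconds to period labels 'BL' / 'C1' / 'C2'."""
        t = np.asarray(t, dtype=float)
        inj1, inj2 = self.injection_s
        out = np.full(t.shape, "BL", dtype="U2")
        out[t >= inj1] = "C1"
        out[t >= inj2] = "C2"
        return out

    def cytokine_of(self, period: str) -> str:
        """Which cytokine defines period 'C1' or 'C2'."""
        if period == "C1":
            return self.cytokine_order[0]
        if period == "C2":
            return self.cytokine_order[1]
        raise ValueError(f"period {period!r} has no cytokine")


@dataclass(frozen=True)
class UnitProfile:
    """Planted parameters of one simulated CAP unit.

    ``baseline_rate`` is the session-averaged baseline rate; inside
    respiratory bursts the instantaneous rate is multiplied by
    ``burst_gain`` and outside by the complementary factor that keeps the
    time average equal to ``baseline_rate``. ``response_c1``/``response_c2``
    are signed fractional rate changes applied after each injection.
    """

    baseline_rate: float
    burst_gain: float
    response_c1: float
    response_c2: float
    template_id: int

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.burst_gain < 1:
            raise ValueError("burst_gain must be >= 1")
        for c in (self.response_c1, self.response_c2):
            if c <= -1:
                raise ValueError("responses must be > -1 (rates stay nonnegative)")

    @property
    def category(self) -> str:
        """Planted response category from the signs of the two responses."""
        s1, s2 = np.sign(self.response_c1), np.sign(self.response_c2)
        if s1 > 0 and s2 > 0:
            return "increasing"
        if s1 < 0 and s2 < 0:
            return "decreasing"
        return "mixed"


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cohort.

    ``unit_profiles`` is a flat tuple over all units of the cohort; units
    belong to mice according to ``units_per_mouse`` (first mouse gets the
    first ``units_per_mouse[0]`` profiles, and so on).
    """

    group_label: str
    n_mice: int
    units_per_mouse: tuple[int, ...]
    unit_profiles: tuple[UnitProfile, ...]
    resp_burst_duration_ms: tuple[float, float] = (133.73, 10.0)  # mean, SD
    resp_burst_period_ms: tuple[float, float] = (649.75, 60.0)
    cardiac_rate_hz: float = 10.0
    noise_sd_base_uv: float = 2.0
    noise_burst_multiplier: float = 3.0
    ecg_noise_sd_uv: float = 5.0
    fs: float = 32000.0
    session_plan: SessionPlan = field(default_factory=SessionPlan)
    #: Gamma shape of the mean-one per-second rate jitter (SD = k**-0.5).
    rate_jitter_shape: float = 4.0
    #: 0 = instantaneous step at injection; >0 = linear ramp over N minutes.
    response_ramp_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in ("CON", "LS"):
            raise ValueError("group_label must be 'CON' or 'LS'")
        if self.n_mice < 1 or len(self.units_per_mouse) != self.n_mice:
            raise ValueError("units_per_mouse must have one entry per mouse")
        if sum(self.units_per_mouse) != len(self.unit_profiles):
            raise ValueError("unit_profiles length must equal sum(units_per_mouse)")
        dur, per = self.resp_burst_duration_ms[0], self.resp_burst_period_ms[0]
        if not (0 < dur < per):
            raise ValueError("burst duration must be positive and shorter than the period")
        if self.noise_burst_multiplier < 1:
            raise ValueError("noise_burst_multiplier must be >= 1")
        if self.noise_sd_base_uv < 0 or self.ecg_noise_sd_uv < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.cardiac_rate_hz < 0:
            raise ValueError("cardiac_rate_hz must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rate_jitter_shape <= 0:
            raise ValueError("rate_jitter_shape must be positive")

    def profiles_of_mouse(self, mouse_index: int) -> tuple[UnitProfile, ...]:
        if not 0 <= mouse_index < self.n_mice:
            raise ValueError(f"mouse_index {mouse_index} out of range (n_mice={self.n_mice})")
        start = sum(self.units_per_mouse[:mouse_index])
        return self.unit_profiles[start:start + self.units_per_mouse[mouse_index]]

    def plan_of_mouse(self, mouse_index: int) -> SessionPlan:
        """Session plan with the counterbalanced cytokine order for one mouse."""
        order = CYTOKINES if mouse_index % 2 == 0 else CYTOKINES[::-1]
        p = self.session_plan
        return SessionPlan(p.bl_min, p.injection_min, p.total_min, order)


@dataclass
class GroundTruth:
    """Planted truth for one simulated mouse (for recovery testing)."""

    spike_times: dict[int, np.ndarray]           # unit_id -> times (s)
    categories: dict[int, str]                   # unit_id -> category
    baseline_rates: dict[int, float]             # unit_id -> planted CAPs/s
    f_bl: float                                  # planted per-mouse summed rates
    f_c1: float
    f_c2: float
    burst_intervals: np.ndarray                  # (n, 2) start/end s
    cardiac_times: np.ndarray                    # (n,) s


@dataclass
class RecordingBundle:
    """Two-channel continuous recording plus events and metadata."""

    vagus_signal: np.ndarray
    ecg_signal: np.ndarray
    fs: float
    events: list[tuple[str, float]]
    group: str
    mouse_id: str

    def __post_init__(self) -> None:
        if len(self.vagus_signal) != len(self.ecg_signal):
            raise ValueError("vagus and ECG channels must have the same length")
        dur = self.duration_s
        for label, t in self.events:
            if not 0 < t < dur:
                raise ValueError(f"event {label!r} at {t} s lies outside the session")

    @property
    def duration_s(self) -> float:
        return len(self.vagus_signal) / self.fs


class BurstIntervals:
    """Sorted, non-overlapping half-open respiratory-burst windows (seconds)."""

    def __init__(self, intervals: Sequence[Sequence[float]] | np.ndarray):
        arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
        if arr.size:
            if np.any(arr[:, 1] <= arr[:, 0]):
                raise ValueError("burst intervals must satisfy end > start")
            if np.any(np.diff(arr[:, 0]) < 0) or np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError("burst intervals must be sorted and non-overlapping")
        self.array = arr

    def __len__(self) -> int:
        return len(self.array)

    def __iter__(self):
        return iter(self.array)

    @property
    def starts(self) -> np.ndarray:
        return self.array[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.array[:, 1]

    def total_time(self) -> float:
        return float(np.sum(self.array[:, 1] - self.array[:, 0]))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside any burst."""
        times = np.asarray(times, dtype=float)
        if not len(self.array):
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(times.shape, dtype=bool)
        inside[ok] = times[ok] < self.ends[idx[ok]]
        return inside

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Boolean per-sample mask of burst membership."""
        mask = np.zeros(n_samples, dtype=bool)
        for s, e in self.array:
            i0 = max(0, int(np.ceil(s * fs)))
            i1 = min(n_samples, int(np.ceil(e * fs)))
            if i1 > i0:
                mask[i0:i1] = True
        return mask


@dataclass
class SpikeEvents:
    """Detected threshold-crossing events with aligned waveform snippets."""

    times: np.ndarray        # (n,) s, at the extremum sample
    snippets: np.ndarray     # (n, snippet_len) uV
    polarities: np.ndarray   # (n,) sign of the detected extremum
    fs: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if self.snippets.shape[0] != n or len(self.polarities) != n:
            raise ValueError("times, snippets and polarities must align")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class UnitCluster:
    """One sorted CAP unit."""

    unit_id: int
    spike_times: np.ndarray
    mean_waveform: np.ndarray
    waveform_sem: np.ndarray
    peak_to_peak_amplitude: float
    half_height_width_ms: float
    cardiac_flag: bool
    fs: float
    #: detection artifact (e.g. filter-ringing shadow of a larger cluster);
    #: retained in output but excluded from firing analysis like cardiac
    artifact_flag: bool = False

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def include_in_analysis(self) -> bool:
        return not (self.cardiac_flag or self.artifact_flag)


@dataclass
class RateSeries:
    """Binned firing rates of one unit with period labels per bin."""

    unit_id: int
    bin_edges: np.ndarray     # (n+1,) s, uniform
    rates: np.ndarray         # (n,) CAPs/s
    period_labels: np.ndarray  # (n,) 'BL'/'C1'/'C2'
    plan: SessionPlan

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.rates) + 1:
            raise ValueError("bin_edges must have len(rates)+1 entries")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class CytokineSummary:
    """Per-mouse summed rates (last 10 min of each period) and cytokine ratios."""

    mouse_id: str
    f_bl: float
    f_tnf: float
    f_il1: float
    ratio_tnf: float | None
    ratio_il1: float | None


@dataclass
class UnitCategory:
    unit_id: int
    category: str            # 'increasing' / 'decreasing' / 'mixed'
    delta_c1: float
    delta_c2: float


@dataclass
class PeriEventHistogram:
    """Burst-onset-aligned summed CAP counts."""

    lag_edges_ms: np.ndarray
    counts: np.ndarray
    burst_duration_ms: float

    @property
    def lag_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.lag_edges_ms[:-1] + self.lag_edges_ms[1:])


@dataclass
class FeatureSeries:
    """Per-second smoothed rate features with true class labels."""

    timepoints: np.ndarray    # (n,) s
    features: np.ndarray      # (n, n_units) CAPs/s
    labels: np.ndarray        # (n,) 'BL'/'C1'/'C2'
    unit_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.features.shape != (len(self.timepoints), len(self.unit_ids)):
            raise ValueError("features must be (n_timepoints, n_units)")
        if len(self.labels) != len(self.timepoints):
            raise ValueError("labels must align with timepoints")


@dataclass
class DecoderModel:
    """Gaussian naive Bayes parameters per class."""

    classes: tuple[str, ...]
    means: np.ndarray         # (n_classes, n_features)
    variances: np.ndarray     # (n_classes, n_features), floored > 0
    priors: np.ndarray        # (n_classes,) sums to 1

    def __post_init__(self) -> None:
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")


@dataclass
class DecodeResult:
    """Per-timepoint posteriors and per-class summary for one mouse."""

    timepoints: np.ndarray
    posteriors: np.ndarray        # (n, 3), rows sum to 1
    decoded: np.ndarray           # (n,) class labels
    truth: np.ndarray             # (n,) class labels
    classes: tuple[str, ...]
    class_correct_prob: dict[str, float]   # mean posterior on the true class
    class_accuracy: dict[str, float]       # hard argmax accuracy per class
    confusion: np.ndarray         # (3, 3) rows = truth, cols = decoded

    @property
    def mean_correct_prob(self) -> float:
        return float(np.mean(list(self.class_correct_prob.values())))
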