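"""Reading and writing of pipeline artifacts (HDF5 recordings, CSV tables)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import DecodeResult, GroundTruth, RecordingBundle, SpikeEvents, UnitCluster

__all__ = [
    "write_recording",
    "read_recording",
    "write_ground_truth",
    "write_spikes",
    "read_spikes",
    "write_units",
    "write_decode_result",
]


def write_recording(path: str | Path, bundle: RecordingBundle) -> None:
    """Recording as HDF5: /vagus, /ecg (float32 uV), /events, fs + metadata attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("vagus", data=np.asarray(bundle.vagus_signal, dtype=np.float32))
        f.create_dataset("ecg", data=np.asarray(bundle.ecg_signal, dtype=np.float32))
        f.attrs["fs"] = bundle.fs
        f.attrs["group"] = bundle.group
        f.attrs["mouse_id"] = bundle.mouse_id
        ev = f.create_group("events")
        ev.create_dataset("label", data=np.array([e[0] for e in bundle.events], dtype="S8"))
        ev.create_dataset("time_s", data=np.array([e[1] for e in bundle.events]))


def read_recording(path: str | Path) -> RecordingBundle:
    with h5py.File(path, "r") as f:
        events = [
            (lbl.decode(), float(t))
            for lbl, t in zip(f["events/label"][()], f["events/time_s"][()])
        ]
        return RecordingBundle(
            vagus_signal=f["vagus"][()],
            ecg_signal=f["ecg"][()],
            fs=float(f.attrs["fs"]),
            events=events,
            group=str(f.attrs["group"]),
            mouse_id=str(f.attrs["mouse_id"]),
        )


def write_ground_truth(out_dir: str | Path, truth: GroundTruth) -> None:
    """Truth tables as CSV: spikes.csv (unit_id, time_s) and units.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {"unit_id": uid, "time_s": t}
        for uid, times in truth.spike_times.items()
        for t in times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        out_dir / "spikes.csv", index=False
    )
    pd.DataFrame(
        {
            "unit_id": list(truth.categories),
            "category": list(truth.categories.values()),
            "baseline_rate": [truth.baseline_rates[u] for u in truth.categories],
        }
    ).to_csv(out_dir / "units.csv", index=False)
    pd.DataFrame(truth.burst_intervals, columns=["start_s", "end_s"]).to_csv(
        out_dir / "bursts.csv", index=False
    )


def write_spikes(out_dir: str | Path, spikes: SpikeEvents) -> None:
    """Detected events as CSV (time_s, polarity) plus a snippet matrix in HDF5."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": spikes.times, "polarity": spikes.polarities}).to_csv(
        out_dir / "spike_events.csv", index=False
    )
    with h5py.File(out_dir / "snippets.h5", "w") as f:
        f.create_dataset("snippets", data=spikes.snippets.astype(np.float32))
        f.attrs["fs"] = spikes.fs


def read_spikes(out_dir: str | Path) -> SpikeEvents:
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "spike_events.csv")
    with h5py.File(out_dir / "snippets.h5", "r") as f:
        snippets = f["snippets"][()].astype(np.float64)
        fs = float(f.attrs["fs"])
    return SpikeEvents(
        times=df["time_s"].to_numpy(),
        snippets=snippets,
        polarities=df["polarity"].to_numpy(),
        fs=fs,
    )


def write_units(out_dir: str | Path, clusters: list[UnitCluster]) -> None:
    """units.csv summary plus mean waveforms in HDF5."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "n_spikes": c.n_spikes,
                "amplitude_uV": c.peak_to_peak_amplitude,
                "width_ms": c.half_height_width_ms,
                "cardiac_flag": c.cardiac_flag,
            }
            for c in clusters
        ]
    ).to_csv(out_dir / "units.csv", index=False)
    rows = [
        {"unit_id": c.unit_id, "time_s": t} for c in clusters for t in c.spike_times
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        out_dir / "spike_assignments.csv", index=False
    )
    with h5py.File(out_dir / "mean_waveforms.h5", "w") as f:
        for c in clusters:
            g = f.create_group(f"unit_{c.unit_id}")
            g.create_dataset("mean", data=c.mean_waveform)
            g.create_dataset("sem", data=c.waveform_sem)
            g.attrs["fs"] = c.fs


def write_decode_result(out_dir: str | Path, result: DecodeResult) -> None:
    """decoder_posteriors.csv and decoder_summary.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(result.posteriors, columns=[f"p_{c}" for c in result.classes])
    df.insert(0, "t_s", result.timepoints)
    df["decoded"] = result.decoded
    df["truth"] = result.truth
    df.to_csv(out_dir / "decoder_posteriors.csv", index=False)
    summary = {
        "class_correct_prob": result.class_correct_prob,
        "class_accuracy": result.class_accuracy,
        "confusion": result.confusion.tolist(),
        "classes": list(result.classes),
    }
    (out_dir / "decoder_summary.json").write_text(json.dumps(summary, indent=2))
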