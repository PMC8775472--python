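"""Readers and writers for the formats used across the pipeline.

Hypnograms travel as two-column CSV (epoch_index, stage); cohorts get a
manifest CSV (subject_id, group, paths, seed); recordings are persisted as
NPZ arrays with a JSON sidecar (rate, channel order, processing log).
EDF/EDF+ reading is available through mne when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError
from .types import EEGRecording, Hypnogram

__all__ = ["write_hypnogram_csv", "read_hypnogram_csv", "save_recording",
           "load_recording", "write_cohort", "read_edf"]


def write_hypnogram_csv(h: Hypnogram, path) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(h)),
                  "stage": h.labels}).to_csv(path, index=False)


def read_hypnogram_csv(path, epoch_s: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path)
    if not {"epoch_index", "stage"} <= set(df.columns):
        raise DataError(f"{path}: expected columns epoch_index, stage")
    df = df.sort_values("epoch_index")
    return Hypnogram.from_labels(df["stage"].tolist(), epoch_s=epoch_s)


def save_recording(rec: EEGRecording, path) -> None:
    """NPZ payload + '<path>.json' sidecar with rate/channels/metadata."""
    path = Path(path)
    np.savez_compressed(path, data=rec.data)
    sidecar = {
        "rate": rec.rate, "channels": rec.channels,
        "lights_off_s": rec.lights_off_s, "subject_id": rec.subject_id,
        "group": rec.group, "meta": rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1, default=str))


def load_recording(path) -> EEGRecording:
    path = Path(path)
    data = np.load(path)["data"]
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return EEGRecording(data=data, channels=side["channels"],
                        rate=side["rate"],
                        lights_off_s=side.get("lights_off_s", 0.0),
                        subject_id=side.get("subject_id", ""),
                        group=side.get("group", "unknown"),
                        meta=side.get("meta", {}))


def write_cohort(cohort, out_dir) -> Path:
    """Write hypnograms (+ recordings when present) and a manifest CSV.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        for night, (h, r) in enumerate(zip(rec.hypnograms, rec.recordings),
                                       start=1):
            stem = f"{rec.subject_id}_n{night}"
            hpath = out_dir / f"{stem}_hypnogram.csv"
            write_hypnogram_csv(h, hpath)
            rpath = ""
            if r is not None:
                rpath = out_dir / f"{stem}_eeg.npz"
                save_recording(r, rpath)
            rows.append({"subject_id": rec.subject_id, "group": rec.group,
                         "night": night, "hypnogram": hpath.name,
                         "recording": Path(rpath).name if rpath else "",
                         "seed": rec.seed})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_edf(path, channels=None) -> EEGRecording:
    """Read an EDF/EDF+ file into an EEGRecording (requires mne)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "EDF reading needs the optional dependency mne "
            "(pip install somnostage[edf])") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels:
        raw = raw.pick(channels)
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data=data, channels=list(raw.ch_names),
                        rate=float(raw.info["sfreq"]),
                        meta={"source": str(path)})
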