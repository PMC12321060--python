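"""Recording container and on-disk cohort formats.

A cohort on disk is a directory with one delimited matrix per
subject-condition recording (channels × samples, tab-separated, no
header) plus a JSON sidecar per recording (channels, sampling rate) and a
``manifest.json`` tying subjects, conditions, VAS-F scores and file paths
together. EDF/EDF+ input is supported through MNE when reading individual
recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "FileCohort",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_cohort",
    "write_matrix",
    "read_matrix",
]

CONDITIONS = ("pre", "post")


@dataclass
class Recording:
    """One subject-condition multichannel EEG record."""

    channels: tuple[str, ...]
    fs: float
    data: np.ndarray  # (n_channels, n_samples)
    subject: int | str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def write_recording(rec: Recording, path: Path | str) -> Path:
    """Write one recording as a TSV matrix plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter="\t", fmt="%.10g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "channels": list(rec.channels),
        "fs": rec.fs,
        "subject": rec.subject,
        "condition": rec.condition,
    }))
    return path


def read_recording(path: Path | str, channels=None, fs=None) -> Recording:
    """Read a recording from EDF/EDF+ (via MNE) or delimited text.

    For delimited text the JSON sidecar written by :func:`write_recording`
    supplies channel labels and sampling rate unless given explicitly.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(channels=tuple(raw.ch_names), fs=float(raw.info["sfreq"]),
                         data=raw.get_data())
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    channels = tuple(channels or meta.get("channels") or ())
    fs = fs or meta.get("fs")
    if not channels or fs is None:
        raise ValueError(f"no channel/fs metadata for {path}")
    return Recording(channels=channels, fs=float(fs), data=data,
                     subject=meta.get("subject"), condition=meta.get("condition"))


@dataclass
class FileCohort:
    """Cohort backed by files on disk; recordings load lazily."""

    root: Path
    subjects: list
    conditions: tuple[str, ...]
    vasf: pd.DataFrame
    paths: dict = field(default_factory=dict)  # (subject, condition) -> filename
    truth: dict | None = None

    def recording(self, subject, condition) -> Recording:
        key = (subject, condition)
        if key not in self.paths:
            raise KeyError(f"no recording for subject {subject!r}, {condition!r}")
        return read_recording(self.root / self.paths[key])

    def iter_recordings(self):
        for subject in self.subjects:
            for condition in self.conditions:
                yield (subject, condition), self.recording(subject, condition)


def write_cohort(cohort, out_dir: Path | str) -> Path:
    """Write every recording plus a manifest; returns the manifest path.

    ``cohort`` is anything exposing ``subjects``, ``conditions``,
    ``recording(subject, condition)`` and a ``vasf`` frame (and optionally
    a ``truth`` dict of generator parameters).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for subject in cohort.subjects:
        for condition in cohort.conditions:
            rec = cohort.recording(subject, condition)
            name = f"sub-{subject}_{condition}.tsv"
            write_recording(rec, out_dir / name)
            paths[f"{subject}|{condition}"] = name
    manifest = {
        "subjects": list(cohort.subjects),
        "conditions": list(cohort.conditions),
        "recordings": paths,
        "vasf": cohort.vasf.to_dict(orient="records"),
        "truth": getattr(cohort, "truth", None),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(manifest_path: Path | str) -> FileCohort:
    """Load a cohort manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    obj = json.loads(manifest_path.read_text())
    paths = {}
    for key, name in obj["recordings"].items():
        subject, condition = key.rsplit("|", 1)
        try:
            subject = int(subject)
        except ValueError:
            pass
        paths[(subject, condition)] = name
    return FileCohort(
        root=manifest_path.parent,
        subjects=obj["subjects"],
        conditions=tuple(obj["conditions"]),
        vasf=pd.DataFrame(obj["vasf"]),
        paths=paths,
        truth=obj.get("truth"),
    )


def write_matrix(weights: np.ndarray, channels, path: Path | str) -> Path:
    """Square delimited matrix with a channel-label header row and column."""
    path = Path(path)
    df = pd.DataFrame(weights, index=list(channels), columns=list(channels))
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_matrix(path: Path | str) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"matrix at {path} is not square-labelled")
    return df.to_numpy(dtype=float), tuple(df.columns)
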