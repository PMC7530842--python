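"""Session file format, run configuration, and output manifests.

A session is a CSV with header ``trial,t,target_x,target_y,cursor_x,
cursor_y,force`` (t in seconds, positions in cm, force in device units;
cursor/force cells may be empty throughout for target-only files) plus a
JSON sidecar ``<name>.meta.json`` carrying subject id, group label, sampling
rate, seed, an echo of the simulation profile, and a format version.
Floats are serialized with 9 significant digits, '.' decimal, UTF-8.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import FilterSpec
from .paths import PathConfig
from .subjects import SessionData, SubjectProfile, Trial

__all__ = [
    "SessionFormatError",
    "FORMAT_VERSION",
    "write_session",
    "read_session",
    "RunConfig",
    "config_hash",
    "write_manifest",
]

FORMAT_VERSION = "1"
COLUMNS = ["trial", "t", "target_x", "target_y", "cursor_x", "cursor_y", "force"]


class SessionFormatError(ValueError):
    """Raised when a session file violates the format contract."""


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_session(session: SessionData, csv_path) -> Path:
    """Write a session to CSV + JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    rows = []
    for trial in session.trials:
        n = len(trial.t)
        rows.append(
            pd.DataFrame(
                {
                    "trial": trial.trial_id,
                    "t": trial.t,
                    "target_x": trial.target[:, 0],
                    "target_y": trial.target[:, 1],
                    "cursor_x": trial.cursor[:, 0] if trial.cursor is not None else [""] * n,
                    "cursor_y": trial.cursor[:, 1] if trial.cursor is not None else [""] * n,
                    "force": trial.force if trial.force is not None else [""] * n,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "format_version": FORMAT_VERSION,
        "subject_id": session.subject_id,
        "group_label": session.group_label,
        "sampling_rate": session.sampling_rate,
        "seed": session.seed,
        "profile": asdict(session.profile) if session.profile is not None else None,
    }
    _meta_path(csv_path).write_text(json.dumps(meta, indent=2))
    return csv_path


def _column(frame: pd.DataFrame, name: str, rows: np.ndarray, csv_path: Path):
    """Extract an optional float column: all-empty -> None, partial -> error."""
    col = pd.to_numeric(frame.loc[rows, name], errors="coerce")
    na = col.isna()
    if na.all():
        return None
    if na.any():
        line = int(col.index[na][0]) + 2  # +1 header, +1 one-based
        raise SessionFormatError(f"{csv_path}: line {line}: missing {name} value")
    return col.to_numpy(dtype=float)


def read_session(csv_path) -> SessionData:
    """Read and validate a session file; errors carry 1-based line numbers."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    meta_path = _meta_path(csv_path)
    if not meta_path.exists():
        raise SessionFormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "format_version" not in meta:
        raise SessionFormatError(f"{meta_path}: format_version missing")
    frame = pd.read_csv(csv_path)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SessionFormatError(f"{csv_path}: missing columns {missing}")

    trial_ids = frame["trial"].to_numpy()
    seen: list[int] = []
    for i, tid in enumerate(trial_ids):
        if not seen or tid != seen[-1]:
            if tid in seen:
                raise SessionFormatError(
                    f"{csv_path}: line {i + 2}: trial {tid} block out of order "
                    "(trial rows must be contiguous)"
                )
            seen.append(tid)

    fs = float(meta["sampling_rate"])
    trials = []
    dts = []
    for tid in seen:
        rows = np.flatnonzero(trial_ids == tid)
        t = frame.loc[rows, "t"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if dt.min() <= 0:
                line = int(rows[int(np.argmin(dt)) + 1]) + 2
                raise SessionFormatError(
                    f"{csv_path}: line {line}: non-monotone time within trial {tid}"
                )
            if np.ptp(dt) > 1e-9:
                line = int(rows[int(np.argmax(np.abs(dt - dt[0]))) + 1]) + 2
                raise SessionFormatError(
                    f"{csv_path}: line {line}: non-uniform sampling interval in trial {tid}"
                )
            dts.append(dt[0])
        target = np.column_stack(
            [
                frame.loc[rows, "target_x"].to_numpy(dtype=float),
                frame.loc[rows, "target_y"].to_numpy(dtype=float),
            ]
        )
        cx = _column(frame, "cursor_x", rows, csv_path)
        cy = _column(frame, "cursor_y", rows, csv_path)
        if (cx is None) != (cy is None):
            raise SessionFormatError(f"{csv_path}: cursor_x/cursor_y presence mismatch in trial {tid}")
        cursor = np.column_stack([cx, cy]) if cx is not None else None
        force = _column(frame, "force", rows, csv_path)
        trials.append(Trial(int(tid), t, target, cursor, force))
    if dts and np.ptp(dts) > 1e-9:
        raise SessionFormatError(f"{csv_path}: mixed sampling rates across trials")
    if dts and abs(1.0 / np.mean(dts) - fs) > 1e-6 * fs:
        raise SessionFormatError(
            f"{csv_path}: sampling rate in data ({1.0 / np.mean(dts):.6g} Hz) "
            f"disagrees with metadata ({fs} Hz)"
        )
    profile = SubjectProfile(**meta["profile"]) if meta.get("profile") else None
    return SessionData(
        subject_id=str(meta["subject_id"]),
        group_label=str(meta["group_label"]),
        sampling_rate=fs,
        trials=trials,
        profile=profile,
        seed=meta.get("seed"),
    )


@dataclass(frozen=True)
class RunConfig:
    """Whole-pipeline configuration; round-trips losslessly through YAML."""

    path: PathConfig = field(default_factory=PathConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    n_iter: int = 100
    C: float = 1.0
    subsample_factor: float | None = None
    averaging: str = "raw"
    n_boot: int = 100
    excursion_mode: str = "position"
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "path" in d and isinstance(d["path"], dict):
            p = dict(d["path"])
            for key in ("radius_range", "curvature_range", "screen_size"):
                if key in p and p[key] is not None:
                    p[key] = tuple(p[key])
            d["path"] = PathConfig(**p)
        if "filter" in d and isinstance(d["filter"], dict):
            f = dict(d["filter"])
            for key in ("tremor_band", "tremor_design_corners"):
                if key in f:
                    f[key] = tuple(f[key])
            d["filter"] = FilterSpec(**f)
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(_tuples_to_lists(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


def _tuples_to_lists(obj):
    if isinstance(obj, dict):
        return {k: _tuples_to_lists(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_tuples_to_lists(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration."""
    canon = json.dumps(_tuples_to_lists(config.to_dict()), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(directory, files, config: RunConfig | None = None, seed: int | None = None) -> Path:
    """Manifest JSON naming every output with its sha256, config hash, seed."""
    directory = Path(directory)
    entries = []
    for f in sorted(Path(p) for p in files):
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        entries.append({"file": f.name, "sha256": digest})
    doc = {
        "format_version": FORMAT_VERSION,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "outputs": entries,
    }
    out = directory / "manifest.json"
    out.write_text(json.dumps(doc, indent=2))
    return out
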