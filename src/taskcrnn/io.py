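"""Shared I/O: NIfTI runs, event files, HDF5 sample containers, configs.

On-disk conventions
-------------------
* Volumes: NIfTI-1, ``.nii`` or ``.nii.gz``, axis order (X, Y, Z, T), the
  TR stored in the header's time-axis zoom.  float32 is the canonical
  precision throughout.
* Timing: three-column tab-delimited event files (onset_s, duration_s,
  label), one file per run — the EV convention.
* Samples: one HDF5 container per split with datasets ``X``
  ``[N, T, X', Y', Z', 1]`` float32, ``y`` ``[N]`` int8, ``subject`` ``[N]``
  strings, plus a JSON provenance manifest next to it.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from taskcrnn.errors import ConfigError, DataError
from taskcrnn.preprocess import RawRun, Sample, TaskConditionSpec, TASK_NAMES
from taskcrnn.training import SampleSet

NIFTI_SUFFIXES = (".nii", ".nii.gz")


def read_nifti(path, subject_id: str = "", tr_s: float | None = None) -> RawRun:
    """Load a rank-4 NIfTI run; the TR defaults to the header time zoom."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed header / unreadable
        raise DataError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise DataError(f"{path}: expected a rank-4 (X,Y,Z,T) image, got rank {data.ndim}")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.72
    return RawRun(data=data, tr_s=tr_s, subject_id=subject_id, affine=np.asarray(img.affine))


def write_nifti(run: RawRun, path) -> None:
    """Write a run as NIfTI-1 float32 with the TR in the header."""
    path = Path(path)
    affine = run.affine if run.affine is not None else np.eye(4)
    img = nib.Nifti1Image(run.data.astype(np.float32), affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def read_events(path) -> list[tuple[float, float, str]]:
    """Parse a (onset_s, duration_s, label) event file; tab or space delimited."""
    rows = []
    path = Path(path)
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise DataError(f"{path}:{ln}: expected 'onset duration label', got {line!r}")
        try:
            onset, duration = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise DataError(f"{path}:{ln}: non-numeric onset/duration in {line!r}") from exc
        rows.append((onset, duration, parts[2]))
    if not rows:
        raise DataError(f"{path}: no events found")
    return rows


def write_events(spec: TaskConditionSpec, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [
        f"{onset:g}\t{spec.condition_duration_s:g}\t{spec.condition_label}"
        for onset in spec.onsets_s
    ]
    path.write_text("\n".join(lines) + "\n")


def events_to_spec(rows, task_name: str, condition_label: str | None = None) -> TaskConditionSpec:
    """Collect the rows of one condition into a TaskConditionSpec.

    With ``condition_label`` omitted, the file must contain exactly one label.
    """
    labels = sorted({r[2] for r in rows})
    if condition_label is None:
        if len(labels) != 1:
            raise DataError(f"event file has several conditions {labels}; pick one")
        condition_label = labels[0]
    sel = [r for r in rows if r[2] == condition_label]
    if not sel:
        raise DataError(f"condition {condition_label!r} not present (found {labels})")
    durations = {r[1] for r in sel}
    if len(durations) != 1:
        raise DataError(f"condition {condition_label!r} has varying durations {sorted(durations)}")
    return TaskConditionSpec(
        task_name=task_name,
        condition_label=condition_label,
        condition_duration_s=sel[0][1],
        onsets_s=tuple(r[0] for r in sel),
    )


def run_basename(subject_id: str, task_name: str) -> str:
    return f"{subject_id}_task-{task_name}"


def write_run_with_events(sim_run, out_dir) -> tuple[Path, Path]:
    """Write one simulated run as NIfTI + its event file."""
    out_dir = Path(out_dir)
    base = run_basename(sim_run.run.subject_id, sim_run.task.task_name)
    nii = out_dir / f"{base}_bold.nii.gz"
    ev = out_dir / f"{base}_events.tsv"
    write_nifti(sim_run.run, nii)
    write_events(sim_run.task, ev)
    return nii, ev


def save_samples(path, samples_or_set, manifest: dict | None = None) -> None:
    """Write a sample container (HDF5) and an optional JSON manifest."""
    if isinstance(samples_or_set, SampleSet):
        data = samples_or_set
    else:
        data = SampleSet.from_samples(list(samples_or_set))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X.astype(np.float32), compression="gzip")
        f.create_dataset("y", data=data.y.astype(np.int8))
        f.create_dataset(
            "subject", data=np.array(data.subjects, dtype=h5py.string_dtype("utf-8"))
        )
    if manifest is not None:
        write_manifest(path.with_suffix(".manifest.json"), manifest)


def load_samples(path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            X=f["X"][...],
            y=f["y"][...].astype(np.int64),
            subjects=np.array([s.decode() if isinstance(s, bytes) else s for s in f["subject"][...]]),
        )


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path, manifest: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def merge_config(defaults: dict, file_cfg: dict | None, flags: dict | None) -> dict:
    """Layer configuration: defaults < file < command-line flags.

    Unknown keys (at any level present in the defaults) are rejected with
    the nearest valid key suggested.  ``None``-valued flags are treated as
    "not given".
    """
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in defaults.items()}

    def apply(layer: dict, target: dict, prefix: str = "") -> None:
        for key, value in layer.items():
            if key not in target:
                close = difflib.get_close_matches(key, target.keys(), n=1)
                hint = f"; did you mean {close[0]!r}?" if close else ""
                raise ConfigError(f"unknown config key {prefix}{key!r}{hint}")
            if isinstance(target[key], dict) and isinstance(value, dict):
                apply(value, target[key], prefix=f"{prefix}{key}.")
            elif value is not None:
                expected = target[key]
                if expected is not None and not isinstance(value, type(expected)) and not (
                    isinstance(expected, float) and isinstance(value, int)
                ):
                    raise ConfigError(
                        f"config key {prefix}{key!r}: expected "
                        f"{type(expected).__name__}, got {type(value).__name__}"
                    )
                target[key] = value

    if file_cfg:
        apply(file_cfg, merged)
    if flags:
        apply(flags, merged)
    return merged


def load_config_file(path) -> dict:
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config file {path} must hold a mapping")
    return cfg
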