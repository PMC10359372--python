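"""Readers and writers for the pipeline's on-disk formats.

All tabular files are UTF-8, tab-separated (CSV for the clinical table),
Unix newlines, ``n/a`` for missing values; floats are written with 6
significant digits and round-trip bit-exactly at that precision.  The events
file follows the BIDS events convention (columns onset, duration,
trial_type).  Writers are atomic: output goes to a ``.partial`` file that is
renamed into place only on success.
"""

from __future__ import annotations

import json
import os
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigm import BlockSpec, Condition
from .rt_engine import FeedbackSample

__all__ = [
    "FormatError",
    "atomic_write",
    "write_events",
    "read_events",
    "write_series",
    "read_series",
    "write_feedback_log",
    "write_clinical",
    "read_clinical",
    "write_manifest",
    "read_manifest",
    "write_json",
]

FLOAT_FMT = "%.6g"
NA = "n/a"


class FormatError(ValueError):
    """Malformed input file (message carries the path and row when known)."""


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


@contextmanager
def atomic_write(path: str | Path):
    """Yield a writable file object; rename into place only on success.

    On failure the ``.partial`` file is left behind as the marker of an
    incomplete write.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    partial = path.with_name(path.name + ".partial")
    with open(partial, "w", encoding="utf-8", newline="\n") as fh:
        yield fh
    os.replace(partial, path)


def write_events(path: str | Path, blocks: Iterable[BlockSpec]) -> None:
    """Write a BIDS-style events TSV (onset, duration, trial_type)."""
    with atomic_write(path) as fh:
        fh.write("onset\tduration\ttrial_type\n")
        for b in blocks:
            fh.write(f"{_fmt(b.onset_s)}\t{_fmt(b.duration_s)}\t{b.condition.value}\n")


def read_events(path: str | Path) -> tuple[BlockSpec, ...]:
    """Read and validate an events TSV: known conditions, non-negative onsets,
    chronological order, no overlapping blocks."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError(f"{path}: cannot parse events TSV: {exc}") from exc
    required = ["onset", "duration", "trial_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        import warnings

        warnings.warn(f"{path}: empty events file", stacklevel=2)
        return ()
    blocks: list[BlockSpec] = []
    prev_end = 0.0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            onset = float(row.onset)
            duration = float(row.duration)
        except ValueError as exc:
            raise FormatError(f"{path} row {row_no}: non-numeric onset/duration") from exc
        if row.trial_type not in (Condition.DOWN.value, Condition.UP.value):
            raise FormatError(
                f"{path} row {row_no}: unknown trial_type {row.trial_type!r}"
            )
        if onset < 0:
            raise FormatError(f"{path} row {row_no}: negative onset")
        if blocks and onset < prev_end - 1e-9:
            raise FormatError(f"{path} row {row_no}: overlapping blocks")
        block = BlockSpec(Condition(row.trial_type), onset, duration)
        blocks.append(block)
        prev_end = block.end_s
    return tuple(blocks)


def write_series(
    path: str | Path,
    target: Sequence[float],
    control: Sequence[float],
    tr_s: float = 1.0,
) -> None:
    """Write a two-ROI series TSV (volume, time_s, target, control)."""
    target = np.asarray(target, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(target) != len(control):
        raise ValueError("target and control must have equal length")
    with atomic_write(path) as fh:
        fh.write("volume\ttime_s\ttarget\tcontrol\n")
        for v, (t_val, c_val) in enumerate(zip(target, control)):
            fh.write(f"{v}\t{_fmt(v * tr_s)}\t{_fmt(t_val)}\t{_fmt(c_val)}\n")


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read a two-ROI series TSV; returns (target, control, tr_s).

    TR is inferred from the time_s spacing and validated constant; the
    volume column must be a gap-free 0-based sequence.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=[NA])
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse series TSV: {exc}") from exc
    required = ["volume", "time_s", "target", "control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 volumes")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise FormatError(f"{path} row {bad[0] + 2}: non-numeric {col!r}")
    volumes = df["volume"].to_numpy(dtype=float)
    expected = np.arange(len(df), dtype=float)
    if not np.array_equal(volumes, expected):
        row = int(np.argmax(volumes != expected)) + 2
        raise FormatError(f"{path} row {row}: volume numbering has a gap or offset")
    times = df["time_s"].to_numpy(dtype=float)
    deltas = np.diff(times)
    tr = float(deltas[0])
    if tr <= 0 or not np.allclose(deltas, tr, rtol=0, atol=1e-6):
        row = int(np.argmax(~np.isclose(deltas, tr, rtol=0, atol=1e-6))) + 3
        raise FormatError(f"{path} row {row}: irregular TR spacing")
    return (
        df["target"].to_numpy(dtype=float),
        df["control"].to_numpy(dtype=float),
        tr,
    )


def write_feedback_log(path: str | Path, samples: Iterable[FeedbackSample]) -> None:
    """Write the per-volume online feedback log."""
    with atomic_write(path) as fh:
        fh.write("volume\tpsc_target\tpsc_control\tdiff\tscore\tdisplayed\n")
        for s in samples:
            fh.write(
                f"{s.volume}\t{_fmt(s.psc_target)}\t{_fmt(s.psc_control)}\t"
                f"{_fmt(s.diff)}\t{_fmt(s.score)}\t{str(s.displayed).lower()}\n"
            )


CLINICAL_COLUMNS = ["subject_id", "group", "time", "madrs", "bdi", "zsrds"]


def write_clinical(path: str | Path, table: pd.DataFrame) -> None:
    """Write the clinical score table as CSV."""
    missing = [c for c in CLINICAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    with atomic_write(path) as fh:
        table[CLINICAL_COLUMNS].to_csv(fh, index=False, lineterminator="\n")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical score CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse clinical CSV: {exc}") from exc
    missing = [c for c in CLINICAL_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_time = ~df["time"].isin(["pre", "mid", "post"])
    if bad_time.any():
        row = int(df.index[bad_time][0]) + 2
        raise FormatError(f"{path} row {row}: time must be pre/mid/post")
    multi_group = df.groupby("subject_id")["group"].nunique()
    if (multi_group > 1).any():
        sid = multi_group.index[multi_group > 1][0]
        raise FormatError(f"{path}: subject {sid!r} appears in more than one group")
    dup = df.duplicated(subset=["subject_id", "time"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise FormatError(f"{path} row {row}: duplicate subject x time row")
    return df


MANIFEST_COLUMNS = [
    "subject", "session", "run", "half_session", "is_transfer",
    "events_path", "series_path",
]


def write_manifest(path: str | Path, records: Iterable[dict]) -> None:
    """Write the per-run manifest TSV tying subjects/half-sessions to files."""
    with atomic_write(path) as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    str(rec[c]).lower() if c == "is_transfer" else str(rec[c])
                    for c in MANIFEST_COLUMNS
                )
                + "\n"
            )


def read_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Read the run manifest; optionally verify the referenced files exist."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse manifest: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["is_transfer"] = df["is_transfer"].astype(str).str.lower() == "true"
    if check_paths:
        base = path.parent
        for col in ("events_path", "series_path"):
            for row_no, p in enumerate(df[col], start=2):
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = base / candidate
                if not candidate.exists():
                    raise FormatError(f"{path} row {row_no}: missing file {p}")
    return df


def write_toy_nifti(out_dir: str | Path, target: Sequence[float],
                    control: Sequence[float]) -> dict[str, Path]:
    """Optional NIfTI export for end-to-end I/O testing: a toy 16 x 16 x 4 x T
    volume holding the target series in one embedded ROI and the control
    series in another, plus the two ROI masks (identity affine, voxel space).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    target = np.asarray(target, dtype=np.float32)
    control = np.asarray(control, dtype=np.float32)
    if len(target) != len(control):
        raise ValueError("target and control must have equal length")
    nt = len(target)
    vol = np.zeros((16, 16, 4, nt), dtype=np.float32)
    mask_t = np.zeros((16, 16, 4), dtype=np.uint8)
    mask_c = np.zeros((16, 16, 4), dtype=np.uint8)
    mask_t[4:8, 4:8, 1] = 1
    mask_c[8:14, 2:12, 2] = 1
    vol[mask_t == 1] = target
    vol[mask_c == 1] = control
    paths = {}
    eye = np.eye(4)
    for name, data in (("bold", vol), ("mask_target", mask_t), ("mask_control", mask_c)):
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, eye), p)
        paths[name] = p
    return paths


def read_toy_nifti(out_dir: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a toy NIfTI export: mean series over each ROI mask."""
    import nibabel as nib

    out_dir = Path(out_dir)
    vol = np.asanyarray(nib.load(out_dir / "bold.nii.gz").dataobj)
    out = []
    for name in ("mask_target", "mask_control"):
        mask = np.asanyarray(nib.load(out_dir / f"{name}.nii.gz").dataobj) > 0
        out.append(vol[mask].mean(axis=0))
    return out[0], out[1]


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON writer (sorted keys, fixed layout, trailing newline)."""
    with atomic_write(path) as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
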