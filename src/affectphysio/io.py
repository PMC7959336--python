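"""Readers, writers and run configuration for all on-disk interfaces.

Conventions: TSV (tab-delimited, UTF-8, header row, '.' decimal marks only,
gzip accepted), physio traces as two-column (time_s, value) or value-only
TSV plus a JSON sidecar stating the sampling frequency, volumes as NIfTI-1,
events TSV following the BIDS events layout.  Voxel indices are 0-based;
world coordinates come from the affine; all times are seconds from scan
start.  Every write is atomic (temp file + rename), and analysis outputs can
carry a provenance sidecar (package version, config hash, seed) sufficient
to re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import FIXATION_VOLUMES, TR_S, VIDEO_VOLUMES, Trial, TrialSchedule
from .glm import BoldDataset
from .trace import PhysioTrace

logger = logging.getLogger(__name__)

EVENTS_COLUMNS = ["onset", "duration", "trial_type", "emotion"]


def _atomic_write(path: Path, write_fn) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.stem}.",
                               suffix="".join(path.suffixes))
    os.close(fd)
    try:
        write_fn(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_tsv_bytes(df: pd.DataFrame, path: Path, float_format: str) -> None:
    """Serialize a TSV (optionally gzipped) byte-reproducibly.

    gzip output carries no filename and mtime 0 so identical content gives
    identical bytes on every run.
    """
    payload = df.to_csv(sep="\t", index=False, float_format=float_format).encode()
    if path.suffix == ".gz":
        payload = gzip.compress(payload, mtime=0)
    _atomic_write(path, lambda p: p.write_bytes(payload))


def _strict_float(series: pd.Series, column: str, path) -> np.ndarray:
    try:
        return series.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"{path}: column {column!r} is not parseable as decimal-point "
            f"numbers ({exc})"
        ) from None


def write_events(schedule: TrialSchedule, path: str | Path) -> None:
    """Serialize a schedule as a BIDS-style events TSV (+ JSON sidecar).

    Columns: onset (s, 3 decimals), duration (s), trial_type, emotion.  The
    sidecar records the TR so the volume spans can be reconstructed.
    """
    df = pd.DataFrame({
        "onset": [f"{t.onset_s:.3f}" for t in schedule.trials],
        "duration": [f"{t.duration_s:.6f}" for t in schedule.trials],
        "trial_type": [t.condition for t in schedule.trials],
        "emotion": [t.emotion for t in schedule.trials],
    })
    path = Path(path)
    _atomic_write(path, lambda p: df.to_csv(p, sep="\t", index=False))
    write_json({"tr_s": schedule.tr_s}, path.with_suffix(".json"))


def read_events(path: str | Path) -> TrialSchedule:
    """Read an events TSV back into a TrialSchedule."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required events columns {missing}")
    onsets = _strict_float(df["onset"], "onset", path)
    durations = _strict_float(df["duration"], "duration", path)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: onsets must be strictly increasing")
    tr_s = TR_S
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        tr_s = float(json.loads(sidecar.read_text()).get("tr_s", TR_S))
    trials = []
    for i, row in enumerate(df.itertuples(index=False)):
        cond = row.trial_type
        n_vol = FIXATION_VOLUMES if cond == "fixation" else VIDEO_VOLUMES
        trials.append(Trial(i, cond, row.emotion, float(onsets[i]),
                            float(durations[i]), n_vol))
    return TrialSchedule(trials, tr_s=tr_s)


def write_physio(trace: PhysioTrace, path: str | Path) -> None:
    """Write a physio trace as value-only TSV(.gz) plus a JSON sidecar.

    The sidecar follows the BIDS physio dialect: SamplingFrequency,
    StartTime, Columns, plus the channel name.
    """
    path = Path(path)
    df = pd.DataFrame({"value": trace.samples})
    _write_tsv_bytes(df, path, "%.10g")
    stem = path.name[:-len(".tsv.gz")] if path.name.endswith(".tsv.gz") \
        else path.stem
    write_json({
        "SamplingFrequency": trace.fs_hz,
        "StartTime": trace.start_time_s,
        "Columns": ["value"],
        "Channel": trace.channel,
    }, path.parent / f"{stem}.json")


def read_physio(path: str | Path, channel: str | None = None) -> PhysioTrace:
    """Read a physio TSV (two-column time/value, or value-only + sidecar).

    Gzip-compressed files parse identically to plain ones.  Value-only files
    require a JSON sidecar stating SamplingFrequency.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    stem = path.name[:-len(".tsv.gz")] if path.name.endswith(".tsv.gz") \
        else path.stem
    sidecar = path.parent / f"{stem}.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if channel is None:
        channel = meta.get("Channel", "ppg")
    if "time_s" in df.columns and "value" in df.columns:
        t = _strict_float(df["time_s"], "time_s", path)
        v = _strict_float(df["value"], "value", path)
        dts = np.diff(t)
        if t.size < 2 or np.any(dts <= 0):
            raise ValueError(f"{path}: time_s must be strictly increasing")
        if np.ptp(dts) > 1e-6 * dts.mean():
            raise ValueError(f"{path}: non-uniform sampling in time_s")
        return PhysioTrace(v, 1.0 / float(dts.mean()), channel=channel,
                           start_time_s=float(t[0]))
    if "value" not in df.columns:
        raise ValueError(f"{path}: expected a 'value' column")
    if "SamplingFrequency" not in meta:
        raise ValueError(
            f"{path}: value-only physio needs a JSON sidecar with "
            "SamplingFrequency")
    v = _strict_float(df["value"], "value", path)
    return PhysioTrace(v, float(meta["SamplingFrequency"]), channel=channel,
                       start_time_s=float(meta.get("StartTime", 0.0)))


def write_nifti(bold: BoldDataset, path: str | Path) -> None:
    """Write a BOLD dataset (or a 3-D mask/map via write_nifti_map) atomically."""
    img = nib.Nifti1Image(np.asarray(bold.volumes, dtype=np.float32), bold.affine)
    img.header.set_zooms((*np.abs(np.diag(bold.affine)[:3]), bold.tr_s))
    _atomic_write(Path(path), lambda p: nib.save(img, str(p)))


def write_nifti_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine)
    _atomic_write(Path(path), lambda p: nib.save(img, str(p)))


def read_nifti(path: str | Path, participant_id: str = "") -> BoldDataset:
    """Read a 4-D NIfTI-1 BOLD run (gzip allowed)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] < 2:
        raise ValueError(
            f"{path}: expected 4-D BOLD data, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else TR_S
    return BoldDataset(data.astype(float), tr_s=tr, affine=np.asarray(img.affine),
                       participant_id=participant_id)


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.17g") -> None:
    """Write a TSV table atomically with full-precision floats."""
    _write_tsv_bytes(df, Path(path), float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    _atomic_write(Path(path), lambda p: p.write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n"))


# --------------------------------------------------------------------------
# Run configuration and provenance
# --------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """All analysis parameters with their defaults, serializable to YAML."""

    seed: int = 0
    tr_s: float = TR_S
    cardiac_baseline_window_s: float = 1.0
    cardiac_horizon_s: float = 4.0
    min_ibi_s: float = 0.33
    min_prominence: float = 0.10
    ibi_cv_max: float = 0.25
    pupil_pad_s: float = 0.05
    pupil_min_capture: float = 0.5
    pupil_sd_mult: float = 2.0
    mask_frac: float = 0.1
    majority_frac: float = 0.5
    cdt_p: float = 0.005
    alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 26

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        _atomic_write(Path(path),
                      lambda p: p.write_text(yaml.safe_dump(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def write_provenance(path: str | Path, config: RunConfig) -> None:
    """Provenance sidecar: package version, config hash and seed."""
    from . import __version__

    write_json({
        "package": "affectphysio",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": config.to_dict(),
    }, Path(str(path) + ".prov.json"))
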