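"""Reading, writing and validation of session recordings and result tables.

The on-disk format is deliberately plain: one long-form CSV per continuous
run (one row per sample, metadata repeated in leading columns), a cohort
manifest CSV that maps design cells to files and carries the timing-gate
speed, and headered CSVs for feature and result tables.  Everything is
diff-able and language-neutral.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Metadata columns identifying one recording, in schema order.
METADATA_COLUMNS = ("participant_id", "day", "surface", "run", "calibration")

#: Signal that downstream gait-cycle segmentation cannot work without.
REQUIRED_SIGNALS = ("foot_ap_position",)

#: Columns of the cohort manifest CSV.
MANIFEST_COLUMNS = METADATA_COLUMNS + ("file", "avg_speed_mps")


class SchemaError(ValueError):
    """A file does not conform to the documented CSV schema."""


@dataclass
class SessionRecording:
    """One continuous run: multichannel time series plus identifying metadata.

    Joint angles are stored in degrees throughout; the right-foot
    anterior-posterior position (``foot_ap_position``) is in metres, expressed
    relative to the pelvis.  ``day``, ``run`` and ``calibration`` are 1-based
    protocol labels.
    """

    participant_id: str
    day: int
    surface: str
    run: int
    calibration: int
    sample_rate: float
    time: np.ndarray
    signals: dict[str, np.ndarray]
    avg_speed: float = float("nan")

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.day, self.surface, self.run, self.calibration)

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def validate(self) -> None:
        if self.n_samples < 2:
            raise SchemaError("recording needs at least 2 samples")
        for name, series in self.signals.items():
            if len(series) != self.n_samples:
                raise SchemaError(
                    f"signal {name!r} has {len(series)} samples, time axis has {self.n_samples}"
                )
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise SchemaError("time axis is not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SchemaError("mixed sample rates: time axis is not uniform")
        if self.sample_rate <= 0:
            raise SchemaError("sample_rate must be positive")
        if not np.isclose(1.0 / dt[0], self.sample_rate, rtol=1e-4):
            raise SchemaError(
                f"sample_rate {self.sample_rate} inconsistent with time step {dt[0]:.6g}"
            )


def write_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write one recording as a long-form CSV (one row per sample)."""
    rec.validate()
    path = Path(path)
    data = {
        "participant_id": rec.participant_id,
        "day": rec.day,
        "surface": rec.surface,
        "run": rec.run,
        "calibration": rec.calibration,
        "time_s": rec.time,
    }
    for name, series in rec.signals.items():
        data[name] = series
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_session(path: str | Path, avg_speed: float = float("nan")) -> SessionRecording:
    """Read a long-form session CSV; ``avg_speed`` normally comes from the manifest."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METADATA_COLUMNS + ("time_s",) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in METADATA_COLUMNS:
        if df[col].nunique() != 1:
            raise SchemaError(f"{path.name}: metadata column {col!r} is not constant")
    signal_cols = [c for c in df.columns if c not in METADATA_COLUMNS + ("time_s",)]
    missing_sig = [s for s in REQUIRED_SIGNALS if s not in signal_cols]
    if missing_sig:
        raise SchemaError(f"{path.name}: missing required signal column(s) {missing_sig}")
    time = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(time)
    if len(time) < 2 or np.any(dt <= 0):
        raise SchemaError(f"{path.name}: time_s is not strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise SchemaError(f"{path.name}: mixed sample rates in time_s")
    rec = SessionRecording(
        participant_id=str(df["participant_id"].iloc[0]),
        day=int(df["day"].iloc[0]),
        surface=str(df["surface"].iloc[0]),
        run=int(df["run"].iloc[0]),
        calibration=int(df["calibration"].iloc[0]),
        sample_rate=float(1.0 / dt[0]),
        time=time,
        signals={c: df[c].to_numpy(dtype=float) for c in signal_cols},
        avg_speed=float(avg_speed),
    )
    rec.validate()
    return rec


def session_filename(rec: SessionRecording) -> str:
    return (
        f"{rec.participant_id}_day{rec.day}_{rec.surface}"
        f"_run{rec.run}_cal{rec.calibration}.csv"
    )


def write_cohort(records: Sequence[SessionRecording], directory: str | Path) -> Path:
    """Write all session files plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = session_filename(rec)
        write_session(rec, directory / fname)
        rows.append(
            dict(zip(METADATA_COLUMNS, rec.key)) | {"file": fname, "avg_speed_mps": rec.avg_speed}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SessionRecording]:
    """Read every session listed in a manifest, attaching the timing-gate speed."""
    manifest_path = Path(manifest_path)
    mf = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in mf.columns]
    if missing:
        raise SchemaError(f"manifest missing column(s) {missing}")
    records = []
    for _, row in mf.iterrows():
        rec = read_session(manifest_path.parent / row["file"], avg_speed=row["avg_speed_mps"])
        records.append(rec)
    return records


@dataclass
class CohortReport:
    """Result of :func:`validate_cohort`; report-only, never mutates data."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_cohort(records: Sequence[SessionRecording]) -> CohortReport:
    """Check a cohort for duplicate keys, missing design cells and rate mismatches.

    The expected design is the full cross-product of the level values observed
    in the cohort (participants x days x surfaces x runs x calibrations).
    """
    report = CohortReport()
    keys = [rec.key for rec in records]
    seen: set = set()
    for key in keys:
        if key in seen:
            report.issues.append(f"duplicate recording for {key}")
        seen.add(key)
    rates = {rec.sample_rate for rec in records}
    if len(rates) > 1:
        report.issues.append(f"mixed sample rates across cohort: {sorted(rates)}")
    if records:
        levels = [sorted({k[i] for k in keys}) for i in range(5)]
        import itertools

        for cell in itertools.product(*levels):
            if cell not in seen:
                report.issues.append(
                    "missing design cell "
                    + ", ".join(f"{n}={v}" for n, v in zip(METADATA_COLUMNS, cell))
                )
    return report


# ---------------------------------------------------------------------------
# Feature tables and generic result tables
# ---------------------------------------------------------------------------

#: Key columns of the discrete-feature table (participant ids, 1-based labels).
FEATURE_KEY_COLUMNS = ("participant", "day", "surface", "run", "calibration")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in FEATURE_KEY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing key column(s) {missing}")
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: feature table missing key column(s) {missing}")
    dup = df.duplicated(subset=list(FEATURE_KEY_COLUMNS))
    if dup.any():
        raise SchemaError(f"{Path(path).name}: duplicate feature-table keys")
    return df


def write_truth(truth, path: str | Path) -> Path:
    """Serialize a ``SimulationTruth`` to a JSON sidecar (provenance record)."""
    path = Path(path)

    def _key(k: tuple) -> str:
        return "|".join(str(x) for x in k)

    payload = {
        "config": _jsonable(dataclasses.asdict(truth.config)),
        "participant_ids": list(truth.participant_ids),
        "stride_period_s": {k: float(v) for k, v in truth.stride_period_s.items()},
        "true_speed": {k: float(v) for k, v in truth.true_speed.items()},
        "boundaries_s": {_key(k): [float(t) for t in v] for k, v in truth.boundaries.items()},
        "level_offsets": {
            _key(k): {s: float(o) for s, o in v.items()} for k, v in truth.level_offsets.items()
        },
        "template_features": {k: float(v) for k, v in truth.template_features.items()},
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth(path: str | Path) -> dict:
    """Read a truth sidecar back as a plain dict (for inspection, not round-trip)."""
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def convert_mvnx(path: str | Path):  # pragma: no cover - documented stub
    """Converter stub for the proprietary motion-capture XML export.

    Not implemented: the vendor export is out of scope.  A converter would map,
    per frame, the pelvis-relative right-foot position x-component to
    ``foot_ap_position`` (m) and the ZXY joint-angle channels of the right hip,
    knee and ankle to ``hip_flexion``/``hip_abduction``/``knee_flexion``/
    ``ankle_dorsiflexion``/``ankle_eversion`` (deg), with the frame timestamps
    as ``time_s``, then write the long-form session CSV via
    :func:`write_session`.
    """
    raise NotImplementedError("vendor XML parsing is out of scope; see docstring for the mapping")
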