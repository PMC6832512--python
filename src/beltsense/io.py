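"""Readers/writers for the on-disk formats and the run configuration.

Everything is plain CSV and JSON by design: the data are simple uniform
time series, and inspectability beats binary compactness. Every artifact
carries schema-version metadata (a ``# beltsense-schema: N`` comment line
in CSVs, a ``"schema"`` key in JSON); readers reject newer majors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .activity import EvalReport, ModelConfig
from .intervention import EngineConfig, InterventionEvent
from .posture import PostureRule
from .signals import ImuRecording, SignalSet
from .waistline import BeltConfig, MagnetometerTrace, PeakDetector

__all__ = [
    "SCHEMA_MAJOR",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "read_mag_trace",
    "write_mag_trace",
    "write_signalset",
    "write_eval_report",
    "write_events",
    "read_belt_config",
    "read_posture_rule",
    "read_engine_config",
]

SCHEMA_MAJOR = 1
_CSV_HEADER_LINE = f"# beltsense-schema: {SCHEMA_MAJOR}"

RECORDING_COLUMNS = ["t", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]


class PipelineConfig(BaseModel):
    """Resolved configuration of a full pipeline run.

    Published as a JSON schema via ``PipelineConfig.model_json_schema()``;
    every run should log ``model_dump()`` so results are reproducible.
    """

    sample_rate: float = Field(default=100.0, gt=0)
    window: int = Field(default=128, gt=0)
    overlap: float = Field(default=0.5, ge=0, lt=1)
    n_estimators: int = Field(default=100, gt=0)
    seed: int = 0
    psi_tolerance: float = Field(default=10.0, ge=0)
    phi_min: float = Field(default=80.0, ge=0, le=90)
    phi_max: float = Field(default=90.0, ge=0, le=90)
    belt_length_cm: float = Field(default=110.0, gt=0)
    pitch_cm: float = Field(default=0.6, gt=0)
    offset_cm: float = 0.0
    posture_debounce: float = Field(default=5.0, gt=0)
    sedentary_limit: float = Field(default=30.0, gt=0)
    refractory: float = Field(default=60.0, gt=0)

    def model_config_(self) -> ModelConfig:
        return ModelConfig(n_estimators=self.n_estimators, seed=self.seed)

    def posture_rule(self) -> PostureRule:
        return PostureRule(
            psi_tolerance=self.psi_tolerance, phi_min=self.phi_min, phi_max=self.phi_max
        )

    def belt_config(self) -> BeltConfig:
        return BeltConfig(
            length_cm=self.belt_length_cm, pitch_cm=self.pitch_cm, offset_cm=self.offset_cm
        )

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            posture_debounce=self.posture_debounce,
            sedentary_limit=self.sedentary_limit,
            refractory=self.refractory,
        )


def _check_schema_line(path: Path, first_line: str) -> bool:
    """True if the file starts with our schema comment; reject newer majors."""
    if not first_line.startswith("# beltsense-schema:"):
        return False
    major = int(first_line.split(":", 1)[1].strip())
    if major > SCHEMA_MAJOR:
        raise ValueError(
            f"{path}: schema major {major} is newer than supported ({SCHEMA_MAJOR})"
        )
    return True


def write_recording(rec: ImuRecording, path) -> None:
    """CSV with header ``t,acc_x,...,gyro_z[,label]``; values round-trip losslessly."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.acc, rec.gyro]), columns=RECORDING_COLUMNS
    )
    if rec.labels is not None:
        df["label"] = rec.labels
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER_LINE + "\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_recording(path) -> ImuRecording:
    """Parse a recording CSV; malformed input errors cite the line."""
    path = Path(path)
    sample_rate = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# beltsense-schema:"):
                _check_schema_line(path, line.rstrip("\n"))
            elif line.startswith("# sample_rate_hz:"):
                sample_rate = float(line.split(":", 1)[1])
            skip += 1
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse CSV: {e}") from e
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}, line {skip + 1}: missing required columns {missing}"
        )
    for col in RECORDING_COLUMNS:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(
                f"{path}, line {int(bad[0]) + skip + 2}: non-numeric value in '{col}'"
            )
    t = df["t"].to_numpy(float)
    if sample_rate is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer sample rate from one sample")
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    labels = df["label"].to_numpy(object) if "label" in df.columns else None
    try:
        return ImuRecording(
            sample_rate=sample_rate,
            acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(float),
            gyro=df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(float),
            time=t,
            labels=labels,
        )
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_mag_trace(trace: MagnetometerTrace, path) -> None:
    path = Path(path)
    t = np.arange(len(trace.values)) / trace.sample_rate
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER_LINE + "\n")
        fh.write(f"# sample_rate_hz: {trace.sample_rate!r}\n")
        pd.DataFrame({"t": t, "mag": trace.values}).to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_mag_trace(path) -> MagnetometerTrace:
    path = Path(path)
    sample_rate = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# beltsense-schema:"):
                _check_schema_line(path, line.rstrip("\n"))
            elif line.startswith("# sample_rate_hz:"):
                sample_rate = float(line.split(":", 1)[1])
            skip += 1
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if "mag" not in df.columns:
        raise ValueError(f"{path}: missing 'mag' column")
    if sample_rate is None:
        t = df["t"].to_numpy(float)
        sample_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return MagnetometerTrace(sample_rate=sample_rate, values=df["mag"].to_numpy(float))


def write_signalset(signals: SignalSet, out_dir) -> None:
    """One CSV per channel for inspection (freq channels: one row per window)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ch in signals.channels.items():
        data = ch.data
        if ch.domain == "time":
            cols = ["x", "y", "z"] if data.ndim == 2 else ["value"]
            df = pd.DataFrame(np.atleast_2d(data.T).T, columns=cols)
        else:
            flat = data.reshape(len(data), -1)
            df = pd.DataFrame(flat)
            df.insert(0, "window_start", signals.window_starts)
        with open(out / f"{name}.csv", "w") as fh:
            fh.write(_CSV_HEADER_LINE + "\n")
            df.to_csv(fh, index=False)


def write_eval_report(report: EvalReport, json_path, confusion_csv_path=None) -> None:
    payload = {"schema": f"beltsense-report/{SCHEMA_MAJOR}"}
    payload.update(report.to_dict())
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if confusion_csv_path is not None:
        df = pd.DataFrame(
            report.confusion, index=list(report.classes), columns=list(report.classes)
        )
        df.to_csv(confusion_csv_path, index_label="true\\pred")


def write_events(events: list[InterventionEvent], path) -> None:
    df = pd.DataFrame(
        [(e.timestamp, e.channel, e.cause, e.pattern) for e in events],
        columns=["t", "channel", "cause", "pattern"],
    )
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER_LINE + "\n")
        df.to_csv(fh, index=False)


def _read_json(path) -> dict:
    data = json.loads(Path(path).read_text())
    schema = data.pop("schema", None)
    if schema is not None:
        major = int(str(schema).rsplit("/", 1)[-1])
        if major > SCHEMA_MAJOR:
            raise ValueError(f"{path}: schema {schema} newer than supported")
    return data


def read_belt_config(path) -> BeltConfig:
    data = _read_json(path)
    det = data.pop("detector", None)
    detector = PeakDetector(**det) if det else PeakDetector()
    return BeltConfig(detector=detector, **data)


def read_posture_rule(path) -> PostureRule:
    return PostureRule(**_read_json(path))


def read_engine_config(path) -> EngineConfig:
    return EngineConfig(**_read_json(path))
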