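"""Data model and serialization for protocolized time-series recordings.

A recording is a :class:`SweepSet`: a family of uniformly sampled traces
(membrane voltage, transmembrane current, or fluorescence) that share one
sampling rate and unit, each optionally paired with the stimulus step that
produced it.  The native exchange format is a comma-delimited sweep table
(one ``time`` column in seconds or milliseconds, one column per sweep)
plus a JSON sidecar ``<name>.protocol.json`` holding mode, unit, sampling
rate, per-sweep stimulus steps, cell capacitance and free-text metadata.
Time is always seconds internally; a file may declare ``time_unit: ms``
and is converted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "TimeSeriesTrace",
    "StimulusStep",
    "SweepSet",
    "read_sweepset",
    "write_sweepset",
    "VALID_UNITS",
    "VALID_MODES",
]

VALID_UNITS = ("mV", "pA", "AFU")  # AFU: arbitrary fluorescence units
VALID_MODES = ("current_clamp", "voltage_clamp", "fluorescence")

#: relative tolerance for declaring a time base uniform
TIME_UNIFORMITY_RTOL = 1e-6


@dataclass
class TimeSeriesTrace:
    """One uniformly sampled trace.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; must be positive.
    values : numpy.ndarray
        Sample values (mV, pA, or arbitrary fluorescence units); finite,
        non-empty.
    unit : str
        One of ``mV``, ``pA``, ``AFU``.
    label : str
        Free-text sweep label (also used as the table column name).
    """

    sampling_rate: float
    values: np.ndarray
    unit: str
    label: str = "sweep"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not (self.sampling_rate > 0):
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValidationError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise ValidationError(f"non-finite value at sample {bad} of trace {self.label!r}")
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.values.size) / self.sampling_rate

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeriesTrace):
            return NotImplemented
        return (
            self.sampling_rate == other.sampling_rate
            and self.unit == other.unit
            and self.label == other.label
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class StimulusStep:
    """A rectangular stimulus step within a sweep.

    ``level`` is in pA for current clamp and mV for voltage clamp;
    ``pre_level`` is the holding/baseline level in the same unit.
    Times are seconds from the start of the sweep.
    """

    onset_time: float
    duration: float
    level: float
    pre_level: float = 0.0

    def __post_init__(self):
        if self.onset_time < 0:
            raise ValidationError(f"onset_time must be >= 0, got {self.onset_time}")
        if not (self.duration > 0):
            raise ValidationError(f"duration must be > 0, got {self.duration}")

    @property
    def offset_time(self) -> float:
        return self.onset_time + self.duration


@dataclass
class SweepSet:
    """A protocolized family of sweeps from one cell.

    All sweeps share sampling rate and unit.  ``sweeps`` pairs each trace
    with the stimulus step that produced it (``None`` for stimulus-free
    recordings such as resting-potential segments).  ``metadata`` carries
    free-form annotations — the synthetic generators store ground truth
    there.
    """

    mode: str
    sweeps: list[tuple[TimeSeriesTrace, Optional[StimulusStep]]]
    cell_id: str = "cell"
    capacitance: Optional[float] = None
    group_label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in VALID_MODES:
            raise ValidationError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if not self.sweeps:
            raise ValidationError("SweepSet must contain at least one sweep")
        rates = {tr.sampling_rate for tr, _ in self.sweeps}
        units = {tr.unit for tr, _ in self.sweeps}
        if len(rates) != 1:
            raise ValidationError(f"sweeps do not share one sampling rate: {sorted(rates)}")
        if len(units) != 1:
            raise ValidationError(f"sweeps do not share one unit: {sorted(units)}")
        if self.capacitance is not None and not (self.capacitance > 0):
            raise ValidationError(f"capacitance must be > 0 pF, got {self.capacitance}")
        for tr, st in self.sweeps:
            if st is not None and st.offset_time > tr.duration * (1 + 1e-9):
                raise ValidationError(
                    f"step extends past the end of sweep {tr.label!r} "
                    f"({st.offset_time:g} s > {tr.duration:g} s)"
                )

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0][0].sampling_rate

    @property
    def unit(self) -> str:
        return self.sweeps[0][0].unit

    @property
    def traces(self) -> list[TimeSeriesTrace]:
        return [tr for tr, _ in self.sweeps]

    def stepped_sweeps(self) -> list[tuple[TimeSeriesTrace, StimulusStep]]:
        """Sweeps that carry a stimulus step."""
        return [(tr, st) for tr, st in self.sweeps if st is not None]

    def stimulus_free_sweeps(self) -> list[TimeSeriesTrace]:
        """Sweeps recorded without any stimulus step."""
        return [tr for tr, st in self.sweeps if st is None]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepSet):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.cell_id == other.cell_id
            and self.capacitance == other.capacitance
            and self.group_label == other.group_label
            and self.metadata == other.metadata
            and self.sweeps == other.sweeps
        )


# ---------------------------------------------------------------------------
# serialization


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".protocol.json")


def _step_to_json(step: Optional[StimulusStep]):
    if step is None:
        return None
    return {
        "onset_s": step.onset_time,
        "duration_s": step.duration,
        "level": step.level,
        "pre_level": step.pre_level,
    }


def _step_from_json(obj) -> Optional[StimulusStep]:
    if obj is None:
        return None
    return StimulusStep(
        onset_time=obj["onset_s"],
        duration=obj["duration_s"],
        level=obj["level"],
        pre_level=obj.get("pre_level", 0.0),
    )


def write_sweepset(sweepset: SweepSet, path) -> None:
    """Write a SweepSet as a CSV sweep table plus a JSON protocol sidecar.

    Values are printed at full float64 precision (``%.17g``) so that
    :func:`read_sweepset` inverts the write bit-identically.
    """
    if not isinstance(sweepset, SweepSet):
        raise ValidationError("write_sweepset expects a SweepSet")
    path = Path(path)
    n = max(tr.values.size for tr in sweepset.traces)
    fs = sweepset.sampling_rate
    labels = [tr.label for tr, _ in sweepset.sweeps]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"sweep labels must be unique, got {labels}")

    cols = {"time": np.arange(n) / fs}
    for tr in sweepset.traces:
        col = np.full(n, np.nan)
        col[: tr.values.size] = tr.values
        cols[tr.label] = col
    table = pd.DataFrame(cols)
    table.to_csv(path, index=False, float_format="%.17g", na_rep="")

    descriptor = {
        "format": "inephys-sweepset",
        "version": 1,
        "mode": sweepset.mode,
        "unit": sweepset.unit,
        "time_unit": "s",
        "sampling_rate_hz": sweepset.sampling_rate,
        "cell_id": sweepset.cell_id,
        "capacitance_pF": sweepset.capacitance,
        "group_label": sweepset.group_label,
        "sweeps": [
            {"label": tr.label, "n_samples": int(tr.values.size), "step": _step_to_json(st)}
            for tr, st in sweepset.sweeps
        ],
        "metadata": sweepset.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(descriptor, indent=1))


def read_sweepset(path, format_hint: str = "csv") -> SweepSet:
    """Read a SweepSet written by :func:`write_sweepset`.

    ``format_hint`` is reserved for adapters (e.g. an Axon Binary Format
    reader registered under ``"abf"``); only ``"csv"`` is built in.

    Raises
    ------
    FormatError
        If the protocol sidecar is missing or malformed.
    ValidationError
        If the time base is non-uniform (relative tolerance 1e-6) or the
        table contains NaN within a sweep's declared length.
    """
    if format_hint != "csv":
        raise FormatError(f"unknown format_hint {format_hint!r}; built-in format is 'csv'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing protocol descriptor {sidecar.name}")
    try:
        descriptor = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable protocol descriptor: {exc}") from exc
    for key in ("mode", "unit", "sampling_rate_hz", "sweeps"):
        if key not in descriptor:
            raise FormatError(f"protocol descriptor lacks required key {key!r}")

    table = pd.read_csv(path, float_precision="round_trip")
    if "time" not in table.columns:
        raise FormatError("sweep table lacks a 'time' column")

    time = table["time"].to_numpy(dtype=float)
    time_unit = descriptor.get("time_unit", "s")
    if time_unit == "ms":
        time = time / 1000.0
    elif time_unit != "s":
        raise FormatError(f"unknown time_unit {time_unit!r}")
    if time.size >= 2:
        dt = np.diff(time)
        dt0 = (time[-1] - time[0]) / (time.size - 1)
        if dt0 <= 0 or not np.allclose(dt, dt0, rtol=TIME_UNIFORMITY_RTOL, atol=1e-12 * abs(dt0)):
            bad = int(np.argmax(np.abs(dt - dt0))) + 1
            raise ValidationError(
                f"non-uniform time base near row {bad}: dt={dt[bad - 1]:g}, expected {dt0:g}"
            )
        fs_table = 1.0 / dt0
        fs = float(descriptor["sampling_rate_hz"])
        if not math.isclose(fs, fs_table, rel_tol=1e-3):
            raise ValidationError(
                f"descriptor sampling rate {fs:g} Hz disagrees with table ({fs_table:g} Hz)"
            )
    else:
        fs = float(descriptor["sampling_rate_hz"])

    unit = descriptor["unit"]
    sweeps = []
    for entry in descriptor["sweeps"]:
        label = entry["label"]
        if label not in table.columns:
            raise FormatError(f"descriptor sweep {label!r} not found in the table")
        col = table[label].to_numpy(dtype=float)
        n = int(entry.get("n_samples", col.size))
        values = col[:n]
        if np.any(np.isnan(values)):
            bad = int(np.flatnonzero(np.isnan(values))[0])
            raise ValidationError(f"NaN at row {bad} of column {label!r}")
        sweeps.append(
            (
                TimeSeriesTrace(sampling_rate=fs, values=values, unit=unit, label=label),
                _step_from_json(entry.get("step")),
            )
        )

    return SweepSet(
        mode=descriptor["mode"],
        sweeps=sweeps,
        cell_id=descriptor.get("cell_id", "cell"),
        capacitance=descriptor.get("capacitance_pF"),
        group_label=descriptor.get("group_label", "") or "",
        metadata=descriptor.get("metadata", {}) or {},
    )
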