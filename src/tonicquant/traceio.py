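"""Trace containers and file round-tripping.

Currents follow the inward-negative convention throughout: a GABA-A
chloride current at Vhold = -70 mV with a high-Cl internal solution is
inward, i.e. negative pA. Traces are carried as plain numpy arrays with
sampling metadata; files use a compact text dialect:

    # sampling_rate_hz=10000
    # units=pA
    # t_drug_s=30.0
    # capacitance_pf=68.0
    # cell_id=cell01
    # group_label=PV
    # condition=SR95531
    -45.123456
    -44.871204
    ...

Header lines are '#'-prefixed ``key=value`` pairs; samples follow one per
line, time implied by index and sampling rate. ``sampling_rate_hz`` and
``units`` are mandatory; the reader rejects any units other than pA (mV
for step responses) rather than silently rescaling. An optional binary
dialect stores the samples as a ``.npy`` array with a JSON metadata
sidecar.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TraceFormatError, TraceParseError, ValidationError

__all__ = [
    "CurrentTrace",
    "StepResponse",
    "read_trace",
    "write_trace",
    "read_step_response",
    "write_step_response",
    "write_results_table",
]

_REQUIRED_KEYS = ("sampling_rate_hz", "units")


@dataclass
class CurrentTrace:
    """A sampled membrane-current recording (pA, inward-negative).

    Parameters
    ----------
    samples
        Current samples in pA.
    sampling_rate_hz
        Sampling rate in Hz (10 kHz in the emulated protocol).
    t_drug_s
        Time of bath drug application in seconds, or ``None`` when the
        recording has no drug switch.
    capacitance_pf
        Cell capacitance in pF (amplifier readout metadata), or ``None``.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    t_drug_s: float | None = None
    capacitance_pf: float | None = None
    cell_id: str = ""
    group_label: str = ""
    condition: str = ""
    units_checked: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("samples: must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples: all values must be finite")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz: must be > 0")
        if self.t_drug_s is not None and not (
            0.0 <= self.t_drug_s <= self.duration_s
        ):
            raise ValidationError(
                "t_drug_s: must lie within [0, trace duration]"
            )
        if self.capacitance_pf is not None and not self.capacitance_pf > 0:
            raise ValidationError("capacitance_pf: must be > 0 when given")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass
class StepResponse:
    """A current-clamp voltage response (mV) to a square current step."""

    voltage_samples: np.ndarray
    sampling_rate_hz: float
    i_step_pa: float
    pulse_start_s: float
    pulse_duration_s: float
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.voltage_samples = np.asarray(self.voltage_samples, dtype=np.float64)
        if self.voltage_samples.ndim != 1 or self.voltage_samples.size < 1:
            raise ValidationError("voltage_samples: must be a non-empty 1-D sequence")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz: must be > 0")
        if not self.pulse_duration_s > 0.1:
            raise ValidationError(
                "pulse_duration_s: must exceed 0.1 s (a last-100-ms window "
                "must fit inside the pulse)"
            )
        dur = self.voltage_samples.size / self.sampling_rate_hz
        if not (0.0 <= self.pulse_start_s and
                self.pulse_start_s + self.pulse_duration_s <= dur + 1e-12):
            raise ValidationError("pulse window: must lie inside the trace")

    @property
    def duration_s(self) -> float:
        return self.voltage_samples.size / self.sampling_rate_hz


def _parse_header(lines: list[str], path: str) -> tuple[dict, int]:
    header: dict[str, str] = {}
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        body = line[1:].strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        header[key.strip()] = value.strip()
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise TraceFormatError(
                f"{path}: missing required header key '{key}'"
            )
    return header, n_header


def _load_samples(lines: list[str], n_header: int, path: str) -> np.ndarray:
    body = lines[n_header:]
    try:
        return np.array([float(s) for s in body if s.strip()], dtype=np.float64)
    except ValueError:
        for offset, raw in enumerate(body):
            s = raw.strip()
            if not s:
                continue
            try:
                float(s)
            except ValueError:
                lineno = n_header + offset + 1
                raise TraceParseError(
                    f"{path}:{lineno}: non-numeric sample {s!r}",
                    line_number=lineno,
                ) from None
        raise  # pragma: no cover - unreachable


def _opt_float(header: dict, key: str) -> float | None:
    raw = header.get(key, "")
    if raw in ("", "none", "None", "NA"):
        return None
    try:
        return float(raw)
    except ValueError:
        raise TraceFormatError(f"header key '{key}' is not numeric: {raw!r}")


def read_trace(path: str | os.PathLike, dialect: str = "text") -> CurrentTrace:
    """Read a :class:`CurrentTrace` written by :func:`write_trace`.

    The reader validates units (``pA``) and raises
    :class:`~tonicquant.errors.TraceFormatError` on a missing header key or
    a unit mismatch, and :class:`~tonicquant.errors.TraceParseError` (with
    the line number) on a non-numeric sample.
    """
    path = Path(path)
    if dialect == "text":
        lines = path.read_text().splitlines()
        header, n_header = _parse_header(lines, str(path))
        samples = _load_samples(lines, n_header, str(path))
    elif dialect == "binary":
        samples = np.load(path.with_suffix(".npy"))
        header = json.loads(path.with_suffix(".json").read_text())
        header = {k: str(v) for k, v in header.items() if v is not None}
        for key in _REQUIRED_KEYS:
            if key not in header:
                raise TraceFormatError(
                    f"{path}: missing required metadata key '{key}'"
                )
    else:
        raise ValidationError(f"dialect: unknown dialect {dialect!r}")
    if header["units"] != "pA":
        raise TraceFormatError(
            f"{path}: units are {header['units']!r}, expected 'pA'; "
            "refusing to rescale"
        )
    return CurrentTrace(
        samples=samples,
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        t_drug_s=_opt_float(header, "t_drug_s"),
        capacitance_pf=_opt_float(header, "capacitance_pf"),
        cell_id=header.get("cell_id", ""),
        group_label=header.get("group_label", ""),
        condition=header.get("condition", ""),
        units_checked=True,
    )


def write_trace(
    trace: CurrentTrace,
    path: str | os.PathLike,
    dialect: str = "text",
    precision: int = 6,
    overwrite: bool = False,
) -> None:
    """Write a trace to ``path``; refuses to overwrite unless asked.

    ``precision`` controls the number of decimals in the text dialect;
    round-trips are bit-identical at that precision.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise ValidationError(
            f"path: {path} exists; pass overwrite=True to replace it"
        )
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "units": "pA",
        "t_drug_s": trace.t_drug_s,
        "capacitance_pf": trace.capacitance_pf,
        "cell_id": trace.cell_id,
        "group_label": trace.group_label,
        "condition": trace.condition,
    }
    if dialect == "text":
        out = []
        for key, value in meta.items():
            if value is None or value == "":
                continue
            if isinstance(value, float):
                value = format(value, "g")
            out.append(f"# {key}={value}")
        out.extend(format(s, f".{precision}f") for s in trace.samples)
        path.write_text("\n".join(out) + "\n")
    elif dialect == "binary":
        np.save(path.with_suffix(".npy"), trace.samples)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    else:
        raise ValidationError(f"dialect: unknown dialect {dialect!r}")


def write_step_response(
    step: StepResponse,
    path: str | os.PathLike,
    precision: int = 6,
    overwrite: bool = False,
) -> None:
    """Write a voltage step response in the text dialect (units=mV)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise ValidationError(
            f"path: {path} exists; pass overwrite=True to replace it"
        )
    out = [
        f"# sampling_rate_hz={format(step.sampling_rate_hz, 'g')}",
        "# units=mV",
        f"# i_step_pa={format(step.i_step_pa, 'g')}",
        f"# pulse_start_s={format(step.pulse_start_s, 'g')}",
        f"# pulse_duration_s={format(step.pulse_duration_s, 'g')}",
    ]
    if step.cell_id:
        out.append(f"# cell_id={step.cell_id}")
    out.extend(format(v, f".{precision}f") for v in step.voltage_samples)
    path.write_text("\n".join(out) + "\n")


def read_step_response(path: str | os.PathLike) -> StepResponse:
    """Read a :class:`StepResponse` written by :func:`write_step_response`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header, n_header = _parse_header(lines, str(path))
    if header["units"] != "mV":
        raise TraceFormatError(
            f"{path}: units are {header['units']!r}, expected 'mV'; "
            "refusing to rescale"
        )
    for key in ("i_step_pa", "pulse_start_s", "pulse_duration_s"):
        if key not in header:
            raise TraceFormatError(f"{path}: missing required header key '{key}'")
    samples = _load_samples(lines, n_header, str(path))
    return StepResponse(
        voltage_samples=samples,
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        i_step_pa=float(header["i_step_pa"]),
        pulse_start_s=float(header["pulse_start_s"]),
        pulse_duration_s=float(header["pulse_duration_s"]),
        cell_id=header.get("cell_id", ""),
    )


# Stable column orders for the results CSVs (RFC 4180 via pandas).
TONIC_COLUMNS = [
    "cell_id", "group_label", "condition", "mode",
    "i_hold_pre_pa", "i_hold_post_pa",
    "tonic_current_pa", "tonic_signed_pa",
    "current_density_pa_per_pf", "capacitance_pf",
    "n_segments_pre", "n_segments_post", "all_clean",
]
COMPARISON_COLUMNS = [
    "quantity", "group1", "group2", "n1", "n2",
    "u_stat", "p_two_sided", "method", "tie_count",
    "mean1", "sem1", "mean2", "sem2",
]


def write_results_table(results: Sequence, path: str | os.PathLike) -> None:
    """Write per-cell tonic results or group comparisons as CSV.

    One row per result; a missing capacitance leaves the density cell
    empty (never zero). An empty input yields a header-only file, taking
    the schema from the first result type it would have written
    (tonic results by default).
    """
    rows = [r.as_row() if hasattr(r, "as_row") else dict(r) for r in results]
    if rows:
        columns = COMPARISON_COLUMNS if "u_stat" in rows[0] else TONIC_COLUMNS
    else:
        columns = TONIC_COLUMNS
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)
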