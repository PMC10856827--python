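"""Discrete joint-angle variables from averaged gait-cycle waveforms.

Nine discrete variables are read off the run-averaged, time-normalized
waveforms: "initial" variables are the value at 0 % of the gait cycle and
"peak" variables are the signed extremum within the approximated stance phase
(0-40 % of the cycle).  Signs follow the ISB-style convention of the source
data: hip adduction and ankle inversion are negative, so the peak hip
adduction is a signed minimum while peak knee flexion, ankle dorsiflexion and
ankle eversion are signed maxima.  Running speed (RS, from the timing gates)
and stride frequency (SF, from the detected cycle durations) complete the row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .segment import NormalizedCycleSet


@dataclass(frozen=True)
class VariableSpec:
    """How to read one discrete variable off an averaged waveform."""

    name: str
    signal: str
    kind: str  # "initial" | "peak"
    direction: str | None = None  # "max" | "min", peaks only
    window: tuple[int, int] = (0, 40)  # percent-of-cycle interval, peaks only

    def __post_init__(self) -> None:
        if self.kind not in ("initial", "peak"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "peak":
            if self.direction not in ("max", "min"):
                raise ValueError(f"peak variable {self.name} needs direction 'max' or 'min'")
            lo, hi = self.window
            if not (0 <= lo < hi <= 40):
                raise ValueError(
                    f"peak window {self.window} must lie within the stance interval [0, 40]"
                )


#: The nine discrete joint-angle variables of the analysis.
DEFAULT_SPECS: tuple[VariableSpec, ...] = (
    VariableSpec("IHF", "hip_flexion", "initial"),
    VariableSpec("IHA", "hip_abduction", "initial"),
    VariableSpec("PHA", "hip_abduction", "peak", "min"),
    VariableSpec("IKF", "knee_flexion", "initial"),
    VariableSpec("PKF", "knee_flexion", "peak", "max"),
    VariableSpec("IAD", "ankle_dorsiflexion", "initial"),
    VariableSpec("PAD", "ankle_dorsiflexion", "peak", "max"),
    VariableSpec("IAI", "ankle_eversion", "initial"),
    VariableSpec("PAE", "ankle_eversion", "peak", "max"),
)

ANGLE_VARIABLES: tuple[str, ...] = tuple(s.name for s in DEFAULT_SPECS)

#: Map from variable name to the waveform signal it is extracted from.
VARIABLE_SIGNALS: dict[str, str] = {s.name: s.signal for s in DEFAULT_SPECS}

#: Full column set of a feature table.
FEATURE_COLUMNS: tuple[str, ...] = (
    "participant",
    "day",
    "surface",
    "run",
    "calibration",
    *ANGLE_VARIABLES,
    "RS",
    "SF",
)


def extract_value(waveform: np.ndarray, spec: VariableSpec) -> float:
    """Read one discrete value off a single 101-point averaged waveform."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.shape != (101,):
        raise ValueError(f"expected a 101-point waveform, got shape {waveform.shape}")
    if spec.kind == "initial":
        return float(waveform[0])
    lo, hi = spec.window
    window = waveform[lo : hi + 1]  # closed interval on the percent grid
    return float(window.max() if spec.direction == "max" else window.min())


def extract_features(
    cycles: "NormalizedCycleSet",
    specs: Sequence[VariableSpec] = DEFAULT_SPECS,
    avg_speed: float = float("nan"),
) -> dict[str, float]:
    """Extract all discrete variables plus RS and SF from one run's cycle set."""
    row: dict[str, float] = {}
    for spec in specs:
        if spec.signal not in cycles.mean_waveforms:
            raise KeyError(
                f"variable {spec.name}: signal {spec.signal!r} missing from averaged waveforms"
            )
        row[spec.name] = extract_value(cycles.mean_waveforms[spec.signal], spec)
    row["RS"] = float(avg_speed)
    row["SF"] = float(cycles.stride_frequency)
    return row


def build_feature_table(
    items: Iterable[tuple[Mapping, "NormalizedCycleSet", float]],
    specs: Sequence[VariableSpec] = DEFAULT_SPECS,
) -> pd.DataFrame:
    """Build the discrete-feature table, one row per (participant, day, surface, run, calibration).

    ``items`` yields ``(meta, cycle_set, avg_speed)`` triples where ``meta``
    carries the five key fields.
    """
    rows = []
    for meta, cycles, avg_speed in items:
        try:
            values = extract_features(cycles, specs=specs, avg_speed=avg_speed)
        except Exception as exc:
            key = {k: meta.get(k) for k in ("participant", "day", "surface", "run", "calibration")}
            raise RuntimeError(f"feature extraction failed for {key}: {exc}") from exc
        rows.append(
            {
                "participant": meta["participant"],
                "day": int(meta["day"]),
                "surface": meta["surface"],
                "run": int(meta["run"]),
                "calibration": int(meta["calibration"]),
                **values,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        dup = table.duplicated(subset=["participant", "day", "surface", "run", "calibration"])
        if dup.any():
            raise ValueError(f"duplicate feature-table keys: {table[dup].iloc[0].to_dict()}")
    return table
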