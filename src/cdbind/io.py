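"""CSV / config / JSON input-output for the analysis pipeline.

Boundary units follow laboratory convention — concentrations in mM,
injection volumes in uL, heats in uJ (or ucal with an explicit flag),
shifts in ppm — and are converted to SI on the way in.

Dialects
--------
continuous-variation table : sample_id, host_total_mM, guest_total_mM, then
    one column per proton label holding delta_obs in ppm (empty = missing).
assignments table : label, species, delta_free_ppm.
ITC table : injection_index, volume_uL, heat_uJ [, control_heat_uJ].
DPPH table : time_s, then one absorbance column per sample label; a sidecar
    config maps labels to concentrations (uM) and gives the control read.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dpph_assay import DPPHTrace
from .errors import ParseError
from .itc_analysis import ITCData, ITCProtocol
from .nmr_titration import CVDataset, CVSample, ProtonAssignment

SCHEMA_VERSION = 1

JOULES_PER_CALORIE = 4.184

_RESERVED_CV_COLUMNS = ("sample_id", "host_total_mM", "guest_total_mM")


def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, column: str, path: str | Path) -> pd.Series:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = values.isna() & df[column].notna()
    if bad.any():
        rows = [int(i) + 2 for i in df.index[bad]]  # header is line 1
        raise ParseError(f"{path}: non-numeric value in column {column!r} at line(s) {rows}")
    return values


def read_assignments_csv(path: str | Path) -> tuple[ProtonAssignment, ...]:
    df = _read_table(path, ("label", "species", "delta_free_ppm"))
    shifts = _numeric(df, "delta_free_ppm", path)
    return tuple(
        ProtonAssignment(label=str(row.label), species=str(row.species), delta_free=float(s))
        for row, s in zip(df.itertuples(index=False), shifts)
    )


def write_assignments_csv(assignments: tuple[ProtonAssignment, ...], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [a.label for a in assignments],
            "species": [a.species for a in assignments],
            "delta_free_ppm": [a.delta_free for a in assignments],
        }
    ).to_csv(path, index=False)


def read_cv_csv(path: str | Path, assignments_path: str | Path) -> CVDataset:
    """Read a continuous-variation series; totals arrive in mM."""
    assignments = read_assignments_csv(assignments_path)
    df = _read_table(path, _RESERVED_CV_COLUMNS)
    proton_columns = [c for c in df.columns if c not in _RESERVED_CV_COLUMNS]
    known = {a.label for a in assignments}
    unknown = [c for c in proton_columns if c not in known]
    if unknown:
        raise ParseError(f"{path}: shift columns {unknown} have no assignment")
    host = _numeric(df, "host_total_mM", path) * 1e-3
    guest = _numeric(df, "guest_total_mM", path) * 1e-3
    shift_cols = {c: _numeric(df, c, path) for c in proton_columns}
    samples = []
    for i in range(len(df)):
        shifts = {
            c: float(col.iloc[i]) for c, col in shift_cols.items() if pd.notna(col.iloc[i])
        }
        samples.append(
            CVSample(
                sample_id=int(df["sample_id"].iloc[i]),
                host_total=float(host.iloc[i]),
                guest_total=float(guest.iloc[i]),
                observed_shifts=shifts,
            )
        )
    total = float(np.median([s.host_total + s.guest_total for s in samples]))
    return CVDataset(samples=tuple(samples), assignments=assignments, total_concentration=total)


def write_cv_csv(dataset: CVDataset, path: str | Path) -> None:
    labels = dataset.proton_labels
    rows = []
    for s in dataset.samples:
        row: dict[str, Any] = {
            "sample_id": s.sample_id,
            "host_total_mM": s.host_total * 1e3,
            "guest_total_mM": s.guest_total * 1e3,
        }
        for lab in labels:
            row[lab] = s.observed_shifts.get(lab, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_itc_csv(path: str | Path, units: str = "uJ") -> tuple[tuple[float, ...], ITCData]:
    """Read injection volumes (returned in L) and heats (returned in J).

    ``units`` selects the heat unit of the file: ``uJ`` (native) or
    ``ucal`` (converted at 4.184 J/cal).  The heat column may be named
    ``heat_uJ`` or ``heat_ucal`` to match.
    """
    if units not in ("uJ", "ucal"):
        raise ParseError(f"unsupported heat units {units!r}; use 'uJ' or 'ucal'")
    df = _read_table(path, ("injection_index", "volume_uL"))
    heat_col = next((c for c in (f"heat_{units}", "heat_uJ") if c in df.columns), None)
    if heat_col is None:
        raise ParseError(f"{path}: no heat column (expected heat_{units})")
    factor = 1e-6 * (JOULES_PER_CALORIE if units == "ucal" else 1.0)
    volumes = tuple(float(v) * 1e-6 for v in _numeric(df, "volume_uL", path))
    heats = tuple(float(q) * factor for q in _numeric(df, heat_col, path))
    control = None
    control_col = next(
        (c for c in (f"control_heat_{units}", "control_heat_uJ") if c in df.columns), None
    )
    if control_col is not None:
        series = _numeric(df, control_col, path)
        if series.notna().any():
            control = tuple(float(q) * factor for q in series)
    return volumes, ITCData(heats=heats, control_heats=control)


def write_itc_csv(protocol: ITCProtocol, data: ITCData, path: str | Path) -> None:
    columns: dict[str, Any] = {
        "injection_index": np.arange(1, protocol.n_injections + 1),
        "volume_uL": [v * 1e6 for v in protocol.injection_volumes],
        "heat_uJ": [q * 1e6 for q in data.heats],
    }
    if data.control_heats is not None:
        columns["control_heat_uJ"] = [q * 1e6 for q in data.control_heats]
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.17g")


_PROTOCOL_KEYS = ("cell_volume_mL", "cell_mM", "syringe_mM", "temperature_C")


def read_protocol_config(
    path: str | Path, injection_volumes: tuple[float, ...]
) -> ITCProtocol:
    """Build an ITCProtocol from a flat key-value config plus the per-file
    injection volumes (L).  Unknown keys are rejected."""
    raw = load_config(path)
    unknown = [k for k in raw if k not in _PROTOCOL_KEYS]
    if unknown:
        raise ParseError(f"{path}: unknown config keys {unknown}; allowed {_PROTOCOL_KEYS}")
    missing = [k for k in _PROTOCOL_KEYS if k not in raw]
    if missing:
        raise ParseError(f"{path}: missing config keys {missing}")
    return ITCProtocol(
        cell_volume=float(raw["cell_volume_mL"]) * 1e-3,
        cell_concentration=float(raw["cell_mM"]) * 1e-3,
        syringe_concentration=float(raw["syringe_mM"]) * 1e-3,
        injection_volumes=injection_volumes,
        temperature=float(raw["temperature_C"]) + 273.15,
    )


def write_protocol_config(protocol: ITCProtocol, path: str | Path) -> None:
    save_config(
        {
            "cell_volume_mL": protocol.cell_volume * 1e3,
            "cell_mM": protocol.cell_concentration * 1e3,
            "syringe_mM": protocol.syringe_concentration * 1e3,
            "temperature_C": protocol.temperature - 273.15,
        },
        path,
    )


def read_dpph_csv(path: str | Path, config_path: str | Path) -> list[DPPHTrace]:
    """Read kinetic traces; the sidecar config supplies ``control_absorbance``
    and a ``concentrations_uM`` map from column label to concentration."""
    raw = load_config(config_path)
    allowed = ("control_absorbance", "concentrations_uM")
    unknown = [k for k in raw if k not in allowed]
    if unknown:
        raise ParseError(f"{config_path}: unknown config keys {unknown}; allowed {allowed}")
    try:
        control = float(raw["control_absorbance"])
        conc_map = {str(k): float(v) for k, v in raw["concentrations_uM"].items()}
    except (KeyError, TypeError, AttributeError) as exc:
        raise ParseError(f"{config_path}: need control_absorbance and concentrations_uM") from exc
    df = _read_table(path, ("time_s",))
    times = tuple(float(t) for t in _numeric(df, "time_s", path))
    traces = []
    for column in df.columns:
        if column == "time_s":
            continue
        if column not in conc_map:
            raise ParseError(f"{path}: column {column!r} has no concentration in the config")
        traces.append(
            DPPHTrace(
                label=column,
                concentration=conc_map[column],
                times=times,
                absorbances=tuple(float(a) for a in _numeric(df, column, path)),
                control_absorbance=control,
            )
        )
    return traces


def write_dpph_csv(traces: list[DPPHTrace], path: str | Path, config_path: str | Path) -> None:
    times = traces[0].times
    columns: dict[str, Any] = {"time_s": times}
    for trace in traces:
        if trace.times != times:
            raise ParseError("all traces must share one time grid to share a file")
        columns[trace.label] = trace.absorbances
    pd.DataFrame(columns).to_csv(path, index=False, float_format="%.17g")
    save_config(
        {
            "control_absorbance": traces[0].control_absorbance,
            "concentrations_uM": {t.label: t.concentration for t in traces},
        },
        config_path,
    )


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    return raw


def save_config(config: dict[str, Any], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_results(result: Any, path: str | Path) -> None:
    """Serialise a result object (dataclass or mapping) to versioned JSON."""
    payload = {"schema_version": SCHEMA_VERSION, "result": _jsonable(result)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
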