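"""Trace and cohort file I/O.

Traces are stored as TSV with header ``time\tdonor\tacceptor``; a cohort is
described by a JSON manifest listing one record per molecule (trace path,
condition label, ligand concentration in molar, frame time).  Every
downstream stage consumes the in-memory types from :mod:`ribokin.datamodel`;
nothing re-parses files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datamodel import AcquisitionParams, Trace

TRACE_COLUMNS = ("time", "donor", "acceptor")


class TraceParseError(ValueError):
    """Raised when a trace file violates the format contract."""


def read_trace(path: str | Path, acquisition: AcquisitionParams | None = None,
               **metadata: Any) -> Trace:
    """Read one TSV trace file.

    The time grid is taken from the file; if ``acquisition`` is given, the
    grid step is validated against its frame_time to 1e-6 s.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed TSV
        raise TraceParseError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    for col in TRACE_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(values.isna().to_numpy())
        if bad.size:
            # +2: header line plus 1-based numbering
            raise TraceParseError(f"{path}: malformed value in line {bad[0] + 2}")
        df[col] = values
    times = df["time"].to_numpy(float)
    if len(times) >= 2:
        steps = np.diff(times)
        if np.any(steps <= 0):
            line = int(np.flatnonzero(steps <= 0)[0]) + 3
            raise TraceParseError(f"{path}: non-increasing time at line {line}")
        if np.max(np.abs(steps - steps[0])) > 1e-6:
            line = int(np.argmax(np.abs(steps - steps[0]))) + 3
            raise TraceParseError(f"{path}: non-uniform time step at line {line}")
        if acquisition is not None and abs(steps[0] - acquisition.frame_time) > 1e-6:
            raise TraceParseError(
                f"{path}: time step {steps[0]:g} s does not match "
                f"frame_time {acquisition.frame_time:g} s"
            )
    metadata.setdefault("molecule_id", path.stem)
    return Trace(
        molecule_id=str(metadata["molecule_id"]),
        times=times,
        donor=df["donor"].to_numpy(float),
        acceptor=df["acceptor"].to_numpy(float),
        condition=str(metadata.get("condition", "")),
        ligand_conc=float(metadata.get("ligand_conc", 0.0)),
    )


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as TSV; round-trips through :func:`read_trace`."""
    if len(trace) == 0:
        raise ValueError("refusing to write empty trace")
    path = Path(path)
    df = pd.DataFrame(
        {"time": trace.times, "donor": trace.donor, "acceptor": trace.acceptor}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_manifest(records: list[dict[str, Any]], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump({"molecules": records}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> list[dict[str, Any]]:
    with open(path) as fh:
        payload = json.load(fh)
    records = payload.get("molecules")
    if not isinstance(records, list):
        raise TraceParseError(f"{path}: manifest must contain a 'molecules' list")
    return records


def write_cohort(traces: list[Trace], out_dir: str | Path,
                 frame_time: float | None = None) -> Path:
    """Write traces plus a JSON manifest into ``out_dir``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for trace in traces:
        fname = f"{trace.molecule_id}.tsv"
        write_trace(trace, out_dir / fname)
        records.append(
            {
                "molecule_id": trace.molecule_id,
                "path": fname,
                "condition": trace.condition,
                "ligand_conc": trace.ligand_conc,
                "frame_time": frame_time if frame_time is not None else trace.frame_time,
            }
        )
    manifest_path = out_dir / "manifest.json"
    write_manifest(records, manifest_path)
    return manifest_path


def load_cohort(manifest: str | Path) -> tuple[dict[str, list[Trace]], pd.DataFrame]:
    """Load all traces listed in a manifest, grouped by condition.

    Returns ``(groups, table)`` where ``groups`` maps condition label to the
    list of traces and ``table`` is the manifest as a DataFrame.  Raises if a
    trace file is missing or frame times disagree within one condition.
    """
    manifest = Path(manifest)
    records = read_manifest(manifest)
    base = manifest.parent
    groups: dict[str, list[Trace]] = {}
    frame_times: dict[str, float] = {}
    for rec in records:
        trace_path = base / rec["path"]
        if not trace_path.exists():
            raise FileNotFoundError(f"manifest references missing trace {trace_path}")
        cond = str(rec.get("condition", ""))
        ft = float(rec.get("frame_time", 0.1))
        if cond in frame_times and abs(frame_times[cond] - ft) > 1e-9:
            raise ValueError(f"inconsistent frame_time within condition {cond!r}")
        frame_times[cond] = ft
        acq = AcquisitionParams(frame_time=ft, n_frames=2)
        trace = read_trace(
            trace_path,
            acquisition=acq,
            molecule_id=rec.get("molecule_id", trace_path.stem),
            condition=cond,
            ligand_conc=float(rec.get("ligand_conc", 0.0)),
        )
        groups.setdefault(cond, []).append(trace)
    table = pd.DataFrame(records)
    return groups, table


def write_idealizations(
    ideals: list, frame_time: float, path: str | Path
) -> None:
    """Serialize idealizations as run-length-encoded JSON."""
    payload = {"frame_time": frame_time, "molecules": []}
    for ideal in ideals:
        states = np.asarray(ideal.states)
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [states.size]))
        runs = [[int(states[i0]), int(i1 - i0)] for i0, i1 in zip(starts, ends)]
        payload["molecules"].append(
            {
                "molecule_id": ideal.molecule_id,
                "valid_until": int(ideal.valid_until),
                "runs": runs,
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_idealizations(path: str | Path) -> tuple[list, float]:
    """Inverse of :func:`write_idealizations`."""
    from .datamodel import Idealization

    with open(path) as fh:
        payload = json.load(fh)
    ideals = []
    for rec in payload["molecules"]:
        states = np.concatenate(
            [np.full(length, state, dtype=np.int8) for state, length in rec["runs"]]
        ) if rec["runs"] else np.zeros(0, dtype=np.int8)
        ideals.append(
            Idealization(
                molecule_id=rec["molecule_id"],
                states=states,
                valid_until=rec["valid_until"],
            )
        )
    return ideals, float(payload["frame_time"])


def nanomolar(value_nm: float) -> float:
    """Convert a nM concentration (CLI convenience) to molar."""
    return float(value_nm) * 1e-9
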