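"""Trace CSV format, configuration, reports and run manifests.

The on-disk trace format is a plain CSV with exactly these columns::

    trace_id,time_s,signal,signal_kind,protein_conc_M,substrate_conc_M,competitor_conc_M,replicate

Concentrations are molar in files, always — human units (nM, µM) are a
CLI affordance converted at parse time, never stored.  Numeric output
is serialized with 15 significant digits so reports round-trip exactly.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time as _time
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .estimation import FitResult
from .tracedata import Design, Trace, TraceSet
from .uncertainty import MCResult

__all__ = [
    "TRACE_COLUMNS",
    "TraceParseError",
    "read_traces",
    "write_traces",
    "write_truth",
    "read_truth",
    "write_fit_report",
    "write_mc_report",
    "write_residuals",
    "write_manifest",
    "load_config",
]

TRACE_COLUMNS = [
    "trace_id",
    "time_s",
    "signal",
    "signal_kind",
    "protein_conc_M",
    "substrate_conc_M",
    "competitor_conc_M",
    "replicate",
]

_FLOAT_FMT = "%.15g"  # >= 12 significant digits, exact round-trip


class TraceParseError(ValueError):
    """Trace CSV violates the format contract."""


def read_traces(path: str | Path, design: Design | str = Design.PLATEREADER) -> TraceSet:
    """Read a trace CSV into a validated TraceSet.

    Errors name the offending column or row: missing columns,
    non-numeric cells and non-increasing time within a trace all raise
    :class:`TraceParseError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TraceParseError(f"{path}: no data rows")
    numeric_cols = TRACE_COLUMNS[1:3] + TRACE_COLUMNS[4:]
    for col in numeric_cols:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise TraceParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in "
                f"column {col!r} at line {row}"
            )
        df[col] = converted

    traces = []
    for (trace_id, rep), grp in df.groupby(["trace_id", "replicate"], sort=False):
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            i = int(np.argmax(np.diff(t) <= 0))
            row = int(grp.index[i + 1]) + 2
            raise TraceParseError(
                f"{path}: non-increasing time in trace {trace_id!r} at line {row}"
            )
        kinds = grp["signal_kind"].unique()
        if len(kinds) != 1:
            raise TraceParseError(
                f"{path}: trace {trace_id!r} mixes signal kinds {list(kinds)}"
            )
        for col in ("protein_conc_M", "substrate_conc_M", "competitor_conc_M"):
            if grp[col].nunique() != 1:
                raise TraceParseError(
                    f"{path}: trace {trace_id!r} has varying {col}"
                )
        traces.append(
            Trace(
                trace_id=str(trace_id),
                time=t,
                signal=grp["signal"].to_numpy(dtype=float),
                kind=str(kinds[0]),
                protein_conc=float(grp["protein_conc_M"].iloc[0]),
                substrate_conc=float(grp["substrate_conc_M"].iloc[0]),
                competitor_conc=float(grp["competitor_conc_M"].iloc[0]),
                replicate=int(rep),
            )
        )
    return TraceSet(traces, Design(design))


def write_traces(traceset: TraceSet, path: str | Path) -> None:
    """Write a TraceSet to the trace CSV format (molar, 15 sig. digits)."""
    frames = []
    for t in traceset:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": t.trace_id,
                    "time_s": t.time,
                    "signal": t.signal,
                    "signal_kind": t.kind.value,
                    "protein_conc_M": t.protein_conc,
                    "substrate_conc_M": t.substrate_conc,
                    "competitor_conc_M": t.competitor_conc,
                    "replicate": t.replicate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_truth(truth: Any, path: str | Path, extra: Mapping[str, Any] | None = None) -> None:
    """Sidecar recording the generating parameters of a synthetic set."""
    payload = {"scheme": type(truth).__name__, "params": asdict(truth)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_fit_report(fit: FitResult, path: str | Path) -> None:
    """Key-value fit report; values re-read exactly."""
    lines = [f"scheme = {fit.scheme.value}"]
    for name in sorted(fit.estimates):
        lines.append(f"{name} = {_FLOAT_FMT % fit.estimates[name]}")
    lines += [
        f"composite_kapp = {_FLOAT_FMT % fit.composite_kapp}",
        f"adjusted_S0 = {_FLOAT_FMT % fit.adjusted_S0}",
        f"objective = {_FLOAT_FMT % fit.objective}",
        f"residual_sd = {_FLOAT_FMT % fit.residual_sd}",
        f"n_points = {fit.n_points}",
        f"n_free = {fit.n_free}",
        f"converged = {fit.converged}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_mc_report(mc: MCResult, path: str | Path) -> None:
    lines = [
        f"n_requested = {mc.n_requested}",
        f"n_kept = {mc.n_kept}",
    ]
    for name in sorted(mc.sd):
        lo, hi = mc.ci[name]
        lines.append(f"{name}_sd = {_FLOAT_FMT % mc.sd[name]}")
        lines.append(f"{name}_ci = {_FLOAT_FMT % lo} {_FLOAT_FMT % hi}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_residuals(
    traceset: TraceSet, model: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """Per-point residual CSV (trace_id, time_s, observed, model, residual)."""
    frames = []
    for t in traceset.reaction_traces():
        m = model[t.trace_id]
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": t.trace_id,
                    "time_s": t.time,
                    "observed": t.signal,
                    "model": m,
                    "residual": t.signal - m,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_manifest(
    out_dir: str | Path,
    *,
    config: Mapping[str, Any] | None,
    seed: int | None,
    inputs: list[str | Path] = (),
) -> Path:
    """Emit the run manifest next to the outputs (one per CLI run)."""
    from . import __version__

    checksums = {}
    for p in inputs:
        p = Path(p)
        checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "command_line": sys.argv,
        "config": dict(config) if config else None,
        "seed": seed,
        "version": __version__,
        "input_checksums": checksums,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def load_config(path: str | Path) -> dict:
    """Load and minimally validate a pipeline YAML config."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
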