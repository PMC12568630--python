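"""Trace conditioning before fitting.

Mirrors the preprocessing applied to raw instrument output: technical
replicates recorded on a shared hardware grid are averaged pointwise;
stopped-flow pretrigger samples are removed and times re-zeroed; the
free-substrate baseline r_free is taken as the time-mean of the
zero-protein trace and held fixed in downstream fits.

No resampling or interpolation happens here: replicates that do not
share a grid are an error, never silently interpolated away.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .tracedata import Trace, TraceSet

__all__ = [
    "average_replicates",
    "average_all_replicates",
    "trim_and_zero",
    "extract_baseline",
    "BaselineMissingError",
    "GridMismatchError",
]

#: grids are "identical" if they agree to this many seconds pointwise
GRID_TOL = 1e-9


class GridMismatchError(ValueError):
    """Replicates do not share a common time grid."""


class BaselineMissingError(ValueError):
    """TraceSet contains no zero-protein trace to extract r_free from."""


def average_replicates(traces: Sequence[Trace]) -> Trace:
    """Pointwise mean of technical replicates on a common grid.

    All traces must share the time grid (to within ``GRID_TOL`` seconds)
    and every annotation except the replicate index.  The result carries
    replicate index 0 and records the replicate count in ``n_averaged``.
    """
    if not traces:
        raise ValueError("no traces to average")
    if len(traces) == 1:
        return traces[0]
    ref = traces[0]
    for t in traces[1:]:
        if len(t) != len(ref) or np.any(np.abs(t.time - ref.time) > GRID_TOL):
            raise GridMismatchError(
                f"trace {t.trace_id!r} grid differs from {ref.trace_id!r}; "
                "replicates must share the hardware grid (no resampling)"
            )
        same = (
            t.kind == ref.kind
            and t.protein_conc == ref.protein_conc
            and t.substrate_conc == ref.substrate_conc
            and t.competitor_conc == ref.competitor_conc
        )
        if not same:
            raise ValueError(
                f"trace {t.trace_id!r} annotations differ from {ref.trace_id!r}; "
                "only replicates of one condition can be averaged"
            )
    mean = np.mean([t.signal for t in traces], axis=0)
    n_total = sum(t.n_averaged for t in traces)
    return ref.with_(signal=mean, replicate=0, n_averaged=n_total)


def average_all_replicates(traceset: TraceSet) -> TraceSet:
    """Collapse every condition group of a TraceSet to its replicate mean."""
    out = [average_replicates(group) for group in traceset.group_by_condition().values()]
    return TraceSet(out, traceset.design)


def trim_and_zero(trace: Trace, trigger_time: float = 0.0) -> Trace:
    """Drop pretrigger samples and shift times to start at zero.

    Samples with ``time < trigger_time`` are removed; the retained times
    are shifted so the first retained sample sits at t = 0.
    """
    keep = trace.time >= trigger_time
    if not np.any(keep):
        raise ValueError(
            f"trace {trace.trace_id!r}: all samples are pretrigger "
            f"(trigger_time={trigger_time})"
        )
    time = trace.time[keep]
    return trace.with_(time=time - time[0], signal=trace.signal[keep])


def extract_baseline(traceset: TraceSet) -> float:
    """Free-substrate signal r_free from the zero-protein traces.

    Returns the time-mean signal pooled over all zero-protein traces
    (a flat-trace model: the free fluorophore neither binds nor
    bleaches on the assay timescale).  The value is meant to be fixed
    in downstream fits.
    """
    baseline = traceset.baseline_traces()
    if not baseline:
        raise BaselineMissingError(
            "no zero-protein trace in set; record a free-substrate baseline "
            "or fit r_free as a free parameter (discouraged)"
        )
    return float(np.mean(np.concatenate([t.signal for t in baseline])))
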