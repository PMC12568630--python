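"""Trace containers for labeling-kinetics experiments.

A :class:`Trace` is one time series recorded on one well / one stopped-flow
shot / one cell population: a time grid (seconds), a signal (mP,
anisotropy, intensity ratio, absorbance or line-profile intensity) and the
experimental annotations needed to fit it (protein, substrate and
competitor concentrations, all molar, and a replicate index).

A :class:`TraceSet` groups the traces of one concentration-series
experiment — the unit a global fit consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = ["SignalKind", "Design", "Trace", "TraceSet"]


class SignalKind(str, enum.Enum):
    """What physical quantity the signal column holds."""

    MP = "mP"
    ANISOTROPY = "anisotropy"
    RATIO = "ratio"
    ABSORBANCE = "absorbance"
    INTENSITY = "intensity"


class Design(str, enum.Enum):
    """Instrument / experimental design that produced a TraceSet."""

    PLATEREADER = "platereader"
    STOPPEDFLOW = "stoppedflow"
    COMPETITION = "competition"
    INCELL = "incell"


@dataclass(frozen=True)
class Trace:
    """One annotated time series.

    Parameters
    ----------
    trace_id
        Unique identifier within a set.
    time
        Sample times in seconds, strictly increasing.
    signal
        Measured values, same length as ``time``.
    kind
        Signal kind (mP, anisotropy, ratio, absorbance, intensity).
    protein_conc, substrate_conc, competitor_conc
        Nominal molar concentrations; 0 where not applicable.
    replicate
        Technical replicate index (0-based).
    n_averaged
        How many replicates were averaged into this trace (1 for raw).
    """

    trace_id: str
    time: np.ndarray
    signal: np.ndarray
    kind: SignalKind = SignalKind.MP
    protein_conc: float = 0.0
    substrate_conc: float = 0.0
    competitor_conc: float = 0.0
    replicate: int = 0
    n_averaged: int = 1

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "signal", signal)
        object.__setattr__(self, "kind", SignalKind(self.kind))
        if time.ndim != 1 or signal.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays")
        if time.size != signal.size:
            raise ValueError(
                f"trace {self.trace_id!r}: time ({time.size}) and signal "
                f"({signal.size}) lengths differ"
            )
        if time.size == 0:
            raise ValueError(f"trace {self.trace_id!r}: empty trace")
        if np.any(np.diff(time) <= 0):
            raise ValueError(
                f"trace {self.trace_id!r}: time must be strictly increasing"
            )
        for name in ("protein_conc", "substrate_conc", "competitor_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"trace {self.trace_id!r}: {name} < 0")

    def __len__(self) -> int:
        return int(self.time.size)

    def with_(self, **changes) -> "Trace":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @property
    def is_baseline(self) -> bool:
        """True for a zero-protein (free-substrate) trace."""
        return self.protein_conc == 0.0


@dataclass
class TraceSet:
    """A collection of traces forming one experiment.

    Invariants enforced: all traces share the signal kind, and at most one
    protein-concentration group is the zero-protein baseline group.
    """

    traces: list[Trace] = field(default_factory=list)
    design: Design = Design.PLATEREADER

    def __post_init__(self) -> None:
        self.traces = list(self.traces)
        self.design = Design(self.design)
        kinds = {t.kind for t in self.traces}
        if len(kinds) > 1:
            raise ValueError(f"mixed signal kinds in one TraceSet: {kinds}")

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    @property
    def protein_concs(self) -> list[float]:
        """Distinct protein concentrations, ascending."""
        return sorted({t.protein_conc for t in self.traces})

    @property
    def substrate_conc(self) -> float:
        """The shared nominal substrate concentration.

        Raises if the non-baseline traces disagree (a concentration series
        varies protein, not substrate).
        """
        concs = {t.substrate_conc for t in self.traces if not t.is_baseline}
        if not concs:
            concs = {t.substrate_conc for t in self.traces}
        if len(concs) != 1:
            raise ValueError(f"multiple substrate concentrations: {sorted(concs)}")
        return concs.pop()

    def baseline_traces(self) -> list[Trace]:
        return [t for t in self.traces if t.is_baseline]

    def reaction_traces(self) -> list[Trace]:
        return [t for t in self.traces if not t.is_baseline]

    def group_by_condition(self) -> dict[tuple[float, float, float], list[Trace]]:
        """Group traces by (protein, substrate, competitor) concentration."""
        groups: dict[tuple[float, float, float], list[Trace]] = {}
        for t in self.traces:
            key = (t.protein_conc, t.substrate_conc, t.competitor_conc)
            groups.setdefault(key, []).append(t)
        return groups

    def select(self, predicate) -> "TraceSet":
        return TraceSet([t for t in self.traces if predicate(t)], self.design)

    @staticmethod
    def from_traces(traces: Iterable[Trace], design: Design | str) -> "TraceSet":
        return TraceSet(list(traces), Design(design))
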