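"""Mapping species trajectories onto measured signals.

Fluorescence polarization (mP) and anisotropy both increase when the
small fluorescent substrate binds the large tag protein.  Both are
treated as affine in the bound mole fraction:

    signal(t) = r_free + (r_bound - r_free) * bound(t) / fluor_total

where ``r_free`` is the free-substrate baseline (fixed from zero-protein
traces), ``r_bound`` the fully-labeled signal, and ``bound(t)`` the
summed concentration of whichever species count as bound.  Under
limiting protein only part of the substrate is ever labeled, which
lowers the plateau — the feature that makes the substrate concentration
identifiable in global fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import Trajectory
from .tracedata import SignalKind, Trace

__all__ = ["ObservableMap", "trajectory_to_signal"]

#: bound-species conventions per scheme
BOUND_DIRECT = ("PS",)
BOUND_TWOSTEP = ("PSstar", "PS")  # a non-covalent complex already tumbles slowly
BOUND_COMPETITION = ("PI",)  # only the reporter arm fluoresces


@dataclass(frozen=True)
class ObservableMap:
    """Affine signal model.

    Parameters
    ----------
    r_free
        Signal of the unbound fluorescent substrate (mP or anisotropy).
    r_bound
        Signal of the bound / covalently labeled substrate.
    bound_species
        Which trajectory species count as bound.  Defaults to the
        covalent product only; for two-step stopped-flow fits use
        ``("PSstar", "PS")``.
    """

    r_free: float
    r_bound: float
    bound_species: tuple[str, ...] = BOUND_DIRECT

    def __post_init__(self) -> None:
        if self.r_bound < self.r_free:
            warnings.warn(
                "r_bound < r_free: binding normally increases polarization; "
                "proceeding (inverted-signal assay?)",
                stacklevel=2,
            )
        if not self.bound_species:
            raise ValueError("bound_species must not be empty")


def trajectory_to_signal(
    traj: Trajectory,
    obs_map: ObservableMap,
    fluor_total: float,
    *,
    kind: SignalKind = SignalKind.MP,
    trace_id: str = "model",
    protein_conc: float = 0.0,
    substrate_conc: float = 0.0,
    competitor_conc: float = 0.0,
) -> Trace:
    """Convert a species trajectory into a model signal trace.

    ``fluor_total`` is the total fluorophore concentration (M), i.e. the
    substrate concentration for direct schemes or the reporter
    concentration for the competition scheme.
    """
    if fluor_total <= 0:
        raise ValueError(f"fluor_total must be > 0, got {fluor_total}")
    missing = [s for s in obs_map.bound_species if s not in traj.species]
    if missing:
        raise KeyError(f"bound species not in trajectory: {missing}")
    frac = traj.total(obs_map.bound_species) / fluor_total
    signal = obs_map.r_free + (obs_map.r_bound - obs_map.r_free) * frac
    return Trace(
        trace_id=trace_id,
        time=np.asarray(traj.time, dtype=float),
        signal=signal,
        kind=kind,
        protein_conc=protein_conc,
        substrate_conc=substrate_conc,
        competitor_conc=competitor_conc,
    )
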