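"""Synthetic datasets emulating the standard labeling-kinetics designs.

Each built-in template reproduces one experimental design used to
characterize self-labeling tag kinetics:

* ``platereader_std`` — microplate FP, substrate 20 nM, protein 0 and a
  2-fold ladder from 900 nM down (8 steps, reaching ~7 nM).
* ``platereader_fast`` — fast variant: substrate 2 nM, protein 0 and
  0.78–50 nM (2-fold ladder).
* ``stoppedflow`` — anisotropy, substrate 0.5 µM, protein 0.25–3.13 µM,
  15 technical replicates, 1 ms sampling over 2 s (a dual-rate
  200 µs / 2 ms variant is available).
* ``competition`` — reporter 100 nM, protein 200 nM, nonfluorescent
  competitor 0 and 0.1–1 µM.
* ``incell`` — sigmoidal labeling ratio sampled every 30 s over 90 min.
* ``dilution_series`` — absorbance at 7.5–2.22 µM (1.5-fold dilution).
* ``line_profile`` — Gaussian filament profile on a 25 nm pixel grid.

Noise is additive i.i.d. Gaussian on the signal; the default sd is 2%
of the free-to-bound dynamic range.  One master seed governs a run;
per-trace generator substreams are derived from (seed, trace index) so
adding traces never reshuffles the noise of earlier ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
import numpy as np

from .models import (
    CompetitionParams,
    InitialConditions,
    Model1Params,
    Model2Params,
    simulate_competition,
    simulate_model1,
    simulate_model2,
)
from .observables import (
    BOUND_COMPETITION,
    BOUND_DIRECT,
    BOUND_TWOSTEP,
    ObservableMap,
)
from .tracedata import Design, SignalKind, Trace, TraceSet

__all__ = [
    "TemplateName",
    "DesignTemplate",
    "SigmoidalTruth",
    "platereader_std",
    "platereader_fast",
    "stoppedflow",
    "competition",
    "incell",
    "dilution_series",
    "line_profile",
    "generate",
    "generate_incell",
    "generate_dilution",
    "generate_profile",
]

#: default noise as a fraction of the free-to-bound dynamic range
DEFAULT_NOISE_FRAC = 0.02


class TemplateName(str, enum.Enum):
    PLATEREADER_STD = "platereader_std"
    PLATEREADER_FAST = "platereader_fast"
    STOPPEDFLOW = "stoppedflow"
    COMPETITION = "competition"
    INCELL = "incell"
    DILUTION_SERIES = "dilution_series"
    LINE_PROFILE = "line_profile"


@dataclass(frozen=True)
class DesignTemplate:
    """One experimental design: concentrations, grid, replication, noise."""

    name: TemplateName
    protein_ladder: tuple[float, ...]  # M; includes 0 for baseline designs
    substrate_conc: float  # M; the fluorescent species
    competitor_ladder: tuple[float, ...] = (0.0,)  # M
    replicates: int = 1
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 2))
    noise_sd: float | None = None  # None -> DEFAULT_NOISE_FRAC of range
    seed: int = 0
    kind: SignalKind = SignalKind.MP
    design: Design = Design.PLATEREADER

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_(self, **changes) -> "DesignTemplate":
        return replace(self, **changes)


@dataclass(frozen=True)
class SigmoidalTruth:
    """Ground truth for the in-cell sigmoidal labeling curve."""

    Y0: float
    Ymax: float
    t_half_min: float  # minutes
    H: float


def _twofold_ladder(top: float, steps: int) -> tuple[float, ...]:
    return tuple(top / 2.0**k for k in range(steps))


def platereader_std(seed: int = 0, **overrides) -> DesignTemplate:
    """Standard microplate FP design: substrate 20 nM, protein 0 + 4.6–900 nM.

    The printed range spans 4.60–900 nM without naming a dilution
    factor; a 2-fold ladder of 8 steps (900 down to ~7 nM) is the
    default and is overridable.
    """
    tpl = DesignTemplate(
        name=TemplateName.PLATEREADER_STD,
        protein_ladder=(0.0,) + _twofold_ladder(900e-9, 8),
        substrate_conc=20e-9,
        grid=np.arange(0.0, 7200.0 + 1, 30.0),
        seed=seed,
        kind=SignalKind.MP,
        design=Design.PLATEREADER,
    )
    return tpl.with_(**overrides) if overrides else tpl


def platereader_fast(seed: int = 0, **overrides) -> DesignTemplate:
    """Fast-kinetics microplate design: substrate 2 nM, protein 0 + 0.78–50 nM."""
    tpl = DesignTemplate(
        name=TemplateName.PLATEREADER_FAST,
        protein_ladder=(0.0,) + _twofold_ladder(50e-9, 7),
        substrate_conc=2e-9,
        grid=np.arange(0.0, 7200.0 + 1, 30.0),
        seed=seed,
        kind=SignalKind.MP,
        design=Design.PLATEREADER,
    )
    return tpl.with_(**overrides) if overrides else tpl


def stoppedflow(seed: int = 0, *, dual_rate: bool = False, **overrides) -> DesignTemplate:
    """Stopped-flow anisotropy design: substrate 0.5 µM, protein 0.25–3.13 µM,
    15 replicates, 1 ms sampling for 2 s.

    ``dual_rate=True`` uses the 200 µs / 2 ms two-stage grid (3 s total).
    """
    if dual_rate:
        grid = np.concatenate(
            [np.arange(0.0, 0.2, 200e-6), np.arange(0.2, 3.0 + 1e-9, 2e-3)]
        )
    else:
        grid = np.arange(0.0, 2.0 + 1e-9, 1e-3)
    tpl = DesignTemplate(
        name=TemplateName.STOPPEDFLOW,
        protein_ladder=(0.0,) + tuple(np.geomspace(0.25e-6, 3.13e-6, 5)),
        substrate_conc=0.5e-6,
        replicates=15,
        grid=grid,
        seed=seed,
        kind=SignalKind.ANISOTROPY,
        design=Design.STOPPEDFLOW,
    )
    return tpl.with_(**overrides) if overrides else tpl


def competition(seed: int = 0, **overrides) -> DesignTemplate:
    """Competition design: reporter 100 nM, protein 200 nM, competitor 0–1 µM."""
    tpl = DesignTemplate(
        name=TemplateName.COMPETITION,
        protein_ladder=(0.0, 200e-9),
        substrate_conc=100e-9,  # the fluorescent reporter
        competitor_ladder=(0.0,) + tuple(np.geomspace(0.1e-6, 1.0e-6, 5)),
        grid=np.arange(0.0, 3600.0 + 1, 10.0),
        seed=seed,
        kind=SignalKind.MP,
        design=Design.COMPETITION,
    )
    return tpl.with_(**overrides) if overrides else tpl


def incell(seed: int = 0, **overrides) -> DesignTemplate:
    """In-cell imaging design: ratio traces sampled every 30 s over 90 min."""
    tpl = DesignTemplate(
        name=TemplateName.INCELL,
        protein_ladder=(),
        substrate_conc=0.0,
        grid=np.arange(0.0, 90.0 * 60.0 + 1, 30.0),
        seed=seed,
        kind=SignalKind.RATIO,
        design=Design.INCELL,
    )
    return tpl.with_(**overrides) if overrides else tpl


def dilution_series(seed: int = 0, **overrides) -> DesignTemplate:
    """Absorbance dilution series, 7.5 down to 2.22 µM (1.5-fold steps)."""
    tpl = DesignTemplate(
        name=TemplateName.DILUTION_SERIES,
        protein_ladder=(),
        substrate_conc=7.5e-6,
        grid=7.5e-6 / 1.5 ** np.arange(4),  # concentration axis
        seed=seed,
        kind=SignalKind.ABSORBANCE,
        design=Design.PLATEREADER,
    )
    return tpl.with_(**overrides) if overrides else tpl


def line_profile(seed: int = 0, **overrides) -> DesignTemplate:
    """Filament intensity line profile on a 25 nm pixel grid, ±0.5 µm."""
    tpl = DesignTemplate(
        name=TemplateName.LINE_PROFILE,
        protein_ladder=(),
        substrate_conc=0.0,
        grid=np.arange(-500.0, 500.0 + 1e-9, 25.0),  # nm position axis
        seed=seed,
        kind=SignalKind.INTENSITY,
        design=Design.PLATEREADER,
    )
    return tpl.with_(**overrides) if overrides else tpl


def _trace_rng(seed: int, index: int) -> np.random.Generator:
    # substream keyed by (seed, index): stable under trace-count changes
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def _noise_sd(template: DesignTemplate, obs_map: ObservableMap) -> float:
    if template.noise_sd is not None:
        return template.noise_sd
    return DEFAULT_NOISE_FRAC * abs(obs_map.r_bound - obs_map.r_free)


def generate(
    template: DesignTemplate,
    truth,
    obs_map: ObservableMap,
) -> TraceSet:
    """Simulate a fully annotated TraceSet from a design and ground truth.

    ``truth`` selects the scheme: :class:`Model1Params`,
    :class:`Model2Params` or :class:`CompetitionParams` (the latter only
    with the competition template).  Zero-protein ladder entries become
    flat baseline traces at r_free.
    """
    if template.name in (TemplateName.INCELL, TemplateName.DILUTION_SERIES,
                         TemplateName.LINE_PROFILE):
        raise ValueError(
            f"template {template.name.value!r} is not a kinetic-scheme design; "
            "use generate_incell / generate_dilution / generate_profile"
        )
    is_comp = isinstance(truth, CompetitionParams)
    if is_comp != (template.name is TemplateName.COMPETITION):
        raise ValueError(
            f"template {template.name.value!r} incompatible with "
            f"{type(truth).__name__}"
        )
    sd = _noise_sd(template, obs_map)

    traces: list[Trace] = []
    index = 0
    competitors = template.competitor_ladder if is_comp else (0.0,)
    for p0 in template.protein_ladder:
        for c0 in competitors:
            if p0 == 0.0 and c0 != 0.0:
                continue  # one baseline group only
            for rep in range(template.replicates):
                rng = _trace_rng(template.seed, index)
                index += 1
                if p0 == 0.0:
                    clean = np.full_like(template.grid, obs_map.r_free)
                elif isinstance(truth, Model1Params):
                    traj = simulate_model1(
                        truth, InitialConditions(p0, template.substrate_conc),
                        template.grid,
                    )
                    clean = _affine(traj, obs_map, template.substrate_conc)
                elif isinstance(truth, Model2Params):
                    traj = simulate_model2(
                        truth, InitialConditions(p0, template.substrate_conc),
                        template.grid,
                    )
                    clean = _affine(traj, obs_map, template.substrate_conc)
                elif isinstance(truth, CompetitionParams):
                    traj = simulate_competition(
                        truth,
                        InitialConditions(p0, c0, template.substrate_conc),
                        template.grid,
                    )
                    clean = _affine(traj, obs_map, template.substrate_conc)
                else:
                    raise ValueError(f"unsupported truth type {type(truth).__name__}")
                noise = rng.normal(0.0, sd, size=clean.size) if sd > 0 else 0.0
                traces.append(
                    Trace(
                        trace_id=f"{template.name.value}_P{p0:.3e}_C{c0:.3e}_r{rep}",
                        time=template.grid.copy(),
                        signal=clean + noise,
                        kind=template.kind,
                        protein_conc=p0,
                        substrate_conc=template.substrate_conc,
                        competitor_conc=c0,
                        replicate=rep,
                    )
                )
    return TraceSet(traces, template.design)


def _affine(traj, obs_map: ObservableMap, fluor_total: float) -> np.ndarray:
    frac = traj.total(obs_map.bound_species) / fluor_total
    return obs_map.r_free + (obs_map.r_bound - obs_map.r_free) * frac


def generate_incell(
    truth: SigmoidalTruth, template: DesignTemplate | None = None
) -> Trace:
    """One noisy in-cell ratio trace following the sigmoidal curve."""
    tpl = template or incell()
    rng = _trace_rng(tpl.seed, 0)
    t_min = tpl.grid / 60.0
    clean = np.full_like(t_min, truth.Y0)
    pos = t_min > 0
    clean[pos] = truth.Y0 + (truth.Ymax - truth.Y0) / (
        1.0 + (truth.t_half_min / t_min[pos]) ** truth.H
    )
    sd = tpl.noise_sd if tpl.noise_sd is not None else DEFAULT_NOISE_FRAC * abs(
        truth.Ymax - truth.Y0
    )
    noise = rng.normal(0.0, sd, size=clean.size) if sd > 0 else 0.0
    return Trace(
        trace_id="incell_r0",
        time=tpl.grid.copy(),
        signal=clean + noise,
        kind=SignalKind.RATIO,
    )


def generate_dilution(
    epsilon: float, path_length: float = 0.3, template: DesignTemplate | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Beer–Lambert absorbance dilution series (concentrations, absorbances)."""
    tpl = template or dilution_series()
    rng = _trace_rng(tpl.seed, 0)
    concs = np.asarray(tpl.grid, dtype=float)
    clean = epsilon * path_length * concs
    sd = tpl.noise_sd if tpl.noise_sd is not None else 0.0
    noise = rng.normal(0.0, sd, size=clean.size) if sd > 0 else 0.0
    return concs, clean + noise


def generate_profile(
    fwhm_true: float,
    template: DesignTemplate | None = None,
    *,
    amplitude: float = 1.0,
    offset: float = 0.0,
    center: float = 0.0,
) -> Trace:
    """Sampled Gaussian line profile with the given true FWHM.

    ``fwhm_true`` is in the grid's length units (nm for the default
    25 nm pixel grid).  The Gauss width is omega = fwhm / sqrt(2 ln 2);
    amplitude is the peak height above offset.
    """
    if fwhm_true <= 0:
        raise ValueError("fwhm_true must be > 0")
    tpl = template or line_profile()
    rng = _trace_rng(tpl.seed, 0)
    x = np.asarray(tpl.grid, dtype=float)
    omega = fwhm_true / np.sqrt(2.0 * np.log(2.0))
    clean = offset + amplitude * np.exp(-2.0 * (x - center) ** 2 / omega**2)
    sd = tpl.noise_sd if tpl.noise_sd is not None else 0.0
    noise = rng.normal(0.0, sd, size=clean.size) if sd > 0 else 0.0
    return Trace(
        trace_id="profile_r0",
        time=x,
        signal=clean + noise,
        kind=SignalKind.INTENSITY,
    )


def default_observable_map(truth) -> ObservableMap:
    """Sensible FP/anisotropy map for a scheme: 60→300 mP, bound species
    per scheme convention."""
    if isinstance(truth, Model2Params):
        return ObservableMap(0.05, 0.25, BOUND_TWOSTEP)
    if isinstance(truth, CompetitionParams):
        return ObservableMap(60.0, 300.0, BOUND_COMPETITION)
    return ObservableMap(60.0, 300.0, BOUND_DIRECT)
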