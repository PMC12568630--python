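"""Fitting: global concentration-series fits and closed-form secondary fits.

The central operation is :func:`global_fit`: a single parameter vector is
optimized against *all* traces of a concentration series simultaneously.
Following standard practice for labeling-kinetics data, the baseline
r_free and the per-trace protein concentrations are fixed, while the
shared substrate concentration is adjustable (within a relative bound)
to absorb quantification error — identifiable because limiting-protein
traces plateau below full labeling.

Rate constants are optimized in log10 space with multi-start refinement,
bounded nonlinear least squares underneath.  The one-step scheme uses
the analytic second-order solution for speed; the two-step and
competition schemes integrate their ODE systems.

Secondary fits: one-phase association (screening-mode k_app), sigmoidal
in-cell labeling curves (t_1/2), Gaussian line profiles (filament FWHM)
and Beer–Lambert extinction-coefficient lines.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from scipy.optimize import least_squares

from .models import (
    CompetitionParams,
    InitialConditions,
    Model1Params,
    Model2Params,
    derive_kapp,
    model1_closed_form,
    simulate_competition,
    simulate_model2,
)
from .observables import ObservableMap
from .tracedata import Trace, TraceSet

__all__ = [
    "Scheme",
    "FitSpec",
    "FitResult",
    "OnePhaseFit",
    "SigmoidalFit",
    "GaussianProfileFit",
    "ExtinctionFit",
    "DegenerateFitError",
    "ConvergenceError",
    "fit_one_phase",
    "kapp_from_rate",
    "global_fit",
    "fit_competition",
    "fit_sigmoidal",
    "fit_gaussian_profile",
    "fit_extinction",
]


class DegenerateFitError(ValueError):
    """Input carries no information about the model parameters."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged."""


class Scheme(str, enum.Enum):
    MODEL1 = "model1"
    MODEL2 = "model2"
    COMPETITION = "competition"


# log10 bounds: second-order rates in M^-1 s^-1, first-order in s^-1
_LOG_BOUNDS_2ND = (0.0, 10.0)
_LOG_BOUNDS_1ST = (-6.0, 6.0)

#: free rate-constant names per scheme
_SCHEME_RATES: dict[Scheme, tuple[str, ...]] = {
    Scheme.MODEL1: ("k_app",),
    Scheme.MODEL2: ("k1", "k_minus1", "k2"),
    Scheme.COMPETITION: ("kS_app", "kI_app"),
}
_SECOND_ORDER = {"k_app", "k1", "kS_app", "kI_app"}


@dataclass
class FitSpec:
    """What is fixed and what is free in a global fit.

    ``r_free`` (the free-substrate baseline) and the per-trace protein
    concentrations are always fixed; ``delay_time`` (instrument dead
    time, seconds) is a fixed offset added to the model times.  Rate
    constants are free unless listed in ``fixed``.  The substrate
    concentration is a shared free parameter within ``s0_rel_bound`` of
    nominal when ``substrate_conc_adjustable``.
    """

    scheme: Scheme
    r_free: float
    delay_time: float = 0.0
    substrate_conc_adjustable: bool = True
    s0_rel_bound: float = 0.5
    fixed: dict[str, float] = field(default_factory=dict)
    starts: dict[str, float] = field(default_factory=dict)
    n_starts: int = 5

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        rates = _SCHEME_RATES[self.scheme]
        unknown = set(self.fixed) - set(rates)
        if unknown:
            raise ValueError(f"fixed parameters not in scheme {self.scheme.value}: {unknown}")
        if not 0 < self.s0_rel_bound < 1:
            raise ValueError("s0_rel_bound must be in (0, 1)")

    @property
    def free_rates(self) -> tuple[str, ...]:
        return tuple(r for r in _SCHEME_RATES[self.scheme] if r not in self.fixed)


@dataclass
class FitResult:
    """Point estimates and bookkeeping from a global fit."""

    estimates: dict[str, float]
    adjusted_S0: float
    objective: float
    residual_sd: float
    converged: bool
    n_points: int
    n_free: int
    scheme: Scheme

    def rate_params(self):
        """Scheme parameter object rebuilt from the estimates."""
        e = self.estimates
        if self.scheme is Scheme.MODEL1:
            return Model1Params(e["k_app"])
        if self.scheme is Scheme.MODEL2:
            return Model2Params(e["k1"], e["k_minus1"], e["k2"])
        return CompetitionParams(e["kS_app"], e["kI_app"])

    @property
    def composite_kapp(self) -> float:
        """The overall labeling rate constant (M^-1 s^-1).

        For the two-step scheme this is the derived composite
        k1*k2/(k2 + k_-1); otherwise the fitted apparent constant itself
        (the reporter arm for competition fits).
        """
        if self.scheme is Scheme.MODEL2:
            return derive_kapp(self.rate_params())
        if self.scheme is Scheme.COMPETITION:
            return self.estimates["kI_app"]
        return self.estimates["k_app"]


# ---------------------------------------------------------------------------
# global fits


def _require_preprocessed(traceset: TraceSet) -> None:
    """Global fits consume averaged traces; refuse raw replicate stacks."""
    for key, group in traceset.group_by_condition().items():
        if len(group) > 1:
            raise ValueError(
                f"condition {key} holds {len(group)} replicate traces; "
                "run preprocess.average_all_replicates first (fits never "
                "preprocess silently)"
            )


def _model_signals(
    theta: np.ndarray,
    spec: FitSpec,
    obs_map: ObservableMap,
    conditions: Sequence[tuple[Trace, InitialConditions]],
    s0_index: int | None,
    rb_index: int,
) -> list[np.ndarray]:
    """Model signal per condition trace for one parameter vector."""
    rates = {name: 10.0 ** theta[i] for i, name in enumerate(spec.free_rates)}
    rates.update(spec.fixed)
    r_bound = theta[rb_index]
    # the adjustable concentration is always the fluorophore's: the
    # substrate for direct schemes, the reporter for competition
    s0_factor = theta[s0_index] if s0_index is not None else 1.0
    out = []
    for trace, ic0 in conditions:
        t = trace.time + spec.delay_time
        if spec.scheme is Scheme.MODEL1:
            ic = InitialConditions(P0=ic0.P0, S0=ic0.S0 * s0_factor)
            fluor = ic.S0
            bound = model1_closed_form(Model1Params(rates["k_app"]), ic, t)
        elif spec.scheme is Scheme.MODEL2:
            ic = InitialConditions(P0=ic0.P0, S0=ic0.S0 * s0_factor)
            fluor = ic.S0
            grid, order = _as_grid(t)
            traj = simulate_model2(
                Model2Params(rates["k1"], rates["k_minus1"], rates["k2"]), ic, grid
            )
            bound = traj.total(obs_map.bound_species)[order]
        else:
            ic = InitialConditions(P0=ic0.P0, S0=ic0.S0, I0=ic0.I0 * s0_factor)
            fluor = ic.I0  # only the reporter fluoresces
            grid, order = _as_grid(t)
            traj = simulate_competition(
                CompetitionParams(rates["kS_app"], rates["kI_app"]), ic, grid
            )
            bound = traj.total(obs_map.bound_species)[order]
        frac = bound / fluor if fluor > 0 else np.zeros_like(bound)
        out.append(spec.r_free + (r_bound - spec.r_free) * frac)
    return out


def _as_grid(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prepend t=0 if needed so the ODE grid starts at zero."""
    if t[0] == 0.0:
        return t, slice(None)
    grid = np.concatenate(([0.0], t))
    return grid, slice(1, None)


def _default_rate_starts(spec: FitSpec, n: int) -> list[dict[str, float]]:
    """Deterministic log-spaced multi-start list for the free rates."""
    starts: list[dict[str, float]] = []
    if spec.scheme is Scheme.MODEL2:
        # joint ladder: association sweeps decades while the unimolecular
        # steps track it, covering both rapid-equilibrium and chemical-
        # step-limited corners
        k1s = np.logspace(5, 8, n)
        km1s = np.logspace(0, 3, n)
        k2s = np.logspace(0, 3, n)
        for k1, km1, k2 in zip(k1s, km1s, k2s):
            starts.append({"k1": k1, "k_minus1": km1, "k2": k2})
    else:
        for k in np.logspace(3, 8, n):
            starts.append({name: k for name in spec.free_rates})
    for s in starts:
        s.update(spec.starts)
        for name in spec.fixed:
            s.pop(name, None)
    return starts


def global_fit(
    traceset: TraceSet, spec: FitSpec, obs_map: ObservableMap
) -> FitResult:
    """Fit one kinetic scheme to all traces of a concentration series.

    Minimizes the summed squared residuals over every non-baseline trace
    with a single shared parameter vector: the scheme's free rate
    constants (log10 parameterization), the bound-state signal r_bound,
    and — if adjustable — a shared substrate-concentration factor.
    Multi-start refinement guards against local minima; the best start's
    solution is returned.
    """
    _require_preprocessed(traceset)
    traces = traceset.reaction_traces()
    if not traces:
        raise ValueError("no reaction (protein > 0) traces to fit")
    if spec.scheme is not Scheme.COMPETITION and len({t.protein_conc for t in traces}) < 2:
        warnings.warn(
            "single protein concentration: the scheme may be under-identified "
            "(rate constants and concentrations trade off)",
            stacklevel=2,
        )

    # trace annotation convention: substrate_conc always holds the
    # fluorescent species (the reporter for competition designs), while
    # competitor_conc holds the nonfluorescent substrate racing for P
    if spec.scheme is Scheme.COMPETITION:
        conditions = [
            (t, InitialConditions(t.protein_conc, t.competitor_conc, t.substrate_conc))
            for t in traces
        ]
    else:
        conditions = [
            (t, InitialConditions(t.protein_conc, t.substrate_conc))
            for t in traces
        ]

    free_rates = spec.free_rates
    n_rates = len(free_rates)
    rb_index = n_rates
    s0_index = n_rates + 1 if spec.substrate_conc_adjustable else None

    all_signal = np.concatenate([t.signal for t in traces])
    sig_lo, sig_hi = float(all_signal.min()), float(all_signal.max())
    sig_range = max(sig_hi - sig_lo, abs(sig_hi), 1e-6)
    rb_start = sig_hi if sig_hi > spec.r_free else spec.r_free + sig_range
    rb_bounds = (min(sig_lo, spec.r_free) - sig_range, sig_hi + 10.0 * sig_range)

    lo = np.empty(n_rates + 1 + (s0_index is not None))
    hi = np.empty_like(lo)
    for i, name in enumerate(free_rates):
        lo[i], hi[i] = _LOG_BOUNDS_2ND if name in _SECOND_ORDER else _LOG_BOUNDS_1ST
    lo[rb_index], hi[rb_index] = rb_bounds
    if s0_index is not None:
        lo[s0_index], hi[s0_index] = 1.0 - spec.s0_rel_bound, 1.0 + spec.s0_rel_bound

    observed = [t.signal for t in traces]

    def residuals(theta: np.ndarray) -> np.ndarray:
        model = _model_signals(theta, spec, obs_map, conditions, s0_index, rb_index)
        return np.concatenate([m - o for m, o in zip(model, observed)])

    best = None
    n_failed = 0
    for start in _default_rate_starts(spec, spec.n_starts):
        theta0 = np.empty_like(lo)
        for i, name in enumerate(free_rates):
            theta0[i] = np.clip(math.log10(start[name]), lo[i], hi[i])
        theta0[rb_index] = np.clip(rb_start, *rb_bounds)
        if s0_index is not None:
            theta0[s0_index] = 1.0
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            n_failed += 1
            continue
        if not sol.success:
            n_failed += 1
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise ConvergenceError(
            f"no start converged ({n_failed} attempts failed) for scheme "
            f"{spec.scheme.value}"
        )

    theta = best.x
    estimates = {name: 10.0 ** theta[i] for i, name in enumerate(free_rates)}
    estimates.update(spec.fixed)
    estimates["r_bound"] = float(theta[rb_index])
    s0_nominal = traces[0].substrate_conc  # the fluorophore's nominal conc
    s0_factor = float(theta[s0_index]) if s0_index is not None else 1.0
    n_points = int(all_signal.size)
    n_free = theta.size
    ssr = float(2.0 * best.cost)
    dof = max(n_points - n_free, 1)
    return FitResult(
        estimates=estimates,
        adjusted_S0=s0_nominal * s0_factor,
        objective=ssr,
        residual_sd=math.sqrt(ssr / dof),
        converged=True,
        n_points=n_points,
        n_free=n_free,
        scheme=spec.scheme,
    )


def fit_competition(
    traceset: TraceSet, spec: FitSpec, obs_map: ObservableMap
) -> FitResult:
    """Fit the competition scheme to a competitor-concentration series.

    The observed signal follows the fluorescent reporter (PI); rising
    competitor concentration suppresses reporter labeling, which encodes
    kS_app.  kI_app is either supplied in ``spec.fixed`` or co-fitted,
    anchored by the zero-competitor trace.
    """
    if spec.scheme is not Scheme.COMPETITION:
        raise ValueError("fit_competition requires the competition scheme")
    _require_preprocessed(traceset)
    has_zero_competitor = any(
        t.competitor_conc == 0.0 and t.protein_conc > 0 for t in traceset
    )
    if "kI_app" not in spec.fixed and not has_zero_competitor:
        raise ValueError(
            "under-identified: no zero-competitor trace and kI_app not fixed"
        )
    return global_fit(traceset, spec, obs_map)


# ---------------------------------------------------------------------------
# secondary fits


@dataclass(frozen=True)
class OnePhaseFit:
    """One-phase association Y = Y0 + (Ymax - Y0)(1 - e^{-k t})."""

    Y0: float
    Ymax: float
    k: float  # s^-1


@dataclass(frozen=True)
class SigmoidalFit:
    """Sigmoidal (Hill-type) labeling curve in minutes.

    Y = Y0 + (Ymax - Y0) / (1 + (t_half / x)^H).
    """

    Y0: float
    Ymax: float
    t_half: float  # minutes
    H: float
    ci_thalf: tuple[float, float]  # asymptotic 95% CI, minutes


@dataclass(frozen=True)
class GaussianProfileFit:
    """Gaussian line profile y = y0 + A/(w sqrt(pi/2)) e^{-2 (x-xc)^2 / w^2}."""

    y0: float
    A: float
    omega: float
    xc: float

    @property
    def fwhm(self) -> float:
        return self.omega * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class ExtinctionFit:
    """Beer–Lambert line A = a + b*c; epsilon = b / path_length."""

    a: float
    b: float
    path_length: float  # cm

    @property
    def epsilon(self) -> float:
        return self.b / self.path_length


def _check_varies(signal: np.ndarray, what: str) -> None:
    if np.ptp(signal) <= 1e-12 * max(1.0, float(np.max(np.abs(signal), initial=0.0))):
        raise DegenerateFitError(f"{what}: signal does not vary")


def fit_one_phase(trace: Trace) -> OnePhaseFit:
    """Least-squares one-phase association fit (screening-mode kinetics)."""
    if len(trace) < 4:
        raise ValueError("one-phase fit needs at least 4 points")
    _check_varies(trace.signal, "one-phase fit")
    t, y = trace.time, trace.signal

    model = lmfit.Model(lambda x, Y0, Ymax, k: Y0 + (Ymax - Y0) * (1 - np.exp(-k * x)))
    span = max(t[-1], 1e-12)
    params = model.make_params(
        Y0=float(y[0]),
        Ymax=float(y[-1]) if y[-1] != y[0] else float(y[0]) + np.ptp(y),
        k=dict(value=2.0 / span, min=0.0),
    )
    out = model.fit(y, params, x=t)
    return OnePhaseFit(
        Y0=float(out.params["Y0"].value),
        Ymax=float(out.params["Ymax"].value),
        k=float(out.params["k"].value),
    )


def kapp_from_rate(k: float, protein_conc: float) -> float:
    """Apparent second-order constant from a pseudo-first-order rate.

    k_app = k / [protein]; valid when protein is in large excess over
    substrate so [P] is effectively constant.
    """
    if protein_conc <= 0:
        raise ValueError(f"protein_conc must be > 0, got {protein_conc}")
    return k / protein_conc


def _sigmoid(x: np.ndarray, Y0: float, Ymax: float, t_half: float, H: float) -> np.ndarray:
    out = np.full_like(x, Y0, dtype=float)
    pos = x > 0
    out[pos] = Y0 + (Ymax - Y0) / (1.0 + (t_half / x[pos]) ** H)
    return out


def fit_sigmoidal(trace: Trace) -> SigmoidalFit:
    """Fit the in-cell labeling curve; times are converted to minutes.

    The 95% CI on t_half is asymptotic (1.96 × the standard error from
    the parameter covariance at the optimum).
    """
    if len(trace) < 6:
        raise ValueError("sigmoidal fit needs at least 6 points")
    _check_varies(trace.signal, "sigmoidal fit")
    x = trace.time / 60.0  # minutes
    y = trace.signal

    model = lmfit.Model(_sigmoid)
    x_pos = x[x > 0]
    params = model.make_params(
        Y0=float(y[0]),
        Ymax=float(y[-1]),
        t_half=dict(value=float(np.median(x_pos)), min=1e-9),
        H=dict(value=1.5, min=0.1, max=20.0),
    )
    out = model.fit(y, params, x=x)
    th = out.params["t_half"]
    if th.stderr is None:
        raise DegenerateFitError(
            "sigmoidal fit: covariance unavailable (transition not spanned?)"
        )
    half_width = 1.96 * th.stderr
    return SigmoidalFit(
        Y0=float(out.params["Y0"].value),
        Ymax=float(out.params["Ymax"].value),
        t_half=float(th.value),
        H=float(out.params["H"].value),
        ci_thalf=(float(th.value - half_width), float(th.value + half_width)),
    )


def fit_gaussian_profile(profile: Trace) -> GaussianProfileFit:
    """Fit a Gaussian to a filament intensity line profile.

    The width convention is the e^{-2} Gauss width w, from which
    FWHM = w * sqrt(2 ln 2).
    """
    x, y = profile.time, profile.signal  # x-coordinate rides in the time slot
    if np.ptp(y) <= 0:
        raise DegenerateFitError("profile has no peak above offset")
    y0_guess = float(np.min(y))
    peak = float(np.max(y) - y0_guess)
    xc_guess = float(x[np.argmax(y)])
    # moment-based width start
    w = np.clip(y - y0_guess, 0, None)
    if w.sum() <= 0:
        raise DegenerateFitError("profile has no peak above offset")
    var = float(np.sum(w * (x - xc_guess) ** 2) / np.sum(w))
    omega_guess = max(2.0 * math.sqrt(var), (x[1] - x[0]))

    def gauss(x, y0, A, omega, xc):
        return y0 + A / (omega * np.sqrt(np.pi / 2.0)) * np.exp(
            -2.0 * (x - xc) ** 2 / omega**2
        )

    model = lmfit.Model(gauss)
    params = model.make_params(
        y0=y0_guess,
        A=dict(value=peak * omega_guess * math.sqrt(math.pi / 2.0), min=0.0),
        omega=dict(value=omega_guess, min=1e-12),
        xc=xc_guess,
    )
    out = model.fit(y, params, x=x)
    if out.params["A"].value <= 0:
        raise DegenerateFitError("profile has no peak above offset")
    return GaussianProfileFit(
        y0=float(out.params["y0"].value),
        A=float(out.params["A"].value),
        omega=float(out.params["omega"].value),
        xc=float(out.params["xc"].value),
    )


def fit_extinction(
    concentrations: np.ndarray,
    absorbances: np.ndarray,
    path_length: float = 0.3,
) -> ExtinctionFit:
    """Extinction coefficient from an absorbance dilution series.

    Ordinary least squares of absorbance against concentration; the
    slope divided by the cuvette path length (cm) gives epsilon in
    inverse concentration per cm (M^-1 cm^-1 for molar inputs).
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.size != a.size:
        raise ValueError("concentration and absorbance lengths differ")
    if c.size < 3:
        raise ValueError("extinction fit needs at least 3 concentrations")
    if np.ptp(c) == 0:
        raise ValueError("concentrations have zero variance")
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    b, intercept = np.polyfit(c, a, 1)
    if np.all(a == 0):
        warnings.warn("all absorbances are zero; epsilon = 0", stacklevel=2)
    return ExtinctionFit(a=float(intercept), b=float(b), path_length=path_length)
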