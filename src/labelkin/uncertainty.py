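"""Uncertainty quantification for kinetic fits.

Two tools:

* :func:`monte_carlo_ci` — Monte Carlo confidence intervals for a global
  fit, implemented as a parametric bootstrap: synthetic datasets are
  simulated from the fitted model with Gaussian noise at the fit's
  residual standard deviation, each is refitted, the worst fraction of
  refits (highest final objective) is excluded, and per-parameter
  standard deviations and percentile intervals are reported.  A
  residual-resampling variant is available.
* :func:`propagate_duplicate_ci` — the arithmetic for combining the
  half-labeling times of a biological duplicate: each replicate's 95%
  CI is converted to a standard error (half-width / 1.96), the two are
  pooled as sqrt((SE1^2 + SE2^2) / 2), and the mean's CI is
  mean ± 1.96 × pooled SE.  Note the pooled form divides the summed
  squares by 2 rather than 4; the conventional standard error of a
  two-replicate mean is available behind ``textbook=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .estimation import FitResult, FitSpec, Scheme, global_fit
from .observables import ObservableMap
from .tracedata import TraceSet

__all__ = [
    "MCResult",
    "ReplicateSummary",
    "MCInstabilityError",
    "monte_carlo_ci",
    "propagate_duplicate_ci",
]


class MCInstabilityError(RuntimeError):
    """Too many Monte Carlo replicate fits failed to converge."""


@dataclass
class MCResult:
    """Monte Carlo parameter distributions from a bootstrap of a global fit."""

    samples: dict[str, np.ndarray]  # per-parameter, length n_kept
    n_requested: int
    n_kept: int
    sd: dict[str, float]
    ci: dict[str, tuple[float, float]]  # 2.5th / 97.5th percentile

    def ci_of(self, name: str) -> tuple[float, float]:
        return self.ci[name]


@dataclass(frozen=True)
class ReplicateSummary:
    """Duplicate-averaged half-labeling time with propagated 95% CI."""

    mean_thalf: float
    se_each: tuple[float, float]
    se_mean: float
    ci: tuple[float, float]


def _model_traceset(
    best: FitResult, traceset: TraceSet, spec: FitSpec, obs_map: ObservableMap
) -> list[np.ndarray]:
    """Noiseless model signal for every reaction trace at the best fit."""
    from .estimation import _model_signals  # shared residual model

    traces = traceset.reaction_traces()
    if spec.scheme is Scheme.COMPETITION:
        from .models import InitialConditions

        conditions = [
            (t, InitialConditions(t.protein_conc, t.competitor_conc, t.substrate_conc))
            for t in traces
        ]
    else:
        from .models import InitialConditions

        conditions = [
            (t, InitialConditions(t.protein_conc, t.substrate_conc)) for t in traces
        ]
    free_rates = spec.free_rates
    n_rates = len(free_rates)
    rb_index = n_rates
    s0_index = n_rates + 1 if spec.substrate_conc_adjustable else None
    theta = np.empty(n_rates + 1 + (s0_index is not None))
    for i, name in enumerate(free_rates):
        theta[i] = math.log10(best.estimates[name])
    theta[rb_index] = best.estimates["r_bound"]
    if s0_index is not None:
        nominal = traces[0].substrate_conc
        theta[s0_index] = best.adjusted_S0 / nominal if nominal > 0 else 1.0
    return _model_signals(theta, spec, obs_map, conditions, s0_index, rb_index)


def monte_carlo_ci(
    traceset: TraceSet,
    spec: FitSpec,
    obs_map: ObservableMap,
    best: FitResult,
    n: int = 1000,
    drop_frac: float = 0.05,
    seed: int | None = None,
    *,
    flavor: str = "parametric",
    max_fail_frac: float = 0.2,
) -> MCResult:
    """Monte Carlo confidence intervals for a converged global fit.

    ``n`` synthetic datasets are built from the best-fit model — with
    i.i.d. Gaussian noise at ``best.residual_sd`` (``flavor='parametric'``)
    or with resampled residuals (``flavor='residual'``) — and refitted
    from the best-fit point.  The ``drop_frac`` of refits with the
    highest final objective is excluded (ties broken by replicate index)
    before computing per-parameter sd and 2.5/97.5 percentile intervals.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for stable percentiles")
    if not best.converged:
        raise ValueError("monte_carlo_ci requires a converged best fit")
    if flavor not in ("parametric", "residual"):
        raise ValueError(f"unknown flavor {flavor!r}")
    rng = np.random.default_rng(seed)

    traces = traceset.reaction_traces()
    model = _model_traceset(best, traceset, spec, obs_map)
    residuals = [t.signal - m for t, m in zip(traces, model)]
    flat_resid = np.concatenate(residuals)

    # refits start at the best-fit point: they explore the noise-induced
    # spread around it, not the global start problem already solved
    refit_spec = FitSpec(
        scheme=spec.scheme,
        r_free=spec.r_free,
        delay_time=spec.delay_time,
        substrate_conc_adjustable=spec.substrate_conc_adjustable,
        s0_rel_bound=spec.s0_rel_bound,
        fixed=dict(spec.fixed),
        starts={name: best.estimates[name] for name in spec.free_rates},
        n_starts=1,
    )

    param_names = list(spec.free_rates) + ["r_bound", "adjusted_S0"]
    kept_rows: list[tuple[float, int, dict[str, float]]] = []
    n_failed = 0
    baseline = traceset.baseline_traces()
    for i in range(n):
        synth_traces = list(baseline)
        for t, m in zip(traces, model):
            if flavor == "parametric":
                noise = rng.normal(0.0, best.residual_sd, size=m.size)
            else:
                noise = rng.choice(flat_resid, size=m.size, replace=True)
            synth_traces.append(t.with_(signal=m + noise))
        synth = TraceSet(synth_traces, traceset.design)
        try:
            fit = global_fit(synth, refit_spec, obs_map)
        except Exception:
            n_failed += 1
            continue
        row = {name: fit.estimates[name] for name in spec.free_rates}
        row["r_bound"] = fit.estimates["r_bound"]
        row["adjusted_S0"] = fit.adjusted_S0
        kept_rows.append((fit.objective, i, row))

    if n_failed > max_fail_frac * n:
        raise MCInstabilityError(
            f"{n_failed}/{n} Monte Carlo refits failed to converge"
        )

    # non-convergent refits count toward the excluded "worst" fraction
    n_keep = round(n * (1.0 - drop_frac))
    n_drop_converged = max(0, (n - n_keep) - n_failed)
    kept_rows.sort(key=lambda r: (r[0], r[1]))  # worst = highest objective
    if n_drop_converged > 0:
        kept_rows = kept_rows[:-n_drop_converged]
    if not kept_rows:
        raise MCInstabilityError("no Monte Carlo refits survived exclusion")

    samples = {
        name: np.array([row[2][name] for row in kept_rows]) for name in param_names
    }
    sd = {name: float(np.std(vals, ddof=1)) for name, vals in samples.items()}
    ci = {
        name: (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
        for name, vals in samples.items()
    }
    return MCResult(
        samples=samples,
        n_requested=n,
        n_kept=len(kept_rows),
        sd=sd,
        ci=ci,
    )


def propagate_duplicate_ci(
    t1: float,
    ci1: tuple[float, float],
    t2: float,
    ci2: tuple[float, float],
    *,
    textbook: bool = False,
) -> ReplicateSummary:
    """Combine the half-labeling times of a biological duplicate.

    mean = (t1 + t2) / 2;  SE_i = (CI_high - CI_low) / (2 * 1.96);
    SE_mean = sqrt((SE1^2 + SE2^2) / 2);  CI = mean +/- 1.96 * SE_mean.

    With ``textbook=True`` the pooled standard error uses the
    conventional standard-error-of-the-mean denominator
    (sqrt((SE1^2 + SE2^2)) / 2, i.e. dividing the summed squares by 4).
    """
    for label, (lo, hi) in (("ci1", ci1), ("ci2", ci2)):
        if hi <= lo:
            raise ValueError(f"{label} is inverted or empty: ({lo}, {hi})")
    mean = 0.5 * (t1 + t2)
    se1 = (ci1[1] - ci1[0]) / (2.0 * 1.96)
    se2 = (ci2[1] - ci2[0]) / (2.0 * 1.96)
    denom = 4.0 if textbook else 2.0
    se_mean = math.sqrt((se1**2 + se2**2) / denom)
    half = 1.96 * se_mean
    return ReplicateSummary(
        mean_thalf=mean,
        se_each=(se1, se2),
        se_mean=se_mean,
        ci=(mean - half, mean + half),
    )
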