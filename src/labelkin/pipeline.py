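"""Config-driven pipeline: simulate and/or preprocess → fit → Monte Carlo.

The YAML config names the stages to run::

    seed: 1
    design:                       # either a template to simulate ...
      template: platereader_std
      noise_sd: 4.8               # optional override
    truth:                        # ... with this ground truth,
      scheme: model1
      k_app: 1.51e5
    # design: {input: traces.csv} # ... or an existing trace CSV
    observables:
      r_free: 60.0
      r_bound: 300.0
    fit:
      scheme: model1
      substrate_conc_adjustable: true
    montecarlo:                   # optional
      n: 1000
      drop_frac: 0.05

Every run writes a fit report, a residual CSV and a manifest into the
output directory; Monte Carlo adds an MC report.
"""

from __future__ import annotations

import sys
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import io as lkio
from . import synthetic
from .estimation import FitSpec, Scheme, fit_competition, global_fit
from .models import CompetitionParams, Model1Params, Model2Params
from .observables import (
    BOUND_COMPETITION,
    BOUND_DIRECT,
    BOUND_TWOSTEP,
    ObservableMap,
)
from .preprocess import average_all_replicates, extract_baseline
from .uncertainty import monte_carlo_ci

__all__ = ["run_pipeline", "PipelineError"]

_TEMPLATES = {
    "platereader_std": synthetic.platereader_std,
    "platereader_fast": synthetic.platereader_fast,
    "stoppedflow": synthetic.stoppedflow,
    "competition": synthetic.competition,
}

_BOUND_BY_SCHEME = {
    Scheme.MODEL1: BOUND_DIRECT,
    Scheme.MODEL2: BOUND_TWOSTEP,
    Scheme.COMPETITION: BOUND_COMPETITION,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _log(quiet: bool, stage: str, msg: str) -> None:
    if not quiet:
        print(f"[{stage}] {msg}", file=sys.stderr)


def _truth_from_config(truth_cfg: Mapping[str, Any]):
    scheme = Scheme(truth_cfg["scheme"])
    if scheme is Scheme.MODEL1:
        return Model1Params(float(truth_cfg["k_app"]))
    if scheme is Scheme.MODEL2:
        return Model2Params(
            float(truth_cfg["k1"]),
            float(truth_cfg["k_minus1"]),
            float(truth_cfg["k2"]),
        )
    return CompetitionParams(
        float(truth_cfg["kS_app"]), float(truth_cfg["kI_app"])
    )


def _validate(config: Mapping[str, Any]) -> None:
    if "fit" not in config or "scheme" not in config.get("fit", {}):
        raise PipelineError("config: missing fit.scheme")
    try:
        Scheme(config["fit"]["scheme"])
    except ValueError as exc:
        raise PipelineError(f"config: unknown scheme {config['fit']['scheme']!r}") from exc
    if "design" not in config:
        raise PipelineError("config: missing design section")
    design = config["design"]
    if "template" not in design and "input" not in design:
        raise PipelineError("config: design needs 'template' or 'input'")
    if "template" in design and "truth" not in config:
        raise PipelineError("config: simulating a template requires a truth section")


def run_pipeline(
    config: Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
    quiet: bool = False,
) -> dict[str, Path]:
    """Run the configured stages; return the written output paths."""
    _validate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    outputs: dict[str, Path] = {}
    inputs: list[Path] = []
    scheme = Scheme(config["fit"]["scheme"])
    obs_cfg = config.get("observables", {})

    # --- simulate or load -------------------------------------------------
    design = config["design"]
    if "template" in design:
        name = design["template"]
        if name not in _TEMPLATES:
            raise PipelineError(f"simulate: unknown template {name!r}")
        overrides = {
            k: v for k, v in design.items() if k not in ("template", "input")
        }
        if "grid" in overrides:
            overrides["grid"] = np.asarray(overrides["grid"], dtype=float)
        for key in ("protein_ladder", "competitor_ladder"):
            if key in overrides:
                overrides[key] = tuple(float(x) for x in overrides[key])
        try:
            template = _TEMPLATES[name](seed=seed, **overrides)
            truth = _truth_from_config(config["truth"])
            obs_map = ObservableMap(
                float(obs_cfg.get("r_free", 60.0)),
                float(obs_cfg.get("r_bound", 300.0)),
                _BOUND_BY_SCHEME[scheme],
            )
            traceset = synthetic.generate(template, truth, obs_map)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"simulate: {exc}") from exc
        traces_path = out_dir / "traces.csv"
        lkio.write_traces(traceset, traces_path)
        lkio.write_truth(truth, out_dir / "truth.json", extra={"seed": seed})
        outputs["traces"] = traces_path
        outputs["truth"] = out_dir / "truth.json"
        _log(quiet, "simulate", f"{len(traceset)} traces from {name}")
    else:
        path = Path(design["input"])
        inputs.append(path)
        try:
            traceset = lkio.read_traces(path)
        except Exception as exc:
            raise PipelineError(f"read: {exc}") from exc
        _log(quiet, "read", f"{len(traceset)} traces from {path}")

    # --- preprocess -------------------------------------------------------
    try:
        averaged = average_all_replicates(traceset)
        r_free = (
            float(config["fit"]["r_free"])
            if "r_free" in config.get("fit", {})
            else extract_baseline(averaged)
        )
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    _log(quiet, "preprocess", f"{len(averaged)} condition traces, r_free={r_free:.6g}")

    # --- fit --------------------------------------------------------------
    fit_cfg = config["fit"]
    try:
        spec = FitSpec(
            scheme=scheme,
            r_free=r_free,
            delay_time=float(fit_cfg.get("delay_time", 0.0)),
            substrate_conc_adjustable=bool(
                fit_cfg.get("substrate_conc_adjustable", True)
            ),
            s0_rel_bound=float(fit_cfg.get("s0_rel_bound", 0.5)),
            fixed={k: float(v) for k, v in fit_cfg.get("fixed", {}).items()},
            n_starts=int(fit_cfg.get("n_starts", 5)),
        )
        obs_map = ObservableMap(r_free, r_free + 1.0, _BOUND_BY_SCHEME[scheme])
        fitter = fit_competition if scheme is Scheme.COMPETITION else global_fit
        fit = fitter(averaged, spec, obs_map)
    except Exception as exc:
        raise PipelineError(f"fit: {exc}") from exc
    fit_path = out_dir / "fit_report.txt"
    lkio.write_fit_report(fit, fit_path)
    outputs["fit_report"] = fit_path
    _log(quiet, "fit", f"composite_kapp={fit.composite_kapp:.6g}")

    from .uncertainty import _model_traceset  # residual CSV uses the model curve

    model = {
        t.trace_id: m
        for t, m in zip(
            averaged.reaction_traces(), _model_traceset(fit, averaged, spec, obs_map)
        )
    }
    resid_path = out_dir / "residuals.csv"
    lkio.write_residuals(averaged, model, resid_path)
    outputs["residuals"] = resid_path

    # --- Monte Carlo ------------------------------------------------------
    if "montecarlo" in config:
        mc_cfg = config["montecarlo"]
        try:
            mc = monte_carlo_ci(
                averaged,
                spec,
                obs_map,
                fit,
                n=int(mc_cfg.get("n", 1000)),
                drop_frac=float(mc_cfg.get("drop_frac", 0.05)),
                seed=seed,
                flavor=mc_cfg.get("flavor", "parametric"),
            )
        except Exception as exc:
            raise PipelineError(f"montecarlo: {exc}") from exc
        mc_path = out_dir / "mc_report.txt"
        lkio.write_mc_report(mc, mc_path)
        outputs["mc_report"] = mc_path
        _log(quiet, "montecarlo", f"kept {mc.n_kept}/{mc.n_requested}")

    outputs["manifest"] = lkio.write_manifest(
        out_dir, config=config, seed=seed, inputs=inputs
    )
    return outputs
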