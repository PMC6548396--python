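"""End-to-end analysis pipeline: scoring -> dyads -> fit -> effects -> CIs.

:func:`run_pipeline` chains every stage on one input file and writes a
report bundle into the output directory:

* ``scored.csv``             -- per-respondent scale scores (item/score input)
* ``exclusions.jsonl``       -- one JSON line per excluded dyad with reason
* ``fit.json``               -- paths, SEs, residual blocks, per-equation and
                                overall R^2
* ``distinguishability.json``-- chi2 / df / p / RMSEA of the role-equality test
* ``effects.csv``            -- the full effect decomposition, unrounded plus
                                3-d.p. display columns
* ``ci.csv``                 -- bootstrap (or Monte-Carlo) 95% intervals
* ``manifest.json``          -- config, seed, package versions, artifact list

Runs are deterministic given the input and seed, and a manifest suffices to
reproduce a run exactly (``run_from_manifest``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .dyads import SCORE_COLUMNS, build_dyads, read_wide, to_wide
from .effects import decompose
from .errors import PipelineError
from .estimate import ROLE_EQUALITY_CONSTRAINTS, fit_constrained, fit_saturated
from .inference import bootstrap_effects, monte_carlo_effects, results_frame
from .scoring import SCALE_RANGES, score_file

DIALECTS = ("item", "score", "wide")


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    dialect: str = "item"            # "item" | "score" | "wide"
    seed: int = 0
    reps: int = 5000
    ci_method: str = "bc"            # "bc" | "percentile" | "monte-carlo"
    distinguishability: bool = True
    constraints: tuple = ROLE_EQUALITY_CONSTRAINTS
    reverse_illbeing: bool = True
    column_map: dict | None = None
    check_ranges: bool = True

    def validate(self) -> None:
        if self.dialect not in DIALECTS:
            raise PipelineError("config", f"unknown dialect {self.dialect!r}")
        if not Path(self.input_path).exists():
            raise PipelineError("config", f"input not found: {self.input_path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constraints"] = [list(c) for c in self.constraints]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["constraints"] = tuple(tuple(c) for c in d.get("constraints", ROLE_EQUALITY_CONSTRAINTS))
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _fit_to_dict(fit) -> dict:
    return {
        "n": fit.n,
        "paths": fit.paths.as_dict(),
        "se": fit.se,
        "residuals": {
            "mediator_cov": np.asarray(fit.resid.mediator_cov).tolist(),
            "outcome_cov": np.asarray(fit.resid.outcome_cov).tolist(),
            "exog_mean": np.asarray(fit.resid.exog_mean).tolist(),
            "exog_cov": np.asarray(fit.resid.exog_cov).tolist(),
        },
        "r2_per_equation": fit.r2_per_equation,
        "r2_overall": fit.r2_overall,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns artifact name -> path."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- stage 1: scoring ---------------------------------------------------
    if config.dialect == "item":
        try:
            scored = score_file(config.input_path, column_map=config.column_map,
                                reverse_illbeing=config.reverse_illbeing)
        except Exception as exc:
            raise PipelineError("scoring", str(exc)) from exc
        scored_path = out_dir / "scored.csv"
        scored.to_csv(scored_path, index=False)
        artifacts["scored"] = str(scored_path)
    elif config.dialect == "score":
        scored = pd.read_csv(config.input_path)
        scored_path = out_dir / "scored.csv"
        scored.to_csv(scored_path, index=False)
        artifacts["scored"] = str(scored_path)
    else:
        scored = None

    # -- stage 2: dyad construction ----------------------------------------
    try:
        if scored is not None:
            ranges = {c: SCALE_RANGES[c] for c in SCORE_COLUMNS} if config.check_ranges else None
            dataset = build_dyads(scored, check_ranges=ranges)
        else:
            dataset = read_wide(config.input_path, column_map=config.column_map)
    except Exception as exc:
        raise PipelineError("dyad_builder", str(exc)) from exc
    excl_path = out_dir / "exclusions.jsonl"
    dataset.write_exclusion_log(excl_path)
    artifacts["exclusions"] = str(excl_path)

    # -- stage 3: saturated fit --------------------------------------------
    try:
        fit = fit_saturated(dataset)
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc
    fit_path = out_dir / "fit.json"
    fit_path.write_text(json.dumps(_fit_to_dict(fit), indent=2))
    artifacts["fit"] = str(fit_path)

    # -- stage 4: distinguishability test ----------------------------------
    if config.distinguishability:
        try:
            _, fstats = fit_constrained(dataset, config.constraints)
        except Exception as exc:
            raise PipelineError("distinguishability", str(exc)) from exc
        dist_path = out_dir / "distinguishability.json"
        dist_path.write_text(json.dumps(dataclasses.asdict(fstats), indent=2))
        artifacts["distinguishability"] = str(dist_path)

    # -- stage 5: effect decomposition -------------------------------------
    table = decompose(fit.paths)
    eff_path = out_dir / "effects.csv"
    table.as_frame().to_csv(eff_path, index=False)
    artifacts["effects"] = str(eff_path)

    # -- stage 6: resampling intervals -------------------------------------
    try:
        if config.ci_method == "monte-carlo":
            results = monte_carlo_effects(fit, draws=config.reps, seed=config.seed)
        else:
            results = bootstrap_effects(dataset, reps=config.reps,
                                        seed=config.seed, method=config.ci_method)
    except Exception as exc:
        raise PipelineError("inference", str(exc)) from exc
    ci_path = out_dir / "ci.csv"
    results_frame(results).to_csv(ci_path, index=False)
    artifacts["ci"] = str(ci_path)

    # -- stage 7: manifest --------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_dyads": dataset.n,
        "n_excluded": len(dataset.exclusions),
        "versions": {
            "dyadmed": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": artifacts,
    }
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2))
    artifacts["manifest"] = str(man_path)
    return artifacts


def run_from_manifest(manifest_path, output_dir=None) -> dict:
    """Reproduce a run exactly from its manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if output_dir is not None:
        config.output_dir = str(output_dir)
    return run_pipeline(config)
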