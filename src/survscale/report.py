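"""Run orchestration: configuration, table emission and the report bundle.

Two strictly separated modes:

* ``printed-baselines`` — scenario grids computed by exact decimal arithmetic
  from supplied baseline risks (the published table values by default).
  Touches no random state; reproduces the published excess-risk and NNH
  tables byte-for-byte on every run.
* ``full-pipeline`` — generate a synthetic cohort, fit Kaplan-Meier curves
  per endpoint, read the baselines off the fitted curves at the landmark
  horizons, and evaluate the same grids (now subject to Monte-Carlo error).
  Deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import defaults
from .cohort import CohortSpec, default_study_spec, generate_cohort, write_cohort_csv
from .hazard import calibrate_piecewise_hazard
from .km import ExtrapolationWarning, km_fit, records_from_frame, risk_at
from .scaling import RiskResult, evaluate_grid, round_half_up, scale_survival_curve

__all__ = ["RunConfig", "load_config", "run_analysis", "write_summary_tables"]

_MODES = ("printed-baselines", "full-pipeline")


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs.

    ``baselines`` maps endpoint -> {horizon: risk in percent} and is required
    in printed-baselines mode (defaults to the published values); the
    ``cohort`` block (keyword arguments for :class:`CohortSpec` minus the
    hazards, plus an optional ``landmark_survival`` map) is used only in
    full-pipeline mode.
    """

    mode: str = "printed-baselines"
    endpoints: tuple[str, ...] = defaults.ENDPOINTS
    multipliers: tuple[str, ...] = defaults.DEFAULT_MULTIPLIERS
    horizons: tuple[float, ...] = defaults.DEFAULT_HORIZONS
    baselines: Mapping[str, Mapping[float, str]] = field(
        default_factory=lambda: {
            ep: dict(v) for ep, v in defaults.PRINTED_BASELINE_RISK_PCT.items()
        }
    )
    cohort: Mapping[str, object] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0
    precision: int = 2

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not self.endpoints:
            raise ValueError("endpoints must be non-empty")
        if self.mode == "printed-baselines":
            for ep in self.endpoints:
                if ep not in self.baselines:
                    raise ValueError(
                        f"printed-baselines mode needs a baselines block for {ep!r}"
                    )
                missing = [h for h in self.horizons if float(h) not in
                           {float(k) for k in self.baselines[ep]}]
                if missing:
                    raise ValueError(
                        f"baselines[{ep!r}] missing horizons {missing}"
                    )
        object.__setattr__(self, "endpoints", tuple(self.endpoints))
        object.__setattr__(self, "multipliers", tuple(str(m) for m in self.multipliers))
        object.__setattr__(self, "horizons", tuple(float(h) for h in self.horizons))


def load_config(path) -> RunConfig:
    """Read a YAML config file into a :class:`RunConfig`."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ValueError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "baselines" in raw:
        raw["baselines"] = {
            ep: {float(h): str(v) for h, v in block.items()}
            for ep, block in raw["baselines"].items()
        }
    return RunConfig(**raw)


def _cohort_spec(config: RunConfig) -> CohortSpec:
    block = dict(config.cohort)
    landmarks = block.pop("landmark_survival", None)
    block.setdefault("seed", config.seed)
    if landmarks is not None:
        hazards = {
            ep: calibrate_piecewise_hazard(
                {float(t): float(s) for t, s in lm.items()}
            )
            for ep, lm in landmarks.items()
        }
        n = block.pop("n_subjects", defaults.DEFAULT_N_SUBJECTS)
        return CohortSpec(n_subjects=n, endpoint_hazards=hazards, **block)
    return default_study_spec(**block)


def write_summary_tables(
    results: Sequence[RiskResult],
    precision: int,
    out_dir,
    endpoint: str,
) -> dict[str, Path]:
    """Emit the excess-risk and NNH grids as CSVs with stable formatting.

    Rows are horizons, columns are multipliers.  Excess cells are percentages
    rounded half-up to ``precision`` decimals; NNH cells are integers
    (``inf`` where the excess is zero).
    """
    if results is None:
        raise ValueError("results must not be None")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    multipliers: list[float] = []
    for r in results:
        if r.scenario.multiplier not in multipliers:
            multipliers.append(r.scenario.multiplier)
    horizons = sorted({r.scenario.horizon for r in results})
    cells = {(r.scenario.horizon, r.scenario.multiplier): r for r in results}

    def _grid_csv(name: str, cell_text) -> Path:
        p = out_dir / f"{endpoint}_{name}.csv"
        header = ["horizon_years"] + [f"{m:g}x" for m in multipliers]
        lines = [",".join(header)]
        for h in horizons:
            row = [f"{h:g}"] + [cell_text(cells[(h, m)]) for m in multipliers]
            lines.append(",".join(row))
        try:
            p.write_text("\n".join(lines) + "\n")
        except OSError as exc:
            raise OSError(f"failed writing {p}: {exc}") from exc
        return p

    paths = {
        "excess": _grid_csv(
            "excess_risk", lambda r: str(r.excess_pct(precision))
        ),
        "nnh": _grid_csv(
            "nnh", lambda r: "inf" if r.nnh is None else str(r.nnh_rounded())
        ),
    }
    # baseline landmark table (one row per horizon)
    p = out_dir / f"{endpoint}_baseline.csv"
    lines = ["horizon_years,baseline_risk_pct,survival_pct"]
    for h in horizons:
        any_cell = cells[(h, multipliers[0])]
        risk = any_cell.baseline_pct(precision)
        surv = round_half_up(100 - any_cell.baseline * 100, precision)
        lines.append(f"{h:g},{risk},{surv}")
    p.write_text("\n".join(lines) + "\n")
    paths["baseline"] = p
    return paths


def run_analysis(config: RunConfig, out_dir=None) -> dict:
    """Execute one configured run and write the report bundle.

    Emits, per endpoint, the baseline landmark table, the excess-risk grid
    and the NNH grid (plus, in full-pipeline mode, the cohort CSV, the fitted
    survival table and one scaled survival table per multiplier), and a
    ``run_log.json`` recording mode, seed and versions.  Identical config and
    seed produce identical bytes.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"mode": config.mode, "out_dir": out, "endpoints": {}, "paths": []}

    curves = {}
    if config.mode == "full-pipeline":
        spec = _cohort_spec(config)
        cohort = generate_cohort(spec)
        cohort_path = out / "cohort.csv"
        write_cohort_csv(cohort, cohort_path)
        bundle["paths"].append(cohort_path)
        for ep in config.endpoints:
            curves[ep] = km_fit(records_from_frame(cohort, ep))

    for ep in config.endpoints:
        if config.mode == "printed-baselines":
            baselines = {
                float(h): config.baselines[ep][float(h)] for h in config.horizons
            }
        else:
            curve = curves[ep]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ExtrapolationWarning)
                baselines = {
                    h: float(risk_at(curve, h)) * 100 for h in config.horizons
                }
            km_path = out / f"{ep}_km.csv"
            curve.to_frame().to_csv(km_path, index=False, float_format="%.10g")
            bundle["paths"].append(km_path)
            for m in config.multipliers:
                scaled = scale_survival_curve(curve, float(m))
                sp = out / f"{ep}_scaled_{float(m):g}x.csv"
                scaled.to_frame().to_csv(sp, index=False, float_format="%.10g")
                bundle["paths"].append(sp)
        results = evaluate_grid(baselines, config.multipliers, percent=True)
        paths = write_summary_tables(results, config.precision, out, ep)
        bundle["endpoints"][ep] = {"results": results, "tables": paths}
        bundle["paths"].extend(paths.values())

    from . import __version__

    log = {
        "mode": config.mode,
        "seed": config.seed,
        "endpoints": list(config.endpoints),
        "multipliers": list(config.multipliers),
        "horizons": list(config.horizons),
        "survscale_version": __version__,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    bundle["paths"].append(log_path)
    return bundle
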