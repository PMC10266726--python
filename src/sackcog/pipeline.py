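"""End-to-end orchestration: simulate → score → analyze, from one config.

Stages communicate only through files (CSV/JSON) inside the run directory,
so each stage can be re-run or replaced independently:

    instances.json     the instance bank (generated or copied from a file)
    difficulty.csv     per-instance Sahni-k, DP complexity, optimal value
    logs.csv           simulated attempt event logs
    metrics.csv        attempt-level behavioral metrics
    rejects.csv        logs that failed replay (if any)
    ladder_<outcome>.csv, coefficients_<outcome>.csv, raneff_<outcome>.csv
    ecdf_<outcome>.csv, dominance.csv
    reversal.csv, wilcoxon.csv
    manifest.json      config echo, seed, output hashes, library versions

The manifest contains no timestamps, so a re-run with the same config and
seed produces byte-identical artifacts and manifest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import CONDITIONS, read_event_logs, score_dataset, write_event_logs
from .instances import (
    Instance,
    generate_instance_bank,
    read_instances,
    write_instances,
)
from .simulate import AgentParams, CohortDesign, ConditionEffects, simulate_cohort
from .solvers import difficulty_profile_for
from .stats import (
    ModelFitError,
    ModelSpec,
    default_ladder,
    dominance_check,
    ecdf_band,
    effect_reversal_analysis,
    fit_mixed_model,
    model_selection,
    wilcoxon_squared_effects,
)

__all__ = ["RunConfig", "run_pipeline", "make_report"]

_ECDF_OUTCOMES = ("value_fraction", "time_s", "n_moves")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    out_dir: Path
    instance_path: Path | None = None
    n_instances: int = 8
    n_items: tuple[int, ...] = (10, 12)
    value_range: tuple[int, int] = (1, 100)
    weight_range: tuple[int, int] = (1, 100)
    capacity_fraction: float = 0.5
    n_participants: int = 40
    attempts_per_instance: int = 2
    ability_sd: float = 1.0
    agent: AgentParams = field(default_factory=AgentParams)
    effects: ConditionEffects = field(default_factory=ConditionEffects)
    outcomes: tuple[str, ...] = ("correct", "time_s", "n_moves", "productivity")
    criterion: str = "AIC"
    attempts_filter: str = "both"  # "both" | "first"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.instance_path is not None:
            self.instance_path = Path(self.instance_path)
            if not self.instance_path.exists():
                raise PipelineError(
                    f"config validation: instance file {self.instance_path} does not exist"
                )
        if self.criterion not in ("AIC", "BIC"):
            raise PipelineError("config validation: criterion must be AIC or BIC")
        if self.attempts_filter not in ("both", "first"):
            raise PipelineError("config validation: attempts_filter must be 'both' or 'first'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        if "seed" not in doc:
            raise PipelineError("config validation: 'seed' is mandatory")
        inst = doc.get("instances", {}) or {}
        cohort = doc.get("cohort", {}) or {}
        agent = doc.get("agent", {}) or {}
        effects = doc.get("effects", None)
        analysis = doc.get("analysis", {}) or {}
        eff = ConditionEffects(**{k: dict(v) for k, v in effects.items()}) if effects else ConditionEffects()
        return cls(
            seed=int(doc["seed"]),
            out_dir=Path(doc.get("out_dir", "sackcog-run")),
            instance_path=inst.get("path"),
            n_instances=int(inst.get("n_instances", 8)),
            n_items=tuple(inst.get("n_items", (10, 12))),
            value_range=tuple(inst.get("value_range", (1, 100))),
            weight_range=tuple(inst.get("weight_range", (1, 100))),
            capacity_fraction=float(inst.get("capacity_fraction", 0.5)),
            n_participants=int(cohort.get("n_participants", 40)),
            attempts_per_instance=int(cohort.get("attempts_per_instance", 2)),
            ability_sd=float(cohort.get("ability_sd", 1.0)),
            agent=AgentParams(**agent),
            effects=eff,
            outcomes=tuple(analysis.get("outcomes", ("correct", "time_s", "n_moves", "productivity"))),
            criterion=str(analysis.get("criterion", "AIC")),
            attempts_filter=str(analysis.get("attempts", "both")),
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["instance_path"] = None if self.instance_path is None else str(self.instance_path)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; return (and write) the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    # -- stage 1: instances ------------------------------------------------
    try:
        if config.instance_path is not None:
            bank = read_instances(config.instance_path)
        else:
            bank = generate_instance_bank(
                config.n_instances, seed=config.seed, n_items=config.n_items,
                value_range=config.value_range, weight_range=config.weight_range,
                capacity_fraction=config.capacity_fraction,
                min_distinct_sahni=2,
            )
        write_instances(bank, out / "instances.json")
        rows = []
        for inst in bank:
            prof, solved = difficulty_profile_for(inst)
            rows.append(
                {"instance_id": inst.instance_id, "n_items": inst.n_items,
                 "sahni_k": prof.sahni_k, "dp_complexity": prof.dp_complexity,
                 "optimal_value": solved.optimal_value}
            )
        _write_csv(pd.DataFrame(rows), out / "difficulty.csv")
    except Exception as exc:
        raise PipelineError(f"stage 'instances': {exc}") from exc

    # -- stage 2: simulate -------------------------------------------------
    try:
        design = CohortDesign(
            n_participants=config.n_participants,
            n_instances=len(bank),
            attempts_per_instance=config.attempts_per_instance,
        )
        logs = simulate_cohort(design, config.effects, bank, seed=config.seed,
                               ability_sd=config.ability_sd,
                               base_params=config.agent)
        write_event_logs(logs, out / "logs.csv")
    except Exception as exc:
        raise PipelineError(f"stage 'simulate': {exc}") from exc

    # -- stage 3: score ----------------------------------------------------
    try:
        metrics, rejects = score_dataset(logs, bank)
        if config.attempts_filter == "first":
            metrics = metrics[metrics["attempt_no"] == 1]
        _write_csv(metrics, out / "metrics.csv")
        if len(rejects):
            _write_csv(rejects, out / "rejects.csv")
            warnings_log.append(f"{len(rejects)} logs failed replay")
    except Exception as exc:
        raise PipelineError(f"stage 'score': {exc}") from exc

    # -- stage 4: analyze --------------------------------------------------
    failed_outcomes: dict[str, str] = {}
    try:
        for outcome in config.outcomes:
            try:
                best, ladder = model_selection(
                    default_ladder(outcome), metrics, config.criterion
                )
            except ModelFitError as exc:
                failed_outcomes[outcome] = str(exc)
                continue
            _write_csv(ladder, out / f"ladder_{outcome}.csv")
            _write_csv(best.coefficients().reset_index(names="term"),
                       out / f"coefficients_{outcome}.csv")
            if best.random_effects is not None:
                _write_csv(best.random_effects.reset_index(names="participant_id"),
                           out / f"raneff_{outcome}.csv")
            if best.singular:
                warnings_log.append(f"{outcome}: selected model has singular random effects")

        # distribution comparisons, PLC vs pooled drugs
        dom_rows = []
        for outcome in _ECDF_OUTCOMES:
            if outcome not in metrics.columns:
                continue
            a = metrics.loc[metrics["condition"] == "PLC", outcome].dropna().values
            b = metrics.loc[metrics["drug"] == 1, outcome].dropna().values
            if len(a) < 2 or len(b) < 2:
                continue
            band_a, band_b = ecdf_band(a), ecdf_band(b)
            pd.DataFrame(
                {"grid": band_a.grid, "F_plc": band_a.F,
                 "lower_plc": band_a.lower, "upper_plc": band_a.upper}
            ).to_csv(out / f"ecdf_{outcome}.csv", index=False, float_format="%.10g")
            rep = dominance_check(band_a, band_b)
            dom_rows.append(
                {"outcome": outcome, "frac_plc_below": rep.frac_a_below,
                 "frac_drug_below": rep.frac_b_below,
                 "frac_separated": rep.frac_separated,
                 "direction": {"A": "PLC", "B": "drug"}.get(rep.direction, "none")}
            )
        _write_csv(pd.DataFrame(dom_rows), out / "dominance.csv")

        # productivity heterogeneity: per-condition random effects
        rev_rows, wil_rows = [], []
        try:
            prod_fit = fit_mixed_model(
                ModelSpec("productivity", ("sahni_k", "condition"), "condition"),
                metrics,
            )
            for drug_cond in ("MPH", "DEX", "MOD"):
                rep = effect_reversal_analysis(prod_fit, "PLC", drug_cond)
                rev_rows.append(asdict(rep))
                stat, p = wilcoxon_squared_effects(
                    prod_fit.random_effects["PLC"].values,
                    prod_fit.random_effects[drug_cond].values,
                )
                wil_rows.append({"pair": f"PLC~{drug_cond}", "statistic": stat, "p": p})
        except (ModelFitError, ValueError) as exc:
            warnings_log.append(f"productivity reversal analysis failed: {exc}")
        _write_csv(pd.DataFrame(rev_rows), out / "reversal.csv")
        _write_csv(pd.DataFrame(wil_rows), out / "wilcoxon.csv")
    except Exception as exc:
        raise PipelineError(f"stage 'analyze': {exc}") from exc

    # -- manifest ----------------------------------------------------------
    import scipy
    import statsmodels

    outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "sackcog_version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__, "statsmodels": statsmodels.__version__},
        "outputs": {name: _sha256(out / name) for name in outputs},
        "failed_outcomes": failed_outcomes,
        "warnings": warnings_log,
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def make_report(run_dir: str | Path) -> str:
    """Assemble a human-readable summary from a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise PipelineError(f"incomplete run: {manifest_path} missing")
    manifest = json.loads(manifest_path.read_text())
    required = ["metrics.csv", "difficulty.csv", "dominance.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise PipelineError(f"incomplete run: missing artifacts {missing}")

    lines = [
        "# Knapsack cohort analysis report",
        "",
        f"seed: {manifest['seed']}  sackcog {manifest['sackcog_version']}",
        "",
    ]
    metrics = pd.read_csv(run_dir / "metrics.csv")
    by_cond = metrics.groupby("condition")[
        [c for c in ("correct", "value_fraction", "time_s", "n_moves", "productivity")
         if c in metrics.columns]
    ].mean()
    lines += ["## Condition means", "", by_cond.round(4).to_string(), ""]

    outcomes = manifest["config"]["outcomes"]
    for outcome in outcomes:
        lines.append(f"## Outcome: {outcome}")
        lines.append("")
        if outcome in manifest.get("failed_outcomes", {}):
            lines.append(f"MODEL SELECTION FAILED: {manifest['failed_outcomes'][outcome]}")
            lines.append("")
            continue
        ladder = pd.read_csv(run_dir / f"ladder_{outcome}.csv")
        coefs = pd.read_csv(run_dir / f"coefficients_{outcome}.csv")
        lines.append(f"best model: {ladder.iloc[0]['model']}")
        lines.append("")
        lines.append(coefs.round(5).to_string(index=False))
        lines.append("")
    dom = pd.read_csv(run_dir / "dominance.csv")
    if len(dom):
        lines += ["## ECDF dominance (PLC vs pooled drugs)", "",
                  dom.round(4).to_string(index=False), ""]
    rev_path = run_dir / "reversal.csv"
    if rev_path.exists():
        rev = pd.read_csv(rev_path)
        if len(rev):
            lines += ["## Productivity random-effect shrinkage/reversal", "",
                      rev.round(4).to_string(index=False), ""]
    wil_path = run_dir / "wilcoxon.csv"
    if wil_path.exists():
        wil = pd.read_csv(wil_path)
        if len(wil):
            lines += ["## Wilcoxon squared-random-effect exchangeability", "",
                      wil.round(5).to_string(index=False), ""]
    if manifest.get("warnings"):
        lines += ["## Warnings", ""] + [f"- {w}" for w in manifest["warnings"]] + [""]
    report = "\n".join(lines)
    (run_dir / "report.md").write_text(report, encoding="utf-8")
    return report
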