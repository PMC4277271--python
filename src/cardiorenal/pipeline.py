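"""End-to-end analysis pipeline: filter, baseline, classify, compare, survive.

One :class:`RunConfig` (buildable from YAML) drives the whole analysis, from
either an on-disk cohort (``patients.csv`` + ``measurements.csv``) or a
simulation config. Outputs are plain CSV/JSON files mirroring the report
tables of an AKI-criteria comparison study, plus a run log recording the
seed, package version and every decision knob in effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .baseline import NormalRange, PRESUMED_GFR, MDRD_COEFFICIENT, estimate_baseline
from .classify import classify_cohort
from .cohort import apply_exclusions, read_cohort, write_cohort
from .concordance import build_report
from .simulate import HazardConfig, SimulationConfig, generate_cohort, simulate_outcomes
from .survival import DEFAULT_ADJUSTMENT, km_curves_frame, mortality_table, survival_report

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_dir`` (cohort CSVs) or ``simulation`` must be set.
    """

    out_dir: str = "results"
    seed: int = 0
    input_dir: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    normal_upper_male_umol: float = 104.0
    normal_upper_female_umol: float = 84.0
    presumed_gfr: float = PRESUMED_GFR
    mdrd_coefficient: float = MDRD_COEFFICIENT
    akin_relative_reference: str = "pair"
    adjusted_covariates: list[str] = field(default_factory=lambda: list(DEFAULT_ADJUSTMENT))

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.simulation is None):
            raise ValueError("exactly one of input_dir / simulation must be provided")

    @property
    def normal_range(self) -> NormalRange:
        return NormalRange(self.normal_upper_male_umol, self.normal_upper_female_umol)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            hazard = sim.pop("hazard", None)
            if hazard is not None:
                sim["hazard"] = HazardConfig(**hazard)
            if "archetype_mix" in sim:
                sim["archetype_mix"] = dict(sim["archetype_mix"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _decision_knobs(config: RunConfig) -> dict:
    return {
        "normal_upper_male_umol": config.normal_upper_male_umol,
        "normal_upper_female_umol": config.normal_upper_female_umol,
        "presumed_gfr": config.presumed_gfr,
        "mdrd_coefficient": config.mdrd_coefficient,
        "akin_relative_reference": config.akin_relative_reference,
        "adjusted_covariates": config.adjusted_covariates,
        "ties": "breslow",
        "detection_window_hours": 168.0,
        "pair_window_hours": 48.0,
        "threshold_comparisons": "inclusive (>=)",
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report files under ``out_dir``.

    Returns the run report (also written as ``run_log.json``). Any stage
    failure raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "decisions": _decision_knobs(config),
    }

    # -- acquire ---------------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation
            cohort, truth = generate_cohort(sim)
            report["source"] = {"kind": "simulation", "n": sim.n, "seed": sim.seed}
        else:
            cohort = read_cohort(config.input_dir)
            truth = None
            report["source"] = {"kind": "files", "input_dir": str(config.input_dir)}
    except Exception as exc:
        raise PipelineError("acquire", str(exc)) from exc

    # -- filter ----------------------------------------------------------
    try:
        cohort, tally = apply_exclusions(cohort)
        report["exclusions"] = tally
        report["n_retained"] = len(cohort)
    except Exception as exc:
        raise PipelineError("filter", str(exc)) from exc
    if len(cohort) == 0:
        report["status"] = "empty_cohort_after_exclusions"
        (out / "run_log.json").write_text(json.dumps(report, indent=2))
        return report

    # -- baseline + classify --------------------------------------------
    try:
        baselines = {
            p.patient_id: estimate_baseline(
                p,
                config.normal_range,
                presumed_gfr=config.presumed_gfr,
                coefficient=config.mdrd_coefficient,
            )
            for p in cohort
        }
        table = classify_cohort(
            cohort, baselines, relative_reference=config.akin_relative_reference
        )
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # -- synthetic outcomes ---------------------------------------------
    if config.simulation is not None:
        try:
            import numpy as np

            rng = np.random.default_rng(
                np.random.SeedSequence([config.simulation.seed, 104729])
            )
            outcomes = simulate_outcomes(cohort, table, config.simulation.hazard, rng)
            truth = truth.merge(outcomes, on="patient_id")
            write_cohort(cohort, out / "cohort")
            truth.to_csv(out / "sim_truth.csv", index=False)
        except Exception as exc:
            raise PipelineError("outcomes", str(exc)) from exc

    # -- compare ---------------------------------------------------------
    try:
        table.write_csv(out / "classifications.csv")
        concordance = build_report(table)
        concordance.incidence.to_csv(out / "incidence.csv", index=False)
        concordance.write_json(out / "concordance.json")
        report["incidence"] = concordance.incidence.to_dict(orient="records")
        report["discordant_counts"] = {
            k: len(v) for k, v in concordance.discordant.items()
        }
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    # -- survive ---------------------------------------------------------
    try:
        mt = mortality_table(table, cohort)
        mt.to_csv(out / "mortality_table.csv", index=False)
        surv = survival_report(cohort, table, config.adjusted_covariates)
        (out / "survival_report.json").write_text(json.dumps(surv, indent=2))
        km = km_curves_frame(cohort, table)
        km.to_csv(out / "km_curves.csv", index=False)
        report["mortality"] = mt.to_dict(orient="records")
        report["survival"] = surv
    except Exception as exc:
        raise PipelineError("survive", str(exc)) from exc

    report["status"] = "ok"
    (out / "run_log.json").write_text(json.dumps(report, indent=2))
    return report
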