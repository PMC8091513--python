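"""Scenario orchestration: replications, weights, fits, summaries, files.

Each replication simulates one phase-I cohort, fits the full-cohort Cox model
(the efficiency benchmark), then draws every requested phase-II design from
the *same* cohort with its own random substream.  Sharing cohorts across
designs (common random numbers) sharpens between-design contrasts at a given
number of replications; substreams are spawned deterministically from the
root seed, so results are bitwise reproducible and independent of the design
list's composition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from phasetwo.inclusion_weights import (
    WeightSet,
    cm_probs,
    empirical_probs,
    ncc_probs,
    post_stratify,
)
from phasetwo.performance_metrics import summaries_table
from phasetwo.sampling_designs import (
    Design,
    DesignSpec,
    PhaseTwoSample,
    build_strata,
    draw_phase2,
    phase2_table,
)
from phasetwo.synthetic_cohort import ScenarioConfig, read_cohort, simulate_cohort
from phasetwo.weighted_cox import fit_weighted_cox, twophase_variance, wald_test

logger = logging.getLogger(__name__)

__all__ = [
    "RunResult",
    "run_scenario",
    "apply_design",
    "compute_weights",
    "standard_designs",
]


def standard_designs(
    n_target: int = 600,
    m: int = 1,
    names: list[str] | None = None,
) -> list[DesignSpec]:
    """The benchmark battery of phase-II designs at a common target size.

    Covers simple random sampling, proportional allocation stratified by the
    event alone or crossed with each phase-I covariate, case-control likewise,
    case-control post-stratified by the surrogate, nested case-control and
    counter-matching on the surrogate.  ``names`` selects a subset.
    """
    catalogue = [
        DesignSpec(Design.SRS, n_target, name="srs"),
        DesignSpec(Design.PPS, n_target, name="pps"),
        DesignSpec(Design.PPS, n_target, strata_vars=("x_risk",), name="pps_risk"),
        DesignSpec(Design.PPS, n_target, strata_vars=("x_conf",), name="pps_conf"),
        DesignSpec(Design.PPS, n_target, strata_vars=("x_surr",), name="pps_surr"),
        DesignSpec(Design.CC, n_target, name="cc"),
        DesignSpec(Design.CC, n_target, strata_vars=("x_risk",), name="cc_risk"),
        DesignSpec(Design.CC, n_target, strata_vars=("x_conf",), name="cc_conf"),
        DesignSpec(Design.CC, n_target, strata_vars=("x_surr",), name="cc_surr"),
        DesignSpec(
            Design.CC, n_target, post_stratify_vars=("x_surr",), name="cc_post_surr"
        ),
        DesignSpec(Design.NCC, n_target, controls_per_case=m, name="ncc"),
        DesignSpec(
            Design.CM, n_target, controls_per_case=m,
            cm_stratum_var="x_surr", name="cm",
        ),
    ]
    if names is None:
        return catalogue
    by_name = {spec.name: spec for spec in catalogue}
    unknown = [n for n in names if n not in by_name]
    if unknown:
        raise ValueError(f"unknown design names {unknown}; choose from {sorted(by_name)}")
    return [by_name[n] for n in names]


def compute_weights(
    cohort: pd.DataFrame, sample: PhaseTwoSample, spec: DesignSpec
) -> WeightSet:
    """Design-appropriate inclusion probabilities and weights for one draw."""
    design = spec.design
    if design in (Design.SRS, Design.PPS, Design.CC):
        ws = empirical_probs(sample)
        if spec.post_stratify_vars:
            post = build_strata(cohort, spec.post_stratify_vars)
            ws = post_stratify(ws, sample, post)
        return ws
    if design is Design.NCC:
        return ncc_probs(cohort, sample, spec.controls_per_case)
    if design is Design.CM:
        return cm_probs(cohort, sample, spec.cm_stratum_var, spec.controls_per_case)
    raise ValueError(f"unknown design {design!r}")


@dataclass
class RunResult:
    records: pd.DataFrame
    summaries: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(out / "records.csv", index=False)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _record(scenario, design, rep, fit, reject, realized_n, n_excluded, error=""):
    if fit is not None and fit.converged:
        bm = fit["x_bm"]
        return {
            "scenario": scenario, "design": design, "rep": rep,
            "estimate": bm["coef"], "se": bm["se"],
            "ci_low": bm["ci95"][0], "ci_high": bm["ci95"][1],
            "p": bm["p"], "reject": bool(reject),
            "realized_n": realized_n, "converged": True,
            "n_excluded": n_excluded, "error": error,
        }
    return {
        "scenario": scenario, "design": design, "rep": rep,
        "estimate": np.nan, "se": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "reject": np.nan,
        "realized_n": realized_n, "converged": False,
        "n_excluded": n_excluded, "error": error,
    }


def run_scenario(
    config: ScenarioConfig,
    designs: list[DesignSpec],
    B: int,
    seed: int | None = None,
    covariates=("x_bm", "x_conf"),
    scenario_id: str = "scenario",
    fit_full: bool = True,
) -> RunResult:
    """Replicate a scenario end to end.

    For each of the B replications: simulate a cohort, fit the full-cohort
    model, then for each design draw the phase-II sample, compute weights,
    fit the weighted Cox model with design-based variance, and run the 5%
    Wald test on the biomarker.  A failing design replication is recorded as
    non-converged and the run continues.
    """
    root_seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(root_seed)
    rows = []
    for rep, rep_ss in enumerate(root.spawn(B)):
        streams = rep_ss.spawn(1 + len(designs))
        cohort = simulate_cohort(config, rng=np.random.default_rng(streams[0]))
        if fit_full:
            try:
                fit = fit_weighted_cox(cohort, None, covariates)
                reject, _ = wald_test(fit, "x_bm")
                rows.append(_record(scenario_id, "full", rep, fit, reject, len(cohort), 0))
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("rep %d full-cohort fit failed: %s", rep, exc)
                rows.append(_record(scenario_id, "full", rep, None, None, len(cohort), 0, str(exc)))
        for spec, ss in zip(designs, streams[1:]):
            rng = np.random.default_rng(ss)
            try:
                sample = draw_phase2(cohort, spec, rng)
                ws = compute_weights(cohort, sample, spec)
                fit = fit_weighted_cox(cohort, ws, covariates)
                fit.set_variance(twophase_variance(fit, sample, ws))
                reject, _ = wald_test(fit, "x_bm")
                rows.append(
                    _record(
                        scenario_id, spec.name, rep, fit, reject,
                        sample.realized_n, ws.n_excluded,
                    )
                )
            except Exception as exc:
                logger.warning("rep %d design %s failed: %s", rep, spec.name, exc)
                rows.append(_record(scenario_id, spec.name, rep, None, None, 0, 0, str(exc)))

    records = pd.DataFrame(rows)
    srs_name = next((s.name for s in designs if s.design is Design.SRS), None)
    summaries = summaries_table(
        records, true_beta=config.beta_bm, srs_design=srs_name, full_design="full"
    )
    manifest = {
        "scenario_id": scenario_id,
        "config": config.to_dict(),
        "designs": [
            {**dataclasses.asdict(s), "design": s.design.value} for s in designs
        ],
        "B": B,
        "seed": int(root_seed),
        "covariates": list(covariates),
        "version": _version(),
        "realized_n": {
            name: float(grp["realized_n"].mean())
            for name, grp in records.groupby("design")
        },
    }
    return RunResult(records, summaries, manifest)


def _version() -> str:
    from phasetwo import __version__

    return __version__


def apply_design(
    cohort_file: str | Path,
    spec: DesignSpec,
    seed: int = 0,
    out_file: str | Path | None = None,
) -> pd.DataFrame:
    """Draw one phase-II sample from a user-supplied cohort table.

    Reads the documented cohort schema, draws the design, attaches inclusion
    probabilities and weights, and (optionally) writes the augmented table.
    No model fitting.
    """
    cohort = read_cohort(cohort_file)
    rng = np.random.default_rng(seed)
    sample = draw_phase2(cohort, spec, rng)
    ws = compute_weights(cohort, sample, spec)
    table = phase2_table(cohort, sample, weights=ws)
    if out_file is not None:
        table.to_csv(out_file, index=False)
    return table
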