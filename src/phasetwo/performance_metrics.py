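"""Replication-level performance measures.

Given B replicated fits of the biomarker log hazard ratio under one design,
the summary reports bias, empirical SE, MSE (= bias^2 + SE^2), coverage and
mean length of the 95% CI, power of the 5% Wald test, and relative-efficiency
ratios: the design effect (mean model-based variance under SRS over the same
under the design — values above 1 mean the design beats simple random
sampling at equal size) and efficiency versus the full-cohort fit.  The
standardized bias is 100 * bias / empirical SE.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PerformanceSummary", "summarize", "summaries_table", "power_curve"]

#: required columns of a replication record table
RECORD_COLUMNS = [
    "scenario", "design", "rep", "estimate", "se",
    "ci_low", "ci_high", "reject", "realized_n", "converged",
]


@dataclass(frozen=True)
class PerformanceSummary:
    bias: float
    empirical_se: float
    mse: float
    coverage: float
    ci_length: float
    power: float
    mean_realized_n: float
    standardized_bias: float
    mean_model_variance: float
    design_effect: float = np.nan
    design_effect_mse: float = np.nan
    design_effect_empirical: float = np.nan
    efficiency_vs_full: float = np.nan
    n_replications: int = 0
    n_converged: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _converged(records: pd.DataFrame) -> pd.DataFrame:
    conv = records[records["converged"].astype(bool)]
    if len(conv) < 2:
        raise ValueError("need at least two converged replications to summarize")
    return conv


def summarize(
    records: pd.DataFrame,
    true_beta: float,
    srs_records: pd.DataFrame | None = None,
    full_records: pd.DataFrame | None = None,
) -> PerformanceSummary:
    """Aggregate one design's replication records.

    ``srs_records`` / ``full_records`` are same-scenario references for the
    design-effect and efficiency ratios; without them those fields are NaN.
    Non-converged replications are excluded and counted.
    """
    conv = _converged(records)
    est = conv["estimate"].to_numpy(dtype=float)
    bias = float(est.mean() - true_beta)
    emp_se = float(est.std(ddof=1))
    mse = bias**2 + emp_se**2
    coverage = float(
        ((conv["ci_low"] <= true_beta) & (true_beta <= conv["ci_high"])).mean()
    )
    ci_length = float((conv["ci_high"] - conv["ci_low"]).mean())
    power = float(conv["reject"].astype(float).mean())
    mean_var = float((conv["se"] ** 2).mean())

    deff = deff_mse = deff_emp = eff_full = np.nan
    if srs_records is not None:
        srs = _converged(srs_records)
        srs_est = srs["estimate"].to_numpy(dtype=float)
        srs_bias = float(srs_est.mean() - true_beta)
        srs_emp = float(srs_est.std(ddof=1))
        deff = float((srs["se"] ** 2).mean()) / mean_var
        deff_mse = (srs_bias**2 + srs_emp**2) / mse
        deff_emp = srs_emp**2 / emp_se**2
    if full_records is not None:
        full = _converged(full_records)
        eff_full = float((full["se"] ** 2).mean()) / mean_var

    return PerformanceSummary(
        bias=bias,
        empirical_se=emp_se,
        mse=mse,
        coverage=coverage,
        ci_length=ci_length,
        power=power,
        mean_realized_n=float(conv["realized_n"].mean()),
        standardized_bias=100.0 * bias / emp_se if emp_se > 0 else 0.0,
        mean_model_variance=mean_var,
        design_effect=deff,
        design_effect_mse=deff_mse,
        design_effect_empirical=deff_emp,
        efficiency_vs_full=eff_full,
        n_replications=int(len(records)),
        n_converged=int(len(conv)),
    )


def summaries_table(
    records: pd.DataFrame,
    true_beta: float,
    srs_design: str | None = "srs",
    full_design: str = "full",
) -> pd.DataFrame:
    """One summary row per design in a combined record table."""
    by_design = {name: grp for name, grp in records.groupby("design", sort=False)}
    srs = by_design.get(srs_design)
    full = by_design.get(full_design)
    rows = []
    for name, grp in by_design.items():
        try:
            summ = summarize(
                grp,
                true_beta,
                srs_records=None if name == srs_design else srs,
                full_records=None if name == full_design else full,
            )
        except ValueError as exc:
            logger.warning("design %s not summarized: %s", name, exc)
            continue
        rows.append({"design": name, **summ.to_dict()})
    return pd.DataFrame(rows)


def power_curve(
    config,
    design_spec,
    n_grid,
    B: int,
    seed: int,
    covariates=("x_bm", "x_conf"),
) -> pd.DataFrame:
    """Power of the 5% Wald test on the biomarker versus phase-II size.

    The same root seed is reused for every n (common random numbers), so the
    curve is smoother than independent runs at equal B.  Risk-set designs cap
    their realized size at (1 + m) * #events; the realized mean is reported
    next to the planned n.
    """
    from phasetwo.engine import run_scenario  # local import: engine uses this module

    rows = []
    for n in n_grid:
        spec = dataclasses.replace(design_spec, n_target=int(n))
        res = run_scenario(config, [spec], B=B, seed=seed, covariates=covariates)
        summ = res.summaries.set_index("design").loc[spec.name]
        rows.append(
            {
                "n": int(n),
                "power": float(summ["power"]),
                "mean_realized_n": float(summ["mean_realized_n"]),
                "n_converged": int(summ["n_converged"]),
            }
        )
        if rows[-1]["mean_realized_n"] < n:
            logger.info(
                "design %s reached mean realized n=%.1f below planned n=%d",
                spec.name, rows[-1]["mean_realized_n"], n,
            )
    return pd.DataFrame(rows)
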