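"""Phase-I cohort generation.

The generative model is a cohort of ``N`` subjects followed up to an
administrative horizon ``tau``:

* binary confounder ``x_conf ~ Bernoulli(p_conf)`` (affects biomarker and event),
* binary risk factor ``x_risk ~ Bernoulli(p_risk)`` (affects the event only),
* binary biomarker ``x_bm`` with logistic dependence on the confounder,
  ``P(x_bm=1 | x_conf) = expit(a + b * x_conf)``,
* binary surrogate ``x_surr`` with logistic dependence on the biomarker,
  ``P(x_surr=1 | x_bm) = expit(c + d * x_bm)`` — its intercept/slope encode the
  surrogate's specificity and sensitivity,
* event time ``T`` from a Weibull proportional-hazards model with shape ``p``
  and scale ``lambda``: ``T = (-log U / (lambda * exp(beta'X)))**(1/p)``,
* random censoring ``C ~ Exponential(rate=censor_rate)`` truncated at ``tau``.

The observed data are ``Z = min(T, C)`` and the event indicator
``event = I(T < C)``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, optimize, special, stats

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "expit_link",
    "inverse_weibull_time",
    "simulate_cohort",
    "burton_replications",
    "expected_event_fraction",
    "marginal_biomarker_prevalence",
    "calibrate_nuisance_log_hr",
    "read_cohort",
    "write_cohort",
]

#: column order of the on-disk cohort table
COHORT_COLUMNS = ["id", "obs_time", "event", "x_bm", "x_conf", "x_risk", "x_surr"]


@dataclass(frozen=True)
class ScenarioConfig:
    """All generative and design parameters of one simulation scenario.

    Times are in the (arbitrary) unit of the Weibull model; coefficients are
    log hazard ratios.
    """

    n_phase1: int = 2000
    tau: float = 2.0
    weibull_shape: float = 0.9
    weibull_scale: float = 0.1
    beta_bm: float = math.log(1.5)
    beta_conf: float = math.log(1.5)
    beta_risk: float = math.log(1.5)
    bm_intercept: float = -2.0
    bm_slope: float = 1.7
    surr_intercept: float = float(special.logit(0.3))
    surr_slope: float = float(special.logit(0.7) - special.logit(0.3))
    p_conf: float = 0.5
    p_risk: float = 0.4
    censor_rate: float = 0.0
    phase2_n: int = 600
    controls_per_case: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phase1 <= 0:
            raise ValueError("n_phase1 must be positive")
        for name in ("tau", "weibull_shape", "weibull_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("p_conf", "p_risk"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.phase2_n <= 0:
            raise ValueError("phase2_n must be positive")
        if self.phase2_n > self.n_phase1:
            raise ValueError("phase2_n must not exceed n_phase1")
        if self.controls_per_case <= 0:
            raise ValueError("controls_per_case must be positive")

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a scenario from YAML or JSON keyed exactly by the field names."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def expit_link(intercept: float, slope: float, x) -> float | np.ndarray:
    """Logistic success probability ``expit(intercept + slope * x)``."""
    return special.expit(intercept + slope * np.asarray(x, dtype=float))


def inverse_weibull_time(u, linear_predictor, scale: float, shape: float):
    """Event time by inversion of the Weibull proportional-hazards survival.

    ``T = (-log(u) / (scale * exp(linear_predictor)))**(1/shape)``, so that
    ``u`` plays the role of the survival probability: the implied survival at
    the returned time is exactly ``u``.
    """
    if scale <= 0 or shape <= 0:
        raise ValueError("scale and shape must be > 0")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    eta = np.asarray(linear_predictor, dtype=float)
    out = (-np.log(u) / (scale * np.exp(eta))) ** (1.0 / shape)
    return float(out) if out.ndim == 0 else out


def simulate_cohort(
    config: ScenarioConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one phase-I cohort under ``config``.

    Returns a DataFrame with one row per subject: ``id``, the four binary
    covariates, ``event_time`` (T), ``censor_time`` (C, already truncated at
    tau), ``obs_time`` (Z = min(T, C)) and ``event`` (I(T < C)).  Deterministic
    given the seed; ``seed`` defaults to ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_phase1

    x_conf = (rng.random(n) < config.p_conf).astype(np.int8)
    x_risk = (rng.random(n) < config.p_risk).astype(np.int8)
    p_bm = expit_link(config.bm_intercept, config.bm_slope, x_conf)
    x_bm = (rng.random(n) < p_bm).astype(np.int8)
    p_surr = expit_link(config.surr_intercept, config.surr_slope, x_bm)
    x_surr = (rng.random(n) < p_surr).astype(np.int8)

    eta = config.beta_bm * x_bm + config.beta_conf * x_conf + config.beta_risk * x_risk
    u = rng.random(n)
    # map U in (0,1); guard the measure-zero endpoints for float safety
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).eps)
    event_time = inverse_weibull_time(u, eta, config.weibull_scale, config.weibull_shape)

    if config.censor_rate > 0:
        censor_time = np.minimum(
            rng.exponential(1.0 / config.censor_rate, size=n), config.tau
        )
    else:
        censor_time = np.full(n, config.tau)

    obs_time = np.minimum(event_time, censor_time)
    event = (event_time < censor_time).astype(np.int8)

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x_bm": x_bm,
            "x_conf": x_conf,
            "x_risk": x_risk,
            "x_surr": x_surr,
            "event_time": event_time,
            "censor_time": censor_time,
            "obs_time": obs_time,
            "event": event,
        }
    )


def burton_replications(accuracy: float, coef_variance: float, alpha: float = 0.05) -> int:
    """Number of simulation replications for a target accuracy of the mean
    coefficient estimate: ``B = ceil((z_{1-alpha/2} * sqrt(var) / accuracy)^2)``.

    The reporting layer conventionally rounds the result to two significant
    figures (e.g. 1997 -> 2000).
    """
    if accuracy <= 0 or coef_variance <= 0:
        raise ValueError("accuracy and coef_variance must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return int(math.ceil((z * math.sqrt(coef_variance) / accuracy) ** 2))


# -- closed-form expectations (used for calibration and as test oracles) -----


def _cell_table(config: ScenarioConfig):
    """Probability weight and linear predictor of each of the 8 covariate cells."""
    cells = []
    for conf in (0, 1):
        p_c = config.p_conf if conf else 1.0 - config.p_conf
        p_bm1 = float(expit_link(config.bm_intercept, config.bm_slope, conf))
        for risk in (0, 1):
            p_r = config.p_risk if risk else 1.0 - config.p_risk
            for bm in (0, 1):
                p_b = p_bm1 if bm else 1.0 - p_bm1
                eta = (
                    config.beta_bm * bm
                    + config.beta_conf * conf
                    + config.beta_risk * risk
                )
                cells.append((p_c * p_r * p_b, eta))
    return cells


def marginal_biomarker_prevalence(config: ScenarioConfig) -> float:
    """P(x_bm = 1) marginalised over the confounder, in closed form."""
    p1 = float(expit_link(config.bm_intercept, config.bm_slope, 1))
    p0 = float(expit_link(config.bm_intercept, config.bm_slope, 0))
    return config.p_conf * p1 + (1.0 - config.p_conf) * p0


def expected_event_fraction(config: ScenarioConfig) -> float:
    """Expected fraction of subjects with an observed event by ``tau``.

    With no random censoring this is the 8-cell average of
    ``1 - exp(-lambda * tau^p * exp(eta))``; with exponential censoring at rate
    rho the per-cell probability ``P(T < min(C, tau))`` is obtained by
    numerical integration of the Weibull density against ``exp(-rho t)``.
    """
    lam, p, tau, rho = (
        config.weibull_scale,
        config.weibull_shape,
        config.tau,
        config.censor_rate,
    )
    total = 0.0
    for w, eta in _cell_table(config):
        rate = lam * math.exp(eta)
        if rho == 0.0:
            prob = 1.0 - math.exp(-rate * tau**p)
        else:

            def integrand(t, rate=rate):
                return (
                    rate * p * t ** (p - 1.0)
                    * math.exp(-rate * t**p)
                    * math.exp(-rho * t)
                )

            prob, _ = integrate.quad(integrand, 0.0, tau, limit=200)
        total += w * prob
    return total


def calibrate_nuisance_log_hr(
    target_event_fraction: float = 0.25,
    base: ScenarioConfig | None = None,
) -> float:
    """Common log hazard ratio for confounder and risk factor that yields the
    target expected event fraction at rho = 0 (biomarker effect held fixed)."""
    base = (base or ScenarioConfig()).replace(censor_rate=0.0)

    def gap(log_hr: float) -> float:
        cfg = base.replace(beta_conf=log_hr, beta_risk=log_hr)
        return expected_event_fraction(cfg) - target_event_fraction

    return float(optimize.brentq(gap, -2.0, 2.0, xtol=1e-12))


_DEFAULT_NUISANCE_LOG_HR = calibrate_nuisance_log_hr()


def default_scenario(**overrides) -> ScenarioConfig:
    """Reference scenario: N=2000, tau=2, common biomarker (~25% prevalence),
    HR_BM = 1.5, surrogate sensitivity = specificity = 0.7, and nuisance
    coefficients calibrated so the expected event count at rho=0 is 500."""
    cfg = ScenarioConfig(
        beta_conf=_DEFAULT_NUISANCE_LOG_HR,
        beta_risk=_DEFAULT_NUISANCE_LOG_HR,
    )
    return cfg.replace(**overrides) if overrides else cfg


# -- cohort table I/O ---------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write the exportable cohort columns (id, obs_time, event, covariates)."""
    cohort[COHORT_COLUMNS].to_csv(path, sep=sep, index=False)


def read_cohort(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a cohort table, validating the documented schema."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    for col in ("event", "x_bm", "x_conf", "x_risk", "x_surr"):
        vals = set(pd.unique(df[col].dropna()))
        if not vals <= {0, 1}:
            raise ValueError(f"column {col!r} must be binary 0/1, got {sorted(vals)[:5]}")
    if (df["obs_time"] <= 0).any():
        raise ValueError("column 'obs_time' must be strictly positive")
    return df
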