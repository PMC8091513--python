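"""Phase-II sampling designs.

Five ways of drawing the subsample on which the expensive biomarker is
measured:

* ``SRS`` — simple random sampling without replacement,
* ``PPS`` — stratified sampling with proportional allocation (probability
  proportional to stratum size),
* ``CC``  — case-control with a fixed total size, half cases / half controls,
  optionally balanced across extra strata within each half,
* ``NCC`` — nested case-control: controls drawn from each case's risk set,
* ``CM``  — counter-matching: controls drawn from the risk set in the
  *opposite* stratum of a binary surrogate.

All draws operate on a cohort DataFrame as produced by
:mod:`phasetwo.synthetic_cohort` and return a :class:`PhaseTwoSample` of
per-subject selection indicators, inclusion probabilities and stratum labels.
For NCC/CM the inclusion probabilities require the risk-set bookkeeping in
:mod:`phasetwo.inclusion_weights` and are left NaN here.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "DesignSpec",
    "PhaseTwoSample",
    "build_strata",
    "draw_srs",
    "draw_pps",
    "draw_cc",
    "draw_ncc",
    "draw_cm",
    "draw_phase2",
    "phase2_table",
]


class Design(str, enum.Enum):
    SRS = "srs"
    PPS = "pps"
    CC = "cc"
    NCC = "ncc"
    CM = "cm"


@dataclass(frozen=True)
class DesignSpec:
    """One phase-II sampling plan.

    ``strata_vars`` are cohort columns crossed with the event indicator to
    form sampling strata (PPS/CC).  ``post_stratify_vars`` request
    post-stratification of the weights after a draw (CC only); the sampling
    itself ignores them.  ``cm_stratum_var`` is the binary matching variable
    for counter-matching.
    """

    design: Design
    n_target: int
    strata_vars: tuple[str, ...] = ()
    controls_per_case: int = 1
    cm_stratum_var: str | None = None
    post_stratify_vars: tuple[str, ...] = ()
    name: str | None = None

    def __post_init__(self) -> None:
        if self.n_target <= 0:
            raise ValueError("n_target must be positive")
        if self.controls_per_case <= 0:
            raise ValueError("controls_per_case must be positive")
        if self.design is Design.CM and not self.cm_stratum_var:
            raise ValueError("CM requires cm_stratum_var")
        if self.name is None:
            object.__setattr__(self, "name", self._default_name())

    def _default_name(self) -> str:
        tag = self.design.value
        if self.strata_vars:
            tag += "_" + "_".join(self.strata_vars)
        if self.post_stratify_vars:
            tag += "_post_" + "_".join(self.post_stratify_vars)
        return tag


@dataclass
class PhaseTwoSample:
    """Result of one phase-II draw over a cohort of size N."""

    selected: np.ndarray  # bool, shape (N,)
    inclusion_prob: np.ndarray  # float, shape (N,); NaN when deferred (NCC/CM)
    stratum: np.ndarray  # object (str labels), shape (N,)
    design_meta: dict = field(default_factory=dict)

    @property
    def realized_n(self) -> int:
        return int(self.selected.sum())

    def __post_init__(self) -> None:
        sel = self.selected
        pi = self.inclusion_prob
        bad = sel & ~np.isnan(pi) & ((pi <= 0) | (pi > 1))
        if bad.any():
            raise ValueError("selected subjects must have inclusion_prob in (0, 1]")


def build_strata(cohort: pd.DataFrame, strata_vars: list[str] | tuple[str, ...]) -> pd.Series:
    """Cross-classify the event indicator with the given binary columns.

    Labels look like ``"e1"`` or ``"e0|x_surr=1"`` and sort deterministically.
    """
    for var in strata_vars:
        if var not in cohort.columns:
            raise ValueError(f"stratification variable {var!r} not in cohort")
        vals = set(pd.unique(cohort[var]))
        if not vals <= {0, 1}:
            raise ValueError(f"stratification variable {var!r} must be binary 0/1")
    labels = "e" + cohort["event"].astype(int).astype(str)
    for var in strata_vars:
        labels = labels + "|" + var + "=" + cohort[var].astype(int).astype(str)
    return pd.Series(labels.to_numpy(dtype=object), index=cohort.index, name="stratum")


# -- allocation helpers -------------------------------------------------------


def _largest_remainder(sizes: np.ndarray, total: int) -> np.ndarray:
    """Proportional integer allocation by largest remainder.

    Ties among remainders are broken by position (callers pass sizes in
    label-sorted order).
    """
    sizes = np.asarray(sizes, dtype=float)
    quota = sizes * total / sizes.sum()
    alloc = np.floor(quota).astype(int)
    leftover = total - alloc.sum()
    if leftover > 0:
        remainders = quota - alloc
        # stable sort descending on remainder, ascending on position
        order = np.lexsort((np.arange(len(sizes)), -remainders))
        alloc[order[:leftover]] += 1
    return alloc


def _equal_split(total: int, k: int) -> np.ndarray:
    base, rem = divmod(total, k)
    out = np.full(k, base, dtype=int)
    out[:rem] += 1
    return out


def _balanced_allocation(sizes: np.ndarray, total: int) -> tuple[np.ndarray, int]:
    """Equal allocation across cells with capping at cell size.

    A cell's planned share that exceeds its size is capped and the shortfall
    redistributed equally among unsaturated cells, iterating until either the
    total is placed or every cell is full.  Returns (allocation, unplaced).
    """
    sizes = np.asarray(sizes, dtype=int)
    alloc = np.zeros_like(sizes)
    remaining = int(total)
    active = [i for i in range(len(sizes)) if sizes[i] > 0]
    while remaining > 0 and active:
        shares = _equal_split(remaining, len(active))
        nxt = []
        for pos, i in enumerate(active):
            take = min(int(shares[pos]), int(sizes[i] - alloc[i]))
            alloc[i] += take
            remaining -= take
            if alloc[i] < sizes[i]:
                nxt.append(i)
        active = nxt
    return alloc, remaining


def _sample_within(ids: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    if k >= len(ids):
        return ids
    return rng.choice(ids, size=k, replace=False)


# -- the five designs ---------------------------------------------------------


def draw_srs(cohort: pd.DataFrame, n_target: int, rng: np.random.Generator) -> PhaseTwoSample:
    """Simple random sample without replacement; pi = n/N for everyone."""
    n = len(cohort)
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds cohort size {n}")
    selected = np.zeros(n, dtype=bool)
    selected[rng.choice(n, size=n_target, replace=False)] = True
    pi = np.full(n, n_target / n)
    stratum = np.full(n, "all", dtype=object)
    return PhaseTwoSample(
        selected, pi, stratum,
        design_meta={"design": Design.SRS, "n_target": n_target},
    )


def draw_pps(
    cohort: pd.DataFrame,
    strata: pd.Series,
    n_target: int,
    rng: np.random.Generator,
) -> PhaseTwoSample:
    """Stratified sampling with proportional allocation (n_h = N_h * n/N,
    rounded by largest remainder), SRS within each stratum."""
    n = len(cohort)
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds cohort size {n}")
    labels = np.asarray(strata, dtype=object)
    uniq = sorted(set(labels))
    sizes = np.array([int((labels == lab).sum()) for lab in uniq])
    alloc = _largest_remainder(sizes, n_target)

    selected = np.zeros(n, dtype=bool)
    pi = np.zeros(n)
    per_stratum = {}
    for lab, size, k in zip(uniq, sizes, alloc):
        ids = np.flatnonzero(labels == lab)
        chosen = _sample_within(ids, int(k), rng)
        selected[chosen] = True
        pi[ids] = k / size if size else 0.0
        per_stratum[lab] = {"size": int(size), "planned": int(k), "realized": int(k)}
    return PhaseTwoSample(
        selected, pi, labels,
        design_meta={"design": Design.PPS, "n_target": n_target, "strata": per_stratum},
    )


def draw_cc(
    cohort: pd.DataFrame,
    strata: pd.Series,
    n_target: int,
    rng: np.random.Generator,
) -> PhaseTwoSample:
    """Case-control sampling at fixed total size.

    Half the sample is allocated to cases, half to controls; within each half
    the allocation is balanced (equal) across the substrata defined by the
    extra stratification variables.  Cells smaller than their planned share
    are taken entirely and the shortfall redistributed within the half; a
    half that cannot fill its quota passes the shortfall to the other half,
    so the total sample size is always met when n_target <= N.
    """
    n = len(cohort)
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds cohort size {n}")
    if n_target % 2:
        raise ValueError("n_target must be even for case-control sampling")
    event = cohort["event"].to_numpy().astype(bool)
    if not event.any():
        raise ValueError("case-control sampling requires at least one case")
    if event.all():
        raise ValueError("case-control sampling requires at least one control")

    labels = np.asarray(strata, dtype=object)

    def half(mask: np.ndarray):
        uniq = sorted(set(labels[mask]))
        sizes = np.array([int(((labels == lab) & mask).sum()) for lab in uniq])
        return uniq, sizes

    case_labs, case_sizes = half(event)
    ctrl_labs, ctrl_sizes = half(~event)
    n2 = n_target // 2
    alloc_case, rem_c = _balanced_allocation(case_sizes, n2)
    alloc_ctrl, rem_k = _balanced_allocation(ctrl_sizes, n2)
    if rem_c:  # not enough cases: fill with controls
        alloc_ctrl, rem_k = _balanced_allocation(ctrl_sizes, n2 + rem_c)
    elif rem_k:  # not enough controls: fill with cases
        alloc_case, rem_c = _balanced_allocation(case_sizes, n2 + rem_k)
    # n_target <= N guarantees the combined capacity suffices

    selected = np.zeros(n, dtype=bool)
    pi = np.zeros(n)
    per_stratum = {}
    for labs, sizes, alloc, mask in (
        (case_labs, case_sizes, alloc_case, event),
        (ctrl_labs, ctrl_sizes, alloc_ctrl, ~event),
    ):
        for lab, size, k in zip(labs, sizes, alloc):
            ids = np.flatnonzero((labels == lab) & mask)
            chosen = _sample_within(ids, int(k), rng)
            selected[chosen] = True
            pi[ids] = k / size if size else 0.0
            per_stratum[lab] = {"size": int(size), "planned": int(k), "realized": int(k)}
    return PhaseTwoSample(
        selected, pi, labels,
        design_meta={"design": Design.CC, "n_target": n_target, "strata": per_stratum},
    )


def _sample_cases(
    event_ids: np.ndarray, n_target: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """NCC/CM case rule: every case if n >= 2 * #events, otherwise a simple
    random n/2 of them with pi = (n/2)/#events."""
    n_events = len(event_ids)
    if n_target >= 2 * n_events:
        return event_ids, 1.0
    k = n_target // 2
    return rng.choice(event_ids, size=k, replace=False), k / n_events


def _draw_riskset_controls(
    obs_time: np.ndarray,
    case_ids: np.ndarray,
    case_times: np.ndarray,
    pool_order: np.ndarray,
    pool_times: np.ndarray,
    m: int,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], int]:
    """Draw m controls per case from a time-sorted candidate pool.

    ``pool_order`` are cohort indices sorted by ``pool_times`` ascending; the
    risk set at time t is the suffix with pool_times >= t, minus the case
    itself.  Returns per-case control arrays and the number of short risk sets.
    """
    controls = []
    short = 0
    for ci, t in zip(case_ids, case_times):
        start = np.searchsorted(pool_times, t, side="left")
        size = len(pool_order) - start
        in_pool = start < len(pool_order)
        if m == 1 and size > 1:
            # rejection sampling: cheap for the common 1:1 matching
            while True:
                j = int(rng.integers(start, len(pool_order)))
                if pool_order[j] != ci:
                    controls.append(pool_order[j : j + 1])
                    break
            continue
        pool = pool_order[start:]
        pool = pool[pool != ci]
        if len(pool) < m:
            short += 1
            controls.append(pool.copy())
        elif in_pool:
            controls.append(rng.choice(pool, size=m, replace=False))
        else:
            short += 1
            controls.append(np.empty(0, dtype=pool_order.dtype))
    return controls, short


def draw_ncc(
    cohort: pd.DataFrame,
    n_target: int,
    m: int,
    rng: np.random.Generator,
) -> PhaseTwoSample:
    """Nested case-control: m controls per sampled case, drawn without
    replacement from the subjects still under observation at the case's event
    time.  A subject drawn more than once (or drawn as control and also
    sampled as case) enters the sample once, so the realized size may fall
    below the planned one.  Inclusion probabilities are left NaN and filled by
    :func:`phasetwo.inclusion_weights.ncc_probs`."""
    n = len(cohort)
    obs_time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy().astype(bool)
    event_ids = np.flatnonzero(event)
    if len(event_ids) == 0:
        raise ValueError("risk-set sampling requires at least one event")

    case_ids, case_pi = _sample_cases(event_ids, n_target, rng)
    case_ids = np.sort(case_ids)
    case_times = obs_time[case_ids]

    order = np.argsort(obs_time, kind="stable")
    times_sorted = obs_time[order]
    controls, short = _draw_riskset_controls(
        obs_time, case_ids, case_times, order, times_sorted, m, rng
    )
    if short:
        warnings.warn(
            f"{short} risk set(s) smaller than m={m}: took all available controls",
            stacklevel=2,
        )

    selected = np.zeros(n, dtype=bool)
    selected[case_ids] = True
    if controls:
        selected[np.concatenate(controls)] = True
    stratum = np.where(event, "case", "control").astype(object)
    pi = np.full(n, np.nan)
    return PhaseTwoSample(
        selected, pi, stratum,
        design_meta={
            "design": Design.NCC,
            "n_target": n_target,
            "m": m,
            "sampled_case_ids": case_ids,
            "case_pi": case_pi,
            "short_risk_sets": short,
        },
    )


def draw_cm(
    cohort: pd.DataFrame,
    cm_stratum_var: str,
    n_target: int,
    m: int,
    rng: np.random.Generator,
) -> PhaseTwoSample:
    """Counter-matching on a binary stratum variable: controls for a case in
    stratum s come from the risk set of stratum 1-s, maximizing the
    case-control discordance of the matching variable.  Empty opposite risk
    sets fall back to the case's own stratum and are flagged in
    ``design_meta['fallback_cases']``."""
    n = len(cohort)
    if cm_stratum_var not in cohort.columns:
        raise ValueError(f"cm_stratum_var {cm_stratum_var!r} not in cohort")
    svals = cohort[cm_stratum_var].to_numpy()
    if not set(np.unique(svals)) <= {0, 1}:
        raise ValueError(f"cm_stratum_var {cm_stratum_var!r} must be binary 0/1")
    obs_time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy().astype(bool)
    event_ids = np.flatnonzero(event)
    if len(event_ids) == 0:
        raise ValueError("risk-set sampling requires at least one event")

    case_ids, case_pi = _sample_cases(event_ids, n_target, rng)
    case_ids = np.sort(case_ids)

    # per-stratum candidate pools sorted by time
    pools = {}
    for s in (0, 1):
        ids = np.flatnonzero(svals == s)
        order = ids[np.argsort(obs_time[ids], kind="stable")]
        pools[s] = (order, obs_time[order])

    selected = np.zeros(n, dtype=bool)
    selected[case_ids] = True
    fallback_cases = 0
    short = 0
    for ci in case_ids:
        t = obs_time[ci]
        opp = 1 - int(svals[ci])
        order, times_sorted = pools[opp]
        start = np.searchsorted(times_sorted, t, side="left")
        pool = order[start:]
        if len(pool) == 0:  # fall back to the case's own stratum
            fallback_cases += 1
            order, times_sorted = pools[int(svals[ci])]
            start = np.searchsorted(times_sorted, t, side="left")
            pool = order[start:]
            pool = pool[pool != ci]
        if len(pool) == 0:
            short += 1
            continue
        k = min(m, len(pool))
        if k < m:
            short += 1
        selected[rng.choice(pool, size=k, replace=False)] = True

    if fallback_cases:
        logger.warning(
            "counter-matching: %d case(s) had an empty opposite-stratum risk set; "
            "controls drawn from the case's own stratum",
            fallback_cases,
        )
    if short:
        warnings.warn(
            f"{short} risk set(s) smaller than m={m} in counter-matched draw",
            stacklevel=2,
        )
    stratum = np.where(event, "case", "control").astype(object)
    pi = np.full(n, np.nan)
    return PhaseTwoSample(
        selected, pi, stratum,
        design_meta={
            "design": Design.CM,
            "n_target": n_target,
            "m": m,
            "cm_stratum_var": cm_stratum_var,
            "sampled_case_ids": case_ids,
            "case_pi": case_pi,
            "fallback_cases": fallback_cases,
            "short_risk_sets": short,
        },
    )


def draw_phase2(
    cohort: pd.DataFrame, spec: DesignSpec, rng: np.random.Generator
) -> PhaseTwoSample:
    """Dispatch a :class:`DesignSpec` to the matching draw function."""
    if spec.n_target > len(cohort):
        raise ValueError("n_target exceeds cohort size")
    if spec.design is Design.SRS:
        return draw_srs(cohort, spec.n_target, rng)
    if spec.design is Design.PPS:
        strata = build_strata(cohort, spec.strata_vars)
        return draw_pps(cohort, strata, spec.n_target, rng)
    if spec.design is Design.CC:
        strata = build_strata(cohort, spec.strata_vars)
        return draw_cc(cohort, strata, spec.n_target, rng)
    if spec.design is Design.NCC:
        return draw_ncc(cohort, spec.n_target, spec.controls_per_case, rng)
    if spec.design is Design.CM:
        return draw_cm(
            cohort, spec.cm_stratum_var, spec.n_target, spec.controls_per_case, rng
        )
    raise ValueError(f"unknown design {spec.design!r}")


def phase2_table(
    cohort: pd.DataFrame,
    sample: PhaseTwoSample,
    weights=None,
) -> pd.DataFrame:
    """Cohort table augmented with xi / pi / weight / stratum columns."""
    out = cohort.copy()
    out["xi"] = sample.selected.astype(int)
    if weights is not None:
        out["pi"] = weights.inclusion_prob
        out["weight"] = weights.weight
    else:
        out["pi"] = sample.inclusion_prob
        out["weight"] = np.where(
            sample.selected & (sample.inclusion_prob > 0),
            1.0 / sample.inclusion_prob,
            0.0,
        )
    out["stratum"] = sample.stratum
    return out
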