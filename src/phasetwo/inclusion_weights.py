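"""Inclusion probabilities and design weights.

Weighted-cohort analysis of a phase-II sample needs, for every selected
subject, the probability that they entered the sample.  For the stratified
designs (SRS / PPS / CC) this is the empirical fraction sampled from the
subject's stratum.  For risk-set designs the probability that a control was
*ever* drawn accumulates over the risk sets it belonged to: with m controls
drawn per case out of a risk set of size R, the per-case escape probability is
1 - m/(R-1) and the overall inclusion probability of control j is

    pi_j = 1 - prod_{cases i with t_i <= Z_j} (1 - m / (R(t_i) - 1))

(Samuelsen's formula).  Counter-matching is the stratified analogue: only
cases in the opposite stratum can sample j, from the stratum-specific risk set
R_s(t) without the -1 (the case is not in the control's stratum).

Post-stratification rescales existing weights so the weighted count in each
post-stratum reproduces the known phase-I count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phasetwo.sampling_designs import Design, PhaseTwoSample

logger = logging.getLogger(__name__)

__all__ = ["WeightSet", "empirical_probs", "ncc_probs", "cm_probs", "post_stratify"]


@dataclass
class WeightSet:
    """Per-subject inclusion probabilities and design weights.

    ``weight`` is 1/pi for selected subjects and 0 otherwise; ``excluded``
    flags selected subjects whose pi is 0 (never reachable under the design's
    probability model) — they carry weight 0 and are dropped from fits.
    """

    inclusion_prob: np.ndarray
    weight: np.ndarray
    method: str
    post_strata: np.ndarray | None = None
    excluded: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return 0 if self.excluded is None else int(self.excluded.sum())


def _weights_from_pi(pi: np.ndarray, selected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    excluded = selected & (pi <= 0)
    w = np.zeros_like(pi)
    ok = selected & (pi > 0)
    w[ok] = 1.0 / pi[ok]
    return w, excluded


def empirical_probs(sample: PhaseTwoSample) -> WeightSet:
    """Empirical stratum inclusion probabilities for SRS/PPS/CC samples:
    pi_h = (number selected in stratum h) / N_h, weights 1/pi_h.

    The weighted count of each stratum equals N_h exactly.
    """
    labels = np.asarray(sample.stratum, dtype=object)
    pi = np.zeros(len(labels))
    for lab in sorted(set(labels)):
        mask = labels == lab
        size = int(mask.sum())
        realized = int((mask & sample.selected).sum())
        pi[mask] = realized / size
        if realized == 0:
            logger.warning(
                "stratum %r has no phase-II selections; its %d subjects get pi=0",
                lab, size,
            )
    w, excluded = _weights_from_pi(pi, sample.selected)
    return WeightSet(pi, w, "empirical", excluded=excluded)


def _riskset_product(
    subject_times: np.ndarray,
    case_times: np.ndarray,
    riskset_sizes: np.ndarray,
    m: int,
) -> np.ndarray:
    """1 - prod over cases with t_i <= Z_j of (1 - m / riskset_sizes_i).

    ``case_times`` must be sorted ascending with matching ``riskset_sizes``.
    Factors are floored at 0 when the risk set is smaller than m (inclusion
    certain from that case on).
    """
    frac = np.zeros(len(case_times)) if len(case_times) == 0 else m / riskset_sizes
    factors = np.clip(1.0 - frac, 0.0, 1.0)
    cum = np.cumprod(factors)
    counts = np.searchsorted(case_times, subject_times, side="right")
    pi = np.zeros(len(subject_times))
    hit = counts > 0
    pi[hit] = 1.0 - cum[counts[hit] - 1]
    return pi


def ncc_probs(cohort: pd.DataFrame, sample: PhaseTwoSample, m: int | None = None) -> WeightSet:
    """Samuelsen inclusion probabilities for a nested case-control sample.

    Cases get the case-sampling probability (1, or (n/2)/#events when cases
    were subsampled); non-cases get the risk-set product over the *sampled*
    cases' event times with overall risk-set sizes R(t_i) - 1.
    """
    meta = sample.design_meta
    if meta.get("design") is not Design.NCC:
        raise ValueError("sample was not drawn by draw_ncc")
    if m is None:
        m = meta["m"]
    obs_time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy().astype(bool)
    case_ids = np.asarray(meta["sampled_case_ids"])
    case_pi = float(meta["case_pi"])

    case_times = np.sort(obs_time[case_ids])
    times_sorted = np.sort(obs_time)
    # R(t) counts every subject still under observation at t, case included
    r_at_case = len(obs_time) - np.searchsorted(times_sorted, case_times, side="left")
    small = r_at_case - 1 < m
    if small.any():
        logger.warning(
            "%d risk set(s) smaller than m+1; inclusion treated as certain there",
            int(small.sum()),
        )
    pi = _riskset_product(obs_time, case_times, (r_at_case - 1).astype(float), m)
    pi[event] = case_pi
    w, excluded = _weights_from_pi(pi, sample.selected)
    if excluded.any():
        logger.warning("%d selected subject(s) with pi=0 excluded", int(excluded.sum()))
    return WeightSet(pi, w, "samuelsen_ncc", excluded=excluded)


def cm_probs(
    cohort: pd.DataFrame,
    sample: PhaseTwoSample,
    cm_stratum_var: str | None = None,
    m: int | None = None,
) -> WeightSet:
    """Inclusion probabilities for a counter-matched sample.

    A non-case in stratum s can only be drawn at event times of sampled cases
    in stratum 1-s, out of the stratum-s risk set R_s(t_i); its probability is
    the corresponding one-minus-escape product.  Cases follow the NCC case
    rule.  Subjects the design can never sample (e.g. sharing a stratum with
    every case) get pi = 0 and are excluded.

    Fallback draws from a case's own stratum (empty opposite risk set) are not
    represented in the product; such samples are flagged at draw time.
    """
    meta = sample.design_meta
    if meta.get("design") is not Design.CM:
        raise ValueError("sample was not drawn by draw_cm")
    if cm_stratum_var is None:
        cm_stratum_var = meta["cm_stratum_var"]
    if m is None:
        m = meta["m"]
    if meta.get("fallback_cases"):
        logger.warning(
            "counter-matched sample used %d own-stratum fallback draw(s); "
            "inclusion probabilities ignore those draws",
            meta["fallback_cases"],
        )
    obs_time = cohort["obs_time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy().astype(bool)
    svals = cohort[cm_stratum_var].to_numpy().astype(int)
    case_ids = np.asarray(meta["sampled_case_ids"])
    case_pi = float(meta["case_pi"])

    pi = np.zeros(len(obs_time))
    for s in (0, 1):
        in_s = svals == s
        # cases in the opposite stratum sample their controls from stratum s
        opp_cases = case_ids[svals[case_ids] == 1 - s]
        case_times = np.sort(obs_time[opp_cases])
        stratum_times = np.sort(obs_time[in_s])
        r_s = len(stratum_times) - np.searchsorted(stratum_times, case_times, side="left")
        pi[in_s] = _riskset_product(
            obs_time[in_s], case_times, r_s.astype(float), m
        )
    pi[event] = case_pi
    w, excluded = _weights_from_pi(pi, sample.selected)
    if excluded.any():
        logger.warning("%d selected subject(s) with pi=0 excluded", int(excluded.sum()))
    return WeightSet(pi, w, "samuelsen_cm", excluded=excluded)


def post_stratify(
    weights: WeightSet,
    sample: PhaseTwoSample,
    post_strata: pd.Series | np.ndarray,
) -> WeightSet:
    """Rescale weights within each post-stratum so the weighted count equals
    the phase-I count N_h; the post-strata become the variance strata."""
    labels = np.asarray(post_strata, dtype=object)
    w = weights.weight.copy()
    pi = weights.inclusion_prob.copy()
    for lab in sorted(set(labels)):
        mask = labels == lab
        n_h = int(mask.sum())
        total = w[mask & sample.selected].sum()
        if total <= 0:
            raise ValueError(
                f"post-stratum {lab!r} has phase-I count {n_h} but no selected "
                "subjects with positive weight; cannot calibrate"
            )
        scale = n_h / total
        w[mask] *= scale
        sel = mask & sample.selected & (w > 0)
        pi[sel] = 1.0 / w[sel]
    return WeightSet(
        pi, w, "post_stratified",
        post_strata=labels,
        excluded=weights.excluded,
        meta=dict(weights.meta),
    )
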