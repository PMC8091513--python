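import numpy as np
import pandas as pd
import pytest

from phasetwo import default_scenario, simulate_cohort
from phasetwo.sampling_designs import (
    Design,
    DesignSpec,
    _largest_remainder,
    build_strata,
    draw_cc,
    draw_cm,
    draw_ncc,
    draw_phase2,
    draw_pps,
    draw_srs,
    phase2_table,
)

from conftest import make_cohort


def rng(seed=0):
    return np.random.default_rng(seed)


class TestBuildStrata:
    def test_event_only_gives_two_strata(self, medium_cohort):
        strata = build_strata(medium_cohort, [])
        assert set(strata) == {"e0", "e1"}

    def test_cross_with_surrogate_gives_four(self, medium_cohort):
        strata = build_strata(medium_cohort, ["x_surr"])
        assert len(set(strata)) == 4
        assert "e1|x_surr=0" in set(strata)

    def test_no_events_leaves_case_strata_empty(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [0, 0, 0], x_surr=[0, 1, 1])
        strata = build_strata(cohort, ["x_surr"])
        assert set(strata) == {"e0|x_surr=0", "e0|x_surr=1"}

    def test_non_binary_variable_rejected(self, medium_cohort):
        with pytest.raises(ValueError, match="binary"):
            build_strata(medium_cohort, ["obs_time"])


class TestSRS:
    def test_constant_inclusion_probability(self, medium_cohort):
        s = draw_srs(medium_cohort, 600, rng())
        assert s.realized_n == 600
        np.testing.assert_allclose(s.inclusion_prob, 0.3)

    def test_full_sample_when_n_equals_cohort(self, medium_cohort):
        s = draw_srs(medium_cohort, len(medium_cohort), rng())
        assert s.selected.all()
        np.testing.assert_allclose(s.inclusion_prob, 1.0)

    def test_oversized_target_rejected(self, medium_cohort):
        with pytest.raises(ValueError):
            draw_srs(medium_cohort, len(medium_cohort) + 1, rng())


class TestPPS:
    def test_exact_proportional_allocation(self):
        cohort = make_cohort(
            np.r_[np.ones(500), np.full(1500, 2.0)],
            np.r_[np.ones(500, int), np.zeros(1500, int)],
        )
        s = draw_pps(cohort, build_strata(cohort, []), 600, rng())
        np.testing.assert_allclose(s.inclusion_prob, 0.3)
        assert s.design_meta["strata"]["e1"]["planned"] == 150
        assert s.design_meta["strata"]["e0"]["planned"] == 450

    def test_largest_remainder_rounding(self):
        # shares 0.9 and 599.1 -> the tiny stratum wins the leftover seat
        np.testing.assert_array_equal(
            _largest_remainder(np.array([3, 1997]), 600), [1, 599]
        )

    def test_remainder_ties_broken_by_position(self):
        np.testing.assert_array_equal(
            _largest_remainder(np.array([10, 10, 10]), 8), [3, 3, 2]
        )

    def test_single_stratum_reduces_to_srs(self, medium_cohort):
        cohort = medium_cohort.assign(event=0)
        s = draw_pps(cohort, build_strata(cohort, []), 600, rng())
        np.testing.assert_allclose(s.inclusion_prob, 0.3)
        assert s.realized_n == 600


class TestCC:
    def make_cc_cohort(self, n_cases, n_controls, surr_case_split=None):
        n = n_cases + n_controls
        event = np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)]
        surr = np.zeros(n, int)
        if surr_case_split is not None:
            surr[: surr_case_split] = 1  # first cells of the case half
            surr[n_cases : n_cases + n_controls // 2] = 1
        return make_cohort(np.linspace(0.5, 2.0, n), event, x_surr=surr)

    def test_balanced_halves_printed_probabilities(self):
        cohort = self.make_cc_cohort(500, 1500)
        s = draw_cc(cohort, build_strata(cohort, []), 600, rng())
        pi = s.inclusion_prob
        np.testing.assert_allclose(pi[cohort.event == 1], 0.6)
        np.testing.assert_allclose(pi[cohort.event == 0], 0.2)
        assert s.realized_n == 600

    def test_all_cases_taken_when_scarce(self):
        cohort = self.make_cc_cohort(200, 1800)
        s = draw_cc(cohort, build_strata(cohort, []), 600, rng())
        assert s.selected[cohort.event == 1].all()
        np.testing.assert_allclose(s.inclusion_prob[cohort.event == 1], 1.0)
        assert (~s.selected[cohort.event == 0]).sum() == 1400  # 400 controls drawn

    def test_cap_and_reallocate_across_substrata(self):
        # case substrata of sizes 100 (surr=1) and 400 (surr=0): the planned
        # 150/150 is capped at 100 and the shortfall moves to the larger cell
        cohort = self.make_cc_cohort(500, 1500, surr_case_split=100)
        s = draw_cc(cohort, build_strata(cohort, ["x_surr"]), 600, rng())
        meta = s.design_meta["strata"]
        assert meta["e1|x_surr=1"]["realized"] == 100
        assert meta["e1|x_surr=0"]["realized"] == 200
        assert s.realized_n == 600

    def test_odd_target_rejected(self, medium_cohort):
        with pytest.raises(ValueError, match="even"):
            draw_cc(medium_cohort, build_strata(medium_cohort, []), 601, rng())

    def test_requires_cases_and_controls(self):
        cohort = make_cohort([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="case"):
            draw_cc(cohort, build_strata(cohort, []), 2, rng())


class TestNCC:
    def test_riskset_enumeration_on_toy_cohort(self, toy_riskset_cohort):
        # control for B (event at t=2) can only be C (the sole subject at risk)
        for seed in range(25):
            s = draw_ncc(toy_riskset_cohort, 4, 1, rng(seed))
            assert s.selected[[0, 1]].all()  # both cases kept (n >= 2 * events)
            assert s.selected[2]  # C forced as B's control
        assert s.design_meta["case_pi"] == 1.0

    def test_case_subsampling_rule(self):
        cfg = default_scenario(censor_rate=0.0)
        cohort = simulate_cohort(cfg, seed=4)
        n_events = int(cohort.event.sum())
        s = draw_ncc(cohort, 600, 1, rng())
        assert s.design_meta["case_pi"] == pytest.approx(300 / n_events)
        assert len(s.design_meta["sampled_case_ids"]) == 300
        # future cases may still enter as controls of earlier cases
        assert s.selected[cohort.event == 1].sum() >= 300

    def test_all_cases_kept_at_boundary(self):
        cohort = simulate_cohort(default_scenario(), seed=4)
        n_events = int(cohort.event.sum())
        s = draw_ncc(cohort, 2 * n_events, 1, rng())
        assert s.design_meta["case_pi"] == 1.0
        assert s.selected[cohort.event == 1].all()
        assert s.realized_n <= 2 * n_events

    @pytest.mark.parametrize("seed", range(5))
    def test_realized_size_capped_at_twice_events(self, seed):
        cohort = simulate_cohort(default_scenario(censor_rate=0.4), seed=seed)
        s = draw_ncc(cohort, 600, 1, rng(seed))
        assert s.realized_n <= 2 * int(cohort.event.sum())
        assert s.realized_n <= 600


class TestCM:
    def test_opposite_stratum_control_is_forced(self, toy_cm_cohort):
        s = draw_cm(toy_cm_cohort, "x_surr", 2, 1, rng())
        assert s.selected[0] and s.selected[1]  # case A + its only opposite control B
        assert s.design_meta["fallback_cases"] == 0

    def test_empty_opposite_stratum_falls_back_flagged(self):
        cohort = make_cohort([1.0, 2.0, 3.0], [1, 0, 0], x_surr=[1, 1, 1])
        s = draw_cm(cohort, "x_surr", 2, 1, rng())
        assert s.design_meta["fallback_cases"] == 1
        assert s.realized_n == 2  # case + own-stratum control

    def test_non_binary_stratum_rejected(self, medium_cohort):
        with pytest.raises(ValueError, match="binary"):
            draw_cm(medium_cohort, "obs_time", 600, 1, rng())

    @pytest.mark.parametrize("seed", range(5))
    def test_realized_size_capped_at_twice_events(self, seed):
        cohort = simulate_cohort(default_scenario(censor_rate=0.4), seed=seed)
        s = draw_cm(cohort, "x_surr", 600, 1, rng(seed))
        assert s.realized_n <= 2 * int(cohort.event.sum())


class TestMonteCarloSelectionFrequencies:
    """Empirical per-subject selection frequency must reproduce the nominal
    inclusion probabilities (oracle equivalence on a fixed 20-subject cohort)."""

    N_DRAWS = 20_000

    @pytest.mark.parametrize(
        "spec",
        [
            DesignSpec(Design.SRS, 10, name="srs"),
            DesignSpec(Design.PPS, 10, name="pps"),
            DesignSpec(Design.CC, 10, name="cc"),
        ],
        ids=lambda s: s.name,
    )
    def test_frequency_matches_pi(self, small_cohort, spec):
        g = rng(99)
        counts = np.zeros(len(small_cohort))
        sample = None
        for _ in range(self.N_DRAWS):
            sample = draw_phase2(small_cohort, spec, g)
            counts += sample.selected
        freq = counts / self.N_DRAWS
        assert np.max(np.abs(freq - sample.inclusion_prob)) < 0.02


def test_phase2_table_exports_xi_pi_weight(medium_cohort):
    s = draw_srs(medium_cohort, 600, rng())
    table = phase2_table(medium_cohort, s)
    assert {"xi", "pi", "weight", "stratum"} <= set(table.columns)
    assert table.xi.sum() == 600
    assert table.loc[table.xi == 1, "weight"].sum() == pytest.approx(2000.0)
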