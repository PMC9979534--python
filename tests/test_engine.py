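"""Dose-transition engine: admissible sets, posterior scoring, safety stop."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from asboincomb import (
    DesignParams,
    TrialState,
    admissible_sets,
    interval_probability,
    next_dose,
    safety_stop,
)
from conftest import make_state


class TestAdmissibleSets:
    def test_lowest_corner(self):
        a_e, a_d = admissible_sets((0, 0), 5, 3)
        assert set(a_e) == {(1, 0), (0, 1)}
        assert a_d == []

    def test_highest_corner(self):
        a_e, a_d = admissible_sets((4, 2), 5, 3)
        assert a_e == []
        assert set(a_d) == {(3, 2), (4, 1)}

    def test_interior(self):
        a_e, a_d = admissible_sets((2, 1), 5, 3)
        assert set(a_e) == {(3, 1), (2, 2)}
        assert set(a_d) == {(1, 1), (2, 0)}

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            admissible_sets((5, 0), 5, 3)


class TestIntervalProbability:
    def test_no_data_reduces_to_prior(self):
        expected = beta_dist(0.5, 0.5).cdf(0.397) - beta_dist(0.5, 0.5).cdf(0.186)
        assert interval_probability(0, 0, 0.186, 0.397) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("y,n", [(0, 0), (1, 3), (0, 3), (5, 12), (12, 12)])
    def test_against_quadrature_oracle(self, y, n):
        a, b = 0.5 + y, 0.5 + n - y
        dens = beta_dist(a, b).pdf
        oracle, err = quad(dens, 0.186, 0.397)
        assert err < 1e-10
        assert interval_probability(y, n, 0.186, 0.397) == pytest.approx(oracle, abs=1e-8)

    def test_full_support_is_one(self):
        assert interval_probability(2, 5, 1e-14, 1 - 1e-14) == pytest.approx(1.0, abs=1e-6)

    def test_out_of_order_bounds_rejected(self):
        with pytest.raises(ValueError):
            interval_probability(1, 3, 0.4, 0.2)

    @given(
        y=st.integers(0, 8),
        n=st.integers(8, 12),
        a=st.floats(0.05, 0.4),
        widen=st.floats(0.01, 0.3),
    )
    def test_widening_never_decreases_probability(self, y, n, a, widen):
        b = a + 0.2
        narrow = interval_probability(y, n, a, b)
        wider = interval_probability(y, n, max(a - widen, 0.0), min(b + widen, 1.0))
        assert wider >= narrow - 1e-12


class TestNextDose:
    def test_zero_toxicity_escalates(self, table1_params, rng):
        state = make_state(n=np.full((5, 3), 0), y=np.zeros((5, 3)), current=(1, 1))
        state.n[1, 1] = 3
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "escalate"
        assert decision.next in {(2, 1), (1, 2)}

    def test_toxic_lowest_dose_stays(self, table1_params, rng):
        state = make_state(n=[[3, 0, 0]] + [[0, 0, 0]] * 4,
                           y=[[2, 0, 0]] + [[0, 0, 0]] * 4, current=(0, 0))
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "stay"
        assert decision.next == (0, 0)
        assert decision.rationale["verdict"] == "de-escalate"

    def test_intermediate_rate_stays(self, table1_params, rng):
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(1, 1))
        state.n[1, 1], state.y[1, 1] = 3, 1  # 1/3 lies between the n=3 boundaries
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "stay"

    def test_top_corner_escalation_stays(self, table1_params, rng):
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(4, 2))
        state.n[4, 2] = 3
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "stay"
        assert decision.next == (4, 2)

    def test_edge_deescalation_moves_along_remaining_axis(self, table1_params, rng):
        # at j=0 with k>0, the only admissible de-escalation is (j, k-1)
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(0, 1))
        state.n[0, 1], state.y[0, 1] = 3, 3
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "de-escalate"
        assert decision.next == (0, 0)

    def test_candidates_ranked_by_interval_probability(self, table1_params, rng):
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(1, 1))
        state.n[1, 1] = 3
        state.n[2, 1], state.y[2, 1] = 3, 1  # near-target history
        state.n[1, 2], state.y[1, 2] = 3, 3  # clearly over-toxic history
        decision = next_dose(state, table1_params, rng)
        assert decision.action == "escalate"
        assert decision.next == (2, 1)
        scores = {tuple(c["dose"]): c["score"] for c in decision.rationale["candidates"]}
        assert scores[(2, 1)] > scores[(1, 2)]

    def test_requires_observed_patients(self, table1_params, rng):
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(0, 0))
        with pytest.raises(ValueError):
            next_dose(state, table1_params, rng)

    def test_tie_break_is_seed_reproducible(self, table1_params):
        state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(1, 1))
        state.n[1, 1] = 3  # both escalation candidates untried -> exact tie
        picks = [next_dose(state, table1_params, np.random.default_rng(7)).next
                 for _ in range(5)]
        assert len(set(picks)) == 1
        draws = {next_dose(state, table1_params, np.random.default_rng(s)).next
                 for s in range(40)}
        assert draws == {(2, 1), (1, 2)}  # both candidates reachable across seeds

    def test_fixed_mode_reproduces_classic_rule(self, rng):
        """Fixed 0.6*phi/1.4*phi boundaries classify every (y, n <= 12) as the
        closed-form rule computed independently here."""
        phi, phi1, phi2 = 0.3, 0.18, 0.42
        le = math.log((1 - phi1) / (1 - phi)) / math.log(phi * (1 - phi1) / (phi1 * (1 - phi)))
        ld = math.log((1 - phi) / (1 - phi2)) / math.log(phi2 * (1 - phi) / (phi * (1 - phi2)))
        params = DesignParams(phi=phi, phi1_init=phi1, phi2_init=phi2, adaptive=False,
                              safety_prob_cutoff=1 - 1e-12)  # isolate the transition rule
        for n in range(1, 13):
            for y in range(n + 1):
                state = make_state(n=np.zeros((5, 3)), y=np.zeros((5, 3)), current=(2, 1))
                state.n[2, 1], state.y[2, 1] = n, y
                verdict = next_dose(state, params, rng).rationale["verdict"]
                if y / n <= le:
                    assert verdict == "escalate"
                elif y / n >= ld:
                    assert verdict == "de-escalate"
                else:
                    assert verdict == "stay"


class TestSafetyStop:
    def test_no_toxicity_never_stops(self):
        params = DesignParams(phi=0.3)
        state = make_state(n=[[3]], y=[[0]])
        assert not safety_stop(state, params)

    def test_all_toxic_cohort_stops(self):
        """3/3 DLTs at the lowest dose: posterior tail mass above the target,
        computed by quadrature, exceeds the 0.95 cutoff."""
        dens = beta_dist(3.5, 0.5).pdf
        tail, _ = quad(dens, 0.3, 1.0)
        assert tail > 0.95
        params = DesignParams(phi=0.3)
        state = make_state(n=[[3]], y=[[3]])
        assert safety_stop(state, params)

    def test_minimum_sample_gate(self):
        params = DesignParams(phi=0.3, safety_min_n=3)
        state = make_state(n=[[2]], y=[[2]])
        assert not safety_stop(state, params)

    def test_threshold_matches_posterior_tail(self):
        # 4/6 DLTs: quadrature tail vs the engine's decision must agree
        params = DesignParams(phi=0.3)
        tail, _ = quad(beta_dist(4.5, 2.5).pdf, 0.3, 1.0)
        state = make_state(n=[[6]], y=[[4]])
        assert safety_stop(state, params) == (tail > 0.95)


class TestStateInvariants:
    def test_counts_validated(self):
        with pytest.raises(ValueError):
            make_state(n=[[1]], y=[[2]])
        with pytest.raises(ValueError):
            make_state(n=[[1]], y=[[0]], current=(1, 0))

    def test_add_cohort_accumulates(self):
        state = TrialState.empty(2, 2)
        state.add_cohort((0, 0), np.array([True, False, False]))
        state.add_cohort((0, 0), np.array([True, True, False]))
        assert state.n[0, 0] == 6 and state.y[0, 0] == 3
        assert state.enrolled == 6 and state.total_dlts == 3
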