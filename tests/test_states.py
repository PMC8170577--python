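"""State space enumeration, matrix validation, and the cycle operator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from obesim import (
    DEAD,
    HealthState,
    StateOccupancy,
    TransitionMatrix,
    enumerate_states,
    is_allowed_transition,
    state_family,
    step,
    validate_matrix,
)
from obesim.states import Cancer, CVStatus, Glycemic


class TestEnumeration:
    def test_exactly_one_absorbing_death_state(self):
        states = enumerate_states()
        dead = [s for s in states if s.is_dead]
        assert dead == [DEAD]
        assert is_allowed_transition(DEAD, DEAD)
        assert all(
            not is_allowed_transition(DEAD, s) for s in states if not s.is_dead
        )

    def test_no_state_combines_two_acute_cv_events(self):
        # each state carries at most one CV status, so acute ACS and acute
        # stroke can never coexist; cancer states carry no CV status at all
        for s in enumerate_states():
            if not s.is_dead and s.cancer == Cancer.NONE:
                assert s.cv in CVStatus

    def test_enumeration_is_the_documented_constrained_product(self):
        # 3 glycemic x 5 CV cancer-free states + 3 cancer states + dead
        expected = {
            HealthState(g, cv) for g in Glycemic for cv in CVStatus
        }
        expected |= {
            HealthState(None, None, c)
            for c in (Cancer.COLORECTAL, Cancer.ENDOMETRIAL_PM, Cancer.BREAST_PM)
        }
        expected.add(DEAD)
        states = enumerate_states()
        assert len(states) == 19
        assert set(states) == expected
        # deterministic order, dead last
        assert states == enumerate_states()
        assert states[-1] is DEAD

    def test_families_aggregate_to_eighteen_plus_death(self):
        fams = {state_family(s) for s in enumerate_states()}
        assert len(fams - {"dead"}) == 18

    def test_severity_order_is_queryable(self):
        ngt = HealthState(Glycemic.NGT, CVStatus.EVENT_FREE)
        pre = HealthState(Glycemic.PREDIABETES, CVStatus.EVENT_FREE)
        t2d = HealthState(Glycemic.T2D, CVStatus.EVENT_FREE)
        assert is_allowed_transition(ngt, pre) and is_allowed_transition(pre, t2d)
        assert not is_allowed_transition(t2d, pre)
        assert not is_allowed_transition(pre, ngt)
        post_acs = HealthState(Glycemic.NGT, CVStatus.POST_ACS)
        assert not is_allowed_transition(post_acs, ngt)  # no return to event-free
        acute = HealthState(Glycemic.NGT, CVStatus.ACS_YEAR)
        assert not is_allowed_transition(acute, HealthState(Glycemic.NGT, CVStatus.EVENT_FREE))
        assert is_allowed_transition(acute, HealthState(Glycemic.NGT, CVStatus.POST_ACS))

    def test_dead_state_carries_no_attributes(self):
        with pytest.raises(ValueError):
            HealthState(Glycemic.NGT, CVStatus.EVENT_FREE, is_dead=True)


def _identity_matrix():
    states = enumerate_states()
    return TransitionMatrix(np.eye(len(states)), states=states)


class TestValidateMatrix:
    def test_identity_passes(self):
        assert validate_matrix(_identity_matrix()).ok

    def test_deficient_row_sum_named(self):
        states = enumerate_states()
        m = np.eye(len(states))
        m[0, 0] = 0.99
        diag = validate_matrix(TransitionMatrix(m, states=states))
        assert not diag.ok
        assert diag.row_sum_errors[0][0] == states[0].name
        assert "0.99" in str(diag)

    def test_glycemic_regression_flagged(self):
        states = enumerate_states()
        i = states.index(HealthState(Glycemic.T2D, CVStatus.EVENT_FREE))
        j = states.index(HealthState(Glycemic.PREDIABETES, CVStatus.EVENT_FREE))
        m = np.eye(len(states))
        m[i, i] = 0.9
        m[i, j] = 0.1
        diag = validate_matrix(TransitionMatrix(m, states=states))
        assert (states[i].name, states[j].name, 0.1) in diag.order_violations

    def test_malformed_state_reference_raises(self):
        bogus = HealthState(Glycemic.NGT, CVStatus.EVENT_FREE)
        with pytest.raises(ValueError, match="unknown state"):
            TransitionMatrix({(bogus, bogus): 1.0}, states=[DEAD])


def _two_state_death_matrix(q):
    """Alive/dead toy embedded in the full state space."""
    states = enumerate_states()
    m = np.eye(len(states))
    alive = states.index(HealthState(Glycemic.NGT, CVStatus.EVENT_FREE))
    dead = states.index(DEAD)
    m[alive, alive] = 1 - q
    m[alive, dead] = q
    return TransitionMatrix(m, states=states), states[alive]


class TestStep:
    def test_identity_matrix_leaves_mass_unchanged(self):
        occ = StateOccupancy({HealthState(Glycemic.NGT, CVStatus.EVENT_FREE): 0.4,
                              HealthState(Glycemic.T2D, CVStatus.POST_ACS): 0.6})
        new = step(occ, _identity_matrix())
        np.testing.assert_allclose(new.mass, occ.mass)
        assert new.cycle_index == occ.cycle_index + 1

    def test_death_is_absorbing(self):
        occ = StateOccupancy({DEAD: 1.0})
        m, _ = _two_state_death_matrix(0.3)
        assert step(occ, m)[DEAD] == 1.0

    def test_geometric_survival_closed_form(self):
        m, alive = _two_state_death_matrix(0.1)
        occ = StateOccupancy({alive: 1.0})
        for _ in range(5):
            occ = step(occ, m)
        assert occ[alive] == pytest.approx(0.9**5, abs=1e-12)
        assert occ[alive] == pytest.approx(0.59049)

    def test_invalid_matrix_propagates_diagnostics(self):
        states = enumerate_states()
        m = np.eye(len(states))
        m[0, 0] = 0.5
        occ = StateOccupancy({DEAD: 1.0})
        with pytest.raises(ValueError, match="sums to"):
            step(occ, TransitionMatrix(m, states=states))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mass_conserved_under_random_valid_chains(self, seed):
        """Any row-stochastic severity-respecting matrix conserves mass."""
        rng = np.random.default_rng(seed)
        states = enumerate_states()
        n = len(states)
        m = np.zeros((n, n))
        for i, a in enumerate(states):
            allowed = [j for j, b in enumerate(states) if is_allowed_transition(a, b)]
            w = rng.random(len(allowed))
            m[i, allowed] = w / w.sum()
        mat = TransitionMatrix(m, states=states)
        assert validate_matrix(mat).ok
        w0 = rng.random(n)
        occ = StateOccupancy(w0 / w0.sum())
        dead_prev = occ.dead_mass
        for _ in range(10):
            occ = step(occ, mat, check=False)
            assert abs(occ.mass.sum() - 1.0) < 1e-9
            assert occ.dead_mass >= dead_prev - 1e-12  # monotone mortality
            dead_prev = occ.dead_mass

    def test_three_state_chain_matches_matrix_power_oracle(self):
        """n-step occupancy equals direct matrix power (brute force)."""
        # 3-state sub-chain: event-free -> post-ACS -> dead, constant probs
        states = enumerate_states()
        a = HealthState(Glycemic.NGT, CVStatus.EVENT_FREE)
        b = HealthState(Glycemic.NGT, CVStatus.ACS_YEAR)
        c = HealthState(Glycemic.NGT, CVStatus.POST_ACS)
        n = len(states)
        m = np.eye(n)
        ia, ib, ic, idd = (states.index(s) for s in (a, b, c, DEAD))
        m[ia, ia], m[ia, ib], m[ia, idd] = 0.85, 0.10, 0.05
        m[ib, ib], m[ib, ic], m[ib, idd] = 0.0, 0.7, 0.3
        m[ic, ic], m[ic, idd] = 0.9, 0.1
        mat = TransitionMatrix(m, states=states)
        occ = StateOccupancy({a: 1.0})
        for _ in range(7):
            occ = step(occ, mat)
        e0 = np.zeros(n)
        e0[ia] = 1.0
        expected = e0 @ np.linalg.matrix_power(m, 7)
        np.testing.assert_allclose(occ.mass, expected, atol=1e-12)


class TestRoundTrip:
    def test_matrix_csv_round_trip(self, tmp_path):
        m, _ = _two_state_death_matrix(0.25)
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        m2 = TransitionMatrix.from_csv(path)
        np.testing.assert_allclose(m2.matrix, m.matrix)
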