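"""Growth/damage ODE, asymmetric division, and the lifespan loop."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import agesim as ag
from agesim.dynamics import CellState, SimParams, divide, ode_step


class TestOdeStep:
    params = SimParams(f0=0.0, r0=0.0)

    def test_no_damage_terms_pure_exponential_growth(self):
        state = CellState(M=2.0, P=0.4, D=0.06)
        out = ode_step(state, g=0.3, f_m=0.0, params=self.params)
        assert out.M == pytest.approx(2.0 * math.exp(0.3 * self.params.dt))
        assert out.P == pytest.approx(state.P)
        assert out.D == pytest.approx(state.D)

    def test_zero_growth_keeps_mass(self):
        state = CellState(M=1.5, P=0.46, D=0.0)
        out = ode_step(state, g=0.0, f_m=0.01,
                       params=SimParams(f0=1e-4, r0=5e-4))
        assert out.M == 1.5

    def test_negative_rates_rejected(self):
        state = CellState()
        with pytest.raises(ValueError):
            ode_step(state, g=-0.1, f_m=0.0, params=self.params)
        with pytest.raises(ValueError):
            ode_step(state, g=0.1, f_m=float("nan"), params=self.params)

    def test_long_horizon_reaches_damage_fixed_point(self):
        """Closed-form fixed point D* = f/(f+r0) * P_tot of the damage
        balance, approached from a damage-free cell."""
        p = SimParams(f0=0.02, r0=0.05, dt=1.0)
        state = CellState(P=p.P_tot, D=0.0)
        for _ in range(2000):
            state = ode_step(state, g=0.0, f_m=0.03, params=p)
        f = 0.03 + p.f0
        assert state.D == pytest.approx(f / (f + p.r0) * p.P_tot, rel=1e-9)

    def test_matches_independent_integrator(self):
        """One exact step vs adaptive numeric integration of the damage
        balance over 100 random parameter draws."""
        rng = np.random.default_rng(20240715)
        worst = 0.0
        for _ in range(100):
            g, f_m = rng.uniform(0, 0.5), rng.uniform(0, 0.1)
            p = SimParams(f0=rng.uniform(0, 0.01), r0=rng.uniform(0, 0.05),
                          dt=rng.uniform(0.01, 0.5))
            D0 = rng.uniform(0, p.P_tot)
            state = CellState(M=1.0, P=p.P_tot - D0, D=D0)
            out = ode_step(state, g, f_m, p)

            def rhs(_, y):
                M, P, D = y
                f = f_m + p.f0
                return [g * M, -f * P + p.r0 * D, f * P - p.r0 * D]

            ref = solve_ivp(rhs, (0, p.dt), [1.0, p.P_tot - D0, D0],
                            rtol=1e-12, atol=1e-14).y[:, -1]
            worst = max(worst, abs(out.M - ref[0]), abs(out.P - ref[1]),
                        abs(out.D - ref[2]))
        assert worst <= 1e-8

    def test_conserves_total_protein_exactly(self):
        p = SimParams(f0=1e-3, r0=2e-3)
        state = CellState(P=p.P_tot, D=0.0)
        for _ in range(500):
            state = ode_step(state, g=0.1, f_m=0.02, params=p)
            assert state.P + state.D == pytest.approx(p.P_tot, abs=1e-12)


class TestDivide:
    def test_symmetric_division_without_retention(self):
        p = SimParams(s=0.5, re=0.0)
        state = CellState(M=2.0, P=0.4, D=0.06, t=5.0)
        mother, daughter = divide(state, p)
        assert (mother.M, mother.P, mother.D) == (1.0, 0.4, 0.06)
        assert (daughter.M, daughter.P, daughter.D) == (1.0, 0.4, 0.06)
        assert mother.divisions == 1 and mother.t_d == 5.0

    def test_full_retention_bookkeeping(self):
        # re = 1, P = 0.3, D = 0.1: mother keeps all damage, none of the
        # intact surplus; P_tot chosen large enough that no cap triggers
        p = SimParams(s=0.5, re=1.0, P_tot=0.7)
        mother, daughter = divide(CellState(M=2.0, P=0.3, D=0.1), p)
        assert (mother.P, mother.D) == (pytest.approx(0.0), pytest.approx(0.2))
        assert (daughter.P, daughter.D) == (pytest.approx(0.6),
                                            pytest.approx(0.0))

    @pytest.mark.parametrize("s", [0.5, 0.6, 0.75, 0.9])
    def test_mass_conserved_for_any_split(self, s):
        p = SimParams(s=s)
        state = CellState(M=1.0 / s, P=0.4, D=0.06)
        mother, daughter = divide(state, p)
        assert mother.M + daughter.M == pytest.approx(state.M, rel=1e-12)

    def test_cap_keeps_fraction_total(self):
        # (1+re)*D would exceed P_tot: damage capped, complement adjusted
        p = SimParams(s=0.5, re=0.5, P_tot=0.46)
        mother, _ = divide(CellState(M=2.0, P=0.06, D=0.40), p)
        assert mother.D == p.P_tot and mother.P == 0.0

    def test_trigger_required(self):
        p = SimParams(s=0.75)
        with pytest.raises(ValueError):
            divide(CellState(M=1.2), p)  # needs M >= 4/3


class TestLifespan:
    def test_wildtype_dies_with_finite_lifespan(self, wildtype):
        assert wildtype.died and not wildtype.censored
        assert 10 <= wildtype.n_divisions <= 40
        deaths = [e for e in wildtype.events if e["kind"] == "death"]
        assert len(deaths) == 1
        assert wildtype.events[-1] is deaths[0]

    def test_protein_total_conserved_at_every_recorded_step(self, wildtype,
                                                            toy):
        df = wildtype.to_dataframe()
        assert (df["P"] + df["D"] - toy.params.P_tot).abs().max() <= 1e-9

    def test_time_strictly_increasing(self, wildtype):
        t = wildtype.to_dataframe()["t"].to_numpy()
        assert (np.diff(t) > 0).all()

    def test_mother_mass_returns_to_initial_after_division(self, wildtype,
                                                           toy):
        # overshoot is at most one step of growth beyond the trigger
        for event in wildtype.events:
            if event["kind"] == "division":
                assert toy.params.M0 <= event["M_mother"] \
                    <= toy.params.M0 * math.exp(0.5 * toy.params.dt)

    def test_generation_times_lengthen_towards_death(self, wildtype):
        gen = wildtype.generation_times
        assert gen[-1] == max(gen)
        assert gen[-1] > 1.5 * gen[0]
        assert all(g > 0 for g in gen)

    def test_high_repair_censors_the_run(self, toy):
        """When repair is fast enough to beat retention, the cell keeps
        dividing until the horizon (no death)."""
        p = dataclasses.replace(toy.params, r0=0.5, t_max=12.0)
        tl = ag.simulate_lifespan(toy.model, toy.network, toy.table, p)
        assert tl.censored and not tl.died
        assert all(e["kind"] != "death" for e in tl.events)
        assert tl.n_divisions >= 10

    def test_death_coincides_with_first_infeasibility(self, wildtype, toy):
        # the state the cell died in is infeasible ...
        dead = ag.set_cell_coupling(toy.model, wildtype.final_state,
                                    toy.params)
        assert not ag.solve(dead).feasible
        # ... while the state feeding the last completed step's FBA
        # (the second-to-last post-step record) still supported one
        prev = wildtype.to_dataframe().iloc[-2]
        alive = ag.set_cell_coupling(
            toy.model, CellState(M=prev["M"], P=prev["P"], D=prev["D"]),
            toy.params)
        assert ag.solve(alive).feasible

    def test_daughters_recorded_once_per_division(self, wildtype):
        assert len(wildtype.daughters) == wildtype.n_divisions
        for d in wildtype.daughters:
            assert d.divisions == 0 and d.M > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(s=0.3)
        with pytest.raises(ValueError):
            SimParams(re=1.5)
        with pytest.raises(ValueError):
            SimParams(dt=0.0)
        with pytest.raises(ValueError):
            SimParams(f0=-1e-4)
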