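"""Growth and protein-damage dynamics with discrete asymmetric divisions.

The cell carries three states: dry mass ``M`` [gDW], the intact protein
fraction ``P`` and the damaged fraction ``D`` [g/gDW], with ``P + D``
constant at ``P_tot``.  Between divisions they follow

    dM/dt =  g(t) M
    dP/dt = -(f_m(t) + f0) P + r0 D
    dD/dt = +(f_m(t) + f0) P - r0 D

where the growth rate ``g`` and the metabolic damage-formation rate
``f_m`` come from the regulated ecFBA solution and are held constant
over one step of length ``dt``, so the step has a closed-form solution.
``f0`` is the non-metabolic damage formation rate and ``r0`` the repair
rate.

When the mass reaches ``M(0)/s`` the cell divides instantaneously.  The
mother keeps fraction ``s`` of the mass and retains damage according to
the retention factor ``re``:

    mother:   M <- s M,      P <- (1-re) P,  D <- (1+re) D
    daughter: M <- (1-s) M,  P <- (1+re) P,  D <- (1-re) D

Only the mother is simulated onward; daughters are recorded.  A
lifespan simulation iterates coupling -> ecFBA -> signalling ->
regulation -> ODE -> division until the ecFBA becomes infeasible (cell
death) or the horizon ``t_max`` is reached (censored run).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .boolean import BooleanNetwork, BooleanState, NoFixedPointError, steady_state
from .ecfba import (FluxSolution, MetabolicModel, _LP, enzyme_variability,
                    set_cell_coupling, solve)
from .regulation import (DelayBuffer, InputThresholds, RegulationTable,
                         derive_inputs, net_ranks, regulate)

if TYPE_CHECKING:  # pragma: no cover
    from .experiments import PerturbationSpec

logger = logging.getLogger(__name__)

__all__ = ["CellState", "SimParams", "Timeline", "ode_step", "divide",
           "simulate_lifespan"]


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of the (mother) cell."""

    t: float = 0.0          # h
    M: float = 1.0          # gDW
    P: float = 0.46         # intact protein fraction, g/gDW
    D: float = 0.0          # damaged protein fraction, g/gDW
    divisions: int = 0
    t_d: float = 0.0        # time of last division, h

    def __post_init__(self):
        if self.M <= 0:
            raise ValueError("mass must be positive")
        if self.P < 0 or self.D < 0:
            raise ValueError("protein fractions must be non-negative")


@dataclass(frozen=True)
class SimParams:
    """Parameters of the multi-scale lifespan simulation.

    Defaults are the bundled fixture's wildtype condition; ``s`` and
    ``re`` are fixture choices within their admissible ranges
    (s in [0.5, 1], re in [0, 1]).
    """

    f0: float = 1e-4            # non-metabolic damage formation [1/h]
    r0: float = 5e-4            # damage repair [1/h]
    epsilon: float = 0.04       # regulation factor (fraction of delta_i)
    gamma: float = 0.05         # flexibility of enzyme variability
    s: float = 0.75             # mother mass share at division
    re: float = 0.3             # damage retention factor
    NGAM_max: float = 0.7       # maximal maintenance [mmol gDW^-1 h^-1]
    P_tot: float = 0.46         # total protein fraction [g/gDW]
    dt: float = 0.1             # step [h]
    n_delay: int = 2            # regulation delay [steps]
    thresholds: InputThresholds = field(default_factory=InputThresholds)
    t_max: float = 100.0        # simulation horizon [h]
    M0: float = 1.0             # initial mass [gDW], arbitrary unit
    trx_enzymes: tuple[str, ...] = ("Trx1",)

    def __post_init__(self):
        if min(self.f0, self.r0, self.epsilon, self.gamma,
               self.NGAM_max) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.5 <= self.s <= 1.0:
            raise ValueError("s must be in [0.5, 1]")
        if not 0.0 <= self.re <= 1.0:
            raise ValueError("re must be in [0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_delay < 0:
            raise ValueError("n_delay must be >= 0")


def ode_step(state: CellState, g: float, f_m: float,
             params: SimParams) -> CellState:
    """Advance one ``dt`` using the exact solution with constant rates.

    ``M`` grows exponentially; ``D`` relaxes toward its fixed point
    ``f/(f+r0) * P_tot`` with rate ``k = f + r0`` where ``f = f_m + f0``;
    ``P = P_tot - D`` exactly, so the invariant ``P + D = P_tot`` holds
    to machine precision.
    """
    if g < 0 or f_m < 0 or not (math.isfinite(g) and math.isfinite(f_m)):
        raise ValueError("rates must be finite and >= 0")
    dt = params.dt
    f = f_m + params.f0
    k = f + params.r0
    M = state.M * math.exp(g * dt)
    if k == 0.0:
        D = state.D
    else:
        D_inf = (f / k) * params.P_tot
        D = D_inf - (D_inf - state.D) * math.exp(-k * dt)
    P = params.P_tot - D
    return replace(state, t=state.t + dt, M=M, P=P, D=D)


def divide(state: CellState, params: SimParams) -> tuple[CellState, CellState]:
    """Instantaneous asymmetric division into mother and daughter.

    Requires the trigger ``M >= M0/s``.  Fractions pushed outside
    ``[0, P_tot]`` by retention are capped with the complement adjusted,
    so ``P + D = P_tot`` holds in both compartments.
    """
    if state.M < params.M0 / params.s - 1e-12:
        raise ValueError(
            f"division trigger not met: M={state.M} < {params.M0 / params.s}")

    def _capped(P: float, D: float) -> tuple[float, float]:
        if D > params.P_tot:
            logger.warning("retention pushed D=%.4g above P_tot; capping", D)
            return 0.0, params.P_tot
        if P > params.P_tot:
            logger.warning("retention pushed P=%.4g above P_tot; capping", P)
            return params.P_tot, 0.0
        return P, D

    mp, md = _capped((1 - params.re) * state.P, (1 + params.re) * state.D)
    dp, dd = _capped((1 + params.re) * state.P, (1 - params.re) * state.D)
    mother = replace(state, M=params.s * state.M, P=mp, D=md,
                     divisions=state.divisions + 1, t_d=state.t)
    daughter = CellState(t=state.t, M=(1 - params.s) * state.M, P=dp, D=dd,
                         divisions=0, t_d=state.t)
    return mother, daughter


@dataclass
class Timeline:
    """Per-step records and events of one lifespan simulation."""

    steps: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    daughters: list[CellState] = field(default_factory=list)
    died: bool = False
    censored: bool = False
    death_time: Optional[float] = None
    params: Optional[SimParams] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    @property
    def n_divisions(self) -> int:
        return sum(1 for e in self.events if e["kind"] == "division")

    @property
    def division_times(self) -> list[float]:
        return [e["t"] for e in self.events if e["kind"] == "division"]

    @property
    def generation_times(self) -> list[float]:
        times = self.division_times
        if not times:
            return []
        return [times[0]] + [b - a for a, b in zip(times, times[1:])]

    @property
    def final_state(self) -> Optional[CellState]:
        return self._final_state

    _final_state: Optional[CellState] = None


def simulate_lifespan(model: MetabolicModel, net: BooleanNetwork,
                      table: RegulationTable, params: SimParams,
                      perturbation: "PerturbationSpec | None" = None,
                      extra_inputs: Optional[dict] = None) -> Timeline:
    """Run the full multi-scale loop until cell death or ``t_max``.

    Starts from a damage-free cell (P = P_tot, D = 0, M = M0).  Each
    step: scale pool/NGAM to the cell state; solve the ecFBA (max growth
    then parsimony); derive Boolean inputs from the fluxes; iterate the
    signalling network to steady state; regulate the model with the TF
    activities from ``n_delay`` steps ago and re-solve; advance the ODE
    with the post-regulation ``g`` and ``f_m``; divide if the mass
    trigger holds.  Death is the first infeasible ecFBA (before or after
    regulation); reaching ``t_max`` without death marks the timeline
    censored.
    """
    from .experiments import PhaseTracker  # local import avoids a cycle

    table.validate_against(net, model)
    timeline = Timeline(params=params)
    state = CellState(t=0.0, M=params.M0, P=params.P_tot, D=0.0)
    bool_state = net.zero_state()
    buffer: DelayBuffer | None = None
    tracker = PhaseTracker()
    prev_sol_reg: FluxSolution | None = None

    while state.t < params.t_max - 1e-12:
        phase = tracker.phase
        coupled = set_cell_coupling(model, state, params)
        ngam_lb = coupled.reaction(coupled.special("ngam")).lower_bound
        if perturbation is not None and perturbation.mode == "deletion" \
                and perturbation.applies(phase):
            coupled = coupled.with_enzyme_bounds(
                {e: (0.0, 0.0) for e in perturbation.enzymes})

        lp = _LP(coupled)
        sol = solve(coupled, lp=lp)
        if not sol.feasible:
            timeline.died = True
            timeline.death_time = state.t
            timeline.events.append(
                {"t": state.t, "kind": "death", "reason": "infeasible"})
            break

        inputs = derive_inputs(sol, coupled, params.thresholds,
                               trx_enzymes=params.trx_enzymes,
                               extra=extra_inputs, trx_solution=prev_sol_reg)
        known = {k: v for k, v in inputs.items() if k in set(net.components)}
        try:
            bool_state = steady_state(net, bool_state.replace(**known))
        except NoFixedPointError as err:
            logger.warning("no Boolean steady state at t=%.2f (cycle length "
                           "%d); keeping previous TF activities",
                           state.t, len(err.cycle))
        if buffer is None:
            buffer = DelayBuffer(bool_state, params.n_delay)
        delayed_tf = buffer.push(bool_state)

        regulated = coupled
        sol_reg = sol
        ranks = net_ranks(delayed_tf, table)
        active = [e for e, r in ranks.items() if r != 0]
        if active and params.epsilon > 0:
            variability = enzyme_variability(coupled, sol, params.gamma,
                                             enzymes=active, lp=lp)
            regulated = regulate(coupled, delayed_tf, table, variability,
                                 params.epsilon)
            if regulated is not coupled:
                sol_reg = solve(regulated, lp=lp.rebound(regulated))
                if not sol_reg.feasible:
                    timeline.died = True
                    timeline.death_time = state.t
                    timeline.events.append({"t": state.t, "kind": "death",
                                            "reason": "regulation-infeasible"})
                    break

        if perturbation is not None and perturbation.mode == "overexpression" \
                and perturbation.applies(phase):
            forced = {e: (1.5 * sol_reg.usage[e], 1.5 * sol_reg.usage[e])
                      for e in perturbation.enzymes}
            forced_model = regulated.with_enzyme_bounds(forced)
            sol_reg = solve(forced_model, lp=lp.rebound(forced_model))
            if not sol_reg.feasible:
                timeline.died = True
                timeline.death_time = state.t
                timeline.events.append({"t": state.t, "kind": "death",
                                        "reason": "perturbation-infeasible"})
                break

        prev_sol_reg = sol_reg
        phase = tracker.step(sol_reg.growth_rate,
                             sol_reg.flux.get(
                                 model.specials.get("ethanol_exchange", ""),
                                 0.0))

        # advance the ODE, then record: the closed-form step re-imposes
        # the constant-proteome assumption (P + D = P_tot) that division
        # bookkeeping transiently breaks, so recorded states satisfy it
        state = ode_step(state, sol_reg.growth_rate,
                         sol_reg.damage_formation, params)
        record = {
            "t": state.t, "M": state.M, "P": state.P, "D": state.D,
            "g": sol_reg.growth_rate, "f_m": sol_reg.damage_formation,
            "ngam": ngam_lb, "phase": phase,
            "regulation_applied": regulated is not coupled,
        }
        for role in ("glucose_uptake", "ethanol_exchange", "o2_uptake",
                     "co2_exchange", "acetate_exchange"):
            rid = model.specials.get(role)
            if rid is not None:
                record[role] = sol_reg.flux.get(rid, 0.0)
        for eid, u in sol_reg.usage.items():
            record[f"u_{eid}"] = u
        for name, val in inputs.items():
            record[f"in_{name}"] = val
        for comp in net.components:
            record[f"tf_{comp}"] = bool_state[comp]
        timeline.steps.append(record)

        if state.M >= params.M0 / params.s - 1e-12:
            M_at_division = state.M
            state, daughter = divide(state, params)
            timeline.daughters.append(daughter)
            timeline.events.append({"t": state.t, "kind": "division",
                                    "division": state.divisions,
                                    "M_at_division": M_at_division,
                                    "M_mother": state.M})
    else:
        timeline.censored = True
        logger.info("simulation censored at t_max=%.1f h", params.t_max)

    timeline._final_state = state
    return timeline
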