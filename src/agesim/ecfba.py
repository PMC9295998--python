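"""Enzyme-constrained flux balance analysis (ecFBA).

The metabolic network is a standard stoichiometric model augmented with
per-enzyme usage variables ``u_i`` (mass fractions of the proteome).
Each catalysed reaction flux is capped by the capacity of its enzymes,

    v_j <= sum_i kcat_ij * u_i,

usages are bounded by ``e_min_i <= u_i <= e_max_i`` and drawn from a
finite pool, ``sum_i u_i <= pool``.  The model is solved
lexicographically: growth is maximised first, then — with growth fixed
at its optimum — total enzyme usage is minimised (parsimony).  Enzyme
variability analysis returns, per enzyme, the admissible usage range
``delta_i`` at near-optimal growth (flexibility ``gamma``); the
regulation layer tightens bounds by fractions of that range.

Two couplings tie the metabolic model to the ageing state of the cell:
the available pool scales with the intact-protein fraction,
``pool * P/P_tot``, and the non-growth-associated maintenance (NGAM)
ATP-hydrolysis floor rises linearly with the damaged fraction,
``NGAM = D/(P+D) * NGAM_max``.

All LPs are solved with the HiGHS solver via scipy; infeasibility is
declared only from solver status, never from objective magnitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .dynamics import CellState, SimParams

__all__ = [
    "Reaction",
    "Enzyme",
    "MetabolicModel",
    "FluxSolution",
    "VariabilityResult",
    "ModelError",
    "solve",
    "enzyme_variability",
    "set_cell_coupling",
    "solve_chemostat",
]

#: relative slack used when fixing growth at its optimum before parsimony;
#: avoids a numerically empty feasible set
_LEX_SLACK = 1e-9


class ModelError(RuntimeError):
    """Structural model error (unbounded objective, solver failure, ...)."""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    tag: str = "core"

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"reaction {self.id}: lower bound > upper bound")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


@dataclass(frozen=True)
class Enzyme:
    id: str
    #: reaction id -> turnover number (flux units per usage unit)
    kcats: Mapping[str, float]
    e_min: float = 0.0
    e_max: float = 1.0
    tag: str = "core"

    def __post_init__(self):
        if not (0.0 <= self.e_min <= self.e_max):
            raise ValueError(
                f"enzyme {self.id}: need 0 <= e_min <= e_max, "
                f"got [{self.e_min}, {self.e_max}]")
        for rxn, kcat in self.kcats.items():
            if kcat <= 0:
                raise ValueError(f"enzyme {self.id}: kcat for {rxn} must be > 0")
        object.__setattr__(self, "kcats", dict(self.kcats))


@dataclass(frozen=True)
class MetabolicModel:
    """Stoichiometry, enzyme couplings and the shared enzyme pool.

    ``specials`` maps the roles ``growth``, ``ngam``, ``damage_exchange``,
    ``glucose_uptake``, ``ethanol_exchange``, ``o2_uptake``,
    ``co2_exchange`` and ``acetate_exchange`` to reaction ids.
    """

    metabolites: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    enzymes: tuple[Enzyme, ...]
    pool_max: float
    specials: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        mets = set(self.metabolites)
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ValueError("duplicate reaction ids")
        enz_ids = [e.id for e in self.enzymes]
        if len(set(enz_ids)) != len(enz_ids):
            raise ValueError("duplicate enzyme ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in mets:
                    raise ValueError(
                        f"reaction {r.id}: unknown metabolite {m!r}")
        rxn_set = set(rxn_ids)
        for e in self.enzymes:
            for rxn in e.kcats:
                if rxn not in rxn_set:
                    raise ValueError(f"enzyme {e.id}: unknown reaction {rxn!r}")
        if self.pool_max < 0:
            # 0 is allowed: the coupled model of a fully damaged cell
            raise ValueError("pool_max must be >= 0")
        for role, rid in self.specials.items():
            if rid not in rxn_set:
                raise ValueError(f"special {role!r}: unknown reaction {rid!r}")
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "specials", dict(self.specials))

    # -- convenient lookups -------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def enzyme(self, eid: str) -> Enzyme:
        for e in self.enzymes:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def special(self, role: str) -> str:
        try:
            return self.specials[role]
        except KeyError:
            raise KeyError(f"model has no special reaction for role {role!r}")

    # -- structural edits (all return modified copies) ----------------------
    def with_pool(self, pool: float) -> "MetabolicModel":
        if pool < 0:
            raise ValueError("pool bound must be >= 0")
        m = dataclasses.replace(self)
        object.__setattr__(m, "pool_max", pool)
        return m

    def with_reaction_bounds(
            self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        new = []
        for r in self.reactions:
            if r.id in bounds:
                lb, ub = bounds[r.id]
                r = dataclasses.replace(r, lower_bound=lb, upper_bound=ub)
            new.append(r)
        missing = set(bounds) - {r.id for r in new}
        if missing:
            raise KeyError(f"unknown reactions {sorted(missing)}")
        return dataclasses.replace(self, reactions=tuple(new))

    def with_enzyme_bounds(
            self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        new = []
        for e in self.enzymes:
            if e.id in bounds:
                e_min, e_max = bounds[e.id]
                e = dataclasses.replace(e, e_min=e_min, e_max=e_max)
            new.append(e)
        missing = set(bounds) - {e.id for e in new}
        if missing:
            raise KeyError(f"unknown enzymes {sorted(missing)}")
        return dataclasses.replace(self, enzymes=tuple(new))


@dataclass(frozen=True)
class FluxSolution:
    """Optimal fluxes and enzyme usages of one ecFBA solve."""

    feasible: bool
    flux: Mapping[str, float] = field(default_factory=dict)
    usage: Mapping[str, float] = field(default_factory=dict)
    growth_rate: float = 0.0
    damage_formation: float = 0.0
    objective: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "flux", dict(self.flux))
        object.__setattr__(self, "usage", dict(self.usage))

    @property
    def total_usage(self) -> float:
        return float(sum(self.usage.values()))

    def imbalance(self, model: MetabolicModel) -> float:
        """Max absolute per-metabolite imbalance |S.v| (steady-state check)."""
        if not self.feasible:
            return 0.0
        acc = {m: 0.0 for m in model.metabolites}
        for r in model.reactions:
            v = self.flux[r.id]
            for m, coeff in r.stoichiometry.items():
                acc[m] += coeff * v
        return max(abs(x) for x in acc.values()) if acc else 0.0


@dataclass(frozen=True)
class VariabilityResult:
    """Per-enzyme admissible usage range at near-optimal growth."""

    delta: Mapping[str, float]
    gamma: float

    def __post_init__(self):
        for eid, d in self.delta.items():
            if d < -1e-9:
                raise ValueError(f"negative variability for {eid}")
        object.__setattr__(
            self, "delta", {k: max(0.0, v) for k, v in self.delta.items()})


# ---------------------------------------------------------------------------
# LP assembly


class _LP:
    """Dense LP matrices for one model; reused across objective changes."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_index = {r.id: j for j, r in enumerate(model.reactions)}
        self.enz_index = {e.id: len(model.reactions) + i
                          for i, e in enumerate(model.enzymes)}
        n = len(model.reactions) + len(model.enzymes)
        self.n = n

        met_index = {m: i for i, m in enumerate(model.metabolites)}
        A_eq = np.zeros((len(model.metabolites), n))
        for r in model.reactions:
            j = self.rxn_index[r.id]
            for m, coeff in r.stoichiometry.items():
                A_eq[met_index[m], j] = coeff
        self.A_eq = A_eq
        self.b_eq = np.zeros(len(model.metabolites))

        rows = []
        # capacity: v_j - sum kcat_ij u_i <= 0 (and the mirror for
        # reversible catalysed reactions)
        coupled: dict[str, list[tuple[str, float]]] = {}
        for e in model.enzymes:
            for rxn, kcat in e.kcats.items():
                coupled.setdefault(rxn, []).append((e.id, kcat))
        for rxn, pairs in coupled.items():
            row = np.zeros(n)
            row[self.rxn_index[rxn]] = 1.0
            for eid, kcat in pairs:
                row[self.enz_index[eid]] = -kcat
            rows.append(row)
            if model.reaction(rxn).lower_bound < 0:
                mirror = -row.copy()
                mirror[self.rxn_index[rxn]] = -1.0
                for eid, kcat in pairs:
                    mirror[self.enz_index[eid]] = -kcat
                rows.append(mirror)
        # pool: sum u <= pool_max
        pool_row = np.zeros(n)
        for e in model.enzymes:
            pool_row[self.enz_index[e.id]] = 1.0
        rows.append(pool_row)
        self.A_ub = np.vstack(rows) if rows else np.zeros((0, n))
        self.b_ub = np.zeros(len(rows))
        self.b_ub[-1] = model.pool_max

        self.bounds = (
            [(r.lower_bound, r.upper_bound) for r in model.reactions]
            + [(e.e_min, e.e_max) for e in model.enzymes]
        )

    def rebound(self, model: MetabolicModel) -> "_LP":
        """Cheap copy for a model differing only in bounds/pool size."""
        clone = object.__new__(_LP)
        clone.__dict__.update(self.__dict__)
        clone.model = model
        clone.bounds = (
            [(r.lower_bound, r.upper_bound) for r in model.reactions]
            + [(e.e_min, e.e_max) for e in model.enzymes]
        )
        clone.b_ub = self.b_ub.copy()
        clone.b_ub[-1] = model.pool_max
        return clone

    def solve(self, c: np.ndarray,
              extra_ub: Sequence[tuple[np.ndarray, float]] = (),
              bound_overrides: Mapping[int, tuple[float, float]] | None = None):
        A_ub, b_ub = self.A_ub, self.b_ub
        if extra_ub:
            A_ub = np.vstack([A_ub] + [row for row, _ in extra_ub])
            b_ub = np.concatenate([b_ub, [rhs for _, rhs in extra_ub]])
        bounds = self.bounds
        if bound_overrides:
            bounds = list(bounds)
            for idx, bd in bound_overrides.items():
                bounds[idx] = bd
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=self.A_eq,
                      b_eq=self.b_eq, bounds=bounds, method="highs")
        if res.status == 3:
            raise ModelError("unbounded objective: model error")
        if res.status not in (0, 2):
            raise ModelError(f"solver failure: {res.message}")
        return res

    def growth_floor(self, g_min: float) -> tuple[np.ndarray, float]:
        """Extra inequality row enforcing v_growth >= g_min."""
        row = np.zeros(self.n)
        row[self.rxn_index[self.model.special("growth")]] = -1.0
        return row, -g_min


def _solution_from(model: MetabolicModel, lp: _LP, x: np.ndarray,
                   objective: float) -> FluxSolution:
    flux = {r.id: float(x[lp.rxn_index[r.id]]) for r in model.reactions}
    usage = {e.id: float(x[lp.enz_index[e.id]]) for e in model.enzymes}
    growth = flux[model.special("growth")]
    f_m = flux[model.special("damage_exchange")] \
        if "damage_exchange" in model.specials else 0.0
    return FluxSolution(feasible=True, flux=flux, usage=usage,
                        growth_rate=growth, damage_formation=f_m,
                        objective=objective)


def solve(model: MetabolicModel, lp: _LP | None = None) -> FluxSolution:
    """Lexicographic ecFBA solve: maximise growth, then parsimony.

    Returns an infeasible :class:`FluxSolution` (no fluxes) when the LP
    has no feasible point; unboundedness and solver failures raise
    :class:`ModelError`.
    """
    lp = lp or _LP(model)
    c = np.zeros(lp.n)
    c[lp.rxn_index[model.special("growth")]] = -1.0
    res = lp.solve(c)
    if res.status == 2:
        return FluxSolution(feasible=False)
    g_opt = -res.fun
    # parsimony: fix growth (with relative slack), minimise total usage
    floor = lp.growth_floor(g_opt - abs(g_opt) * _LEX_SLACK - 1e-15)
    c2 = np.zeros(lp.n)
    for e in model.enzymes:
        c2[lp.enz_index[e.id]] = 1.0
    res2 = lp.solve(c2, extra_ub=[floor])
    if res2.status == 2:  # pragma: no cover - slack makes this unreachable
        return _solution_from(model, lp, res.x, g_opt)
    return _solution_from(model, lp, res2.x, g_opt)


def enzyme_variability(model: MetabolicModel, solution: FluxSolution,
                       gamma: float,
                       enzymes: Iterable[str] | None = None,
                       lp: _LP | None = None) -> VariabilityResult:
    """Admissible usage range per enzyme at growth >= (1-gamma)*g_opt.

    ``enzymes`` restricts the analysis to a subset (the regulation layer
    only needs ranges for enzymes with a non-zero net rank).
    """
    if not solution.feasible:
        raise ValueError("variability requires a feasible solution")
    if not (0.0 <= gamma < 1.0):
        raise ValueError("gamma must be in [0, 1)")
    lp = lp or _LP(model)
    floor = lp.growth_floor((1.0 - gamma) * solution.growth_rate)
    ids = [e.id for e in model.enzymes] if enzymes is None else list(enzymes)
    delta = {}
    for eid in ids:
        col = lp.enz_index[eid]  # KeyError on unknown enzyme
        c = np.zeros(lp.n)
        c[col] = 1.0
        lo = lp.solve(c, extra_ub=[floor])
        c[col] = -1.0
        hi = lp.solve(c, extra_ub=[floor])
        if lo.status == 2 or hi.status == 2:
            raise ModelError(
                f"variability sub-problem infeasible for enzyme {eid} "
                f"(inconsistent gamma={gamma})")
        delta[eid] = max(0.0, float(-hi.fun - lo.fun))
    return VariabilityResult(delta=delta, gamma=gamma)


def set_cell_coupling(model: MetabolicModel, state: "CellState",
                      params: "SimParams") -> MetabolicModel:
    """Scale the enzyme pool and the NGAM floor to the cell's ageing state.

    Pool bound becomes ``pool_max * P/P_tot``; the NGAM reaction lower
    bound becomes ``D/(P+D) * NGAM_max`` (0 when P = D = 0).
    """
    if state.P < 0 or state.D < 0:
        raise ValueError("protein fractions must be non-negative")
    pool = model.pool_max * state.P / params.P_tot
    total = state.P + state.D
    ngam = params.NGAM_max * state.D / total if total > 0 else 0.0
    ngam_id = model.special("ngam")
    ub = model.reaction(ngam_id).upper_bound
    return model.with_pool(pool).with_reaction_bounds(
        {ngam_id: (ngam, max(ub, ngam))})


def solve_chemostat(model: MetabolicModel, rate: float,
                    allow_ethanol_uptake: bool = False) -> FluxSolution:
    """Chemostat solve: growth fixed to the dilution rate, glucose
    uptake minimised, then parsimony at the glucose optimum.

    The feed medium contains glucose only, so ethanol uptake is
    disallowed by default (the exchange lower bound is clamped to 0).
    """
    if rate < 0:
        raise ValueError("dilution rate must be >= 0")
    growth_id = model.special("growth")
    glc_id = model.special("glucose_uptake")
    bounds = {growth_id: (rate, rate)}
    if not allow_ethanol_uptake and "ethanol_exchange" in model.specials:
        etoh = model.reaction(model.special("ethanol_exchange"))
        bounds[etoh.id] = (max(0.0, etoh.lower_bound), etoh.upper_bound)
    fixed = model.with_reaction_bounds(bounds)
    lp = _LP(fixed)
    c = np.zeros(lp.n)
    c[lp.rxn_index[glc_id]] = 1.0
    res = lp.solve(c)
    if res.status == 2:
        return FluxSolution(feasible=False)
    glc_opt = res.fun
    cap_row = np.zeros(lp.n)
    cap_row[lp.rxn_index[glc_id]] = 1.0
    cap = (cap_row, glc_opt + abs(glc_opt) * _LEX_SLACK + 1e-12)
    c2 = np.zeros(lp.n)
    for e in model.enzymes:
        c2[lp.enz_index[e.id]] = 1.0
    res2 = lp.solve(c2, extra_ub=[cap])
    x = res2.x if res2.status == 0 else res.x
    return _solution_from(fixed, lp, x, glc_opt)
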