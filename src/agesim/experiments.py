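"""In-silico experiment harnesses.

Covers the analysis layers on top of single lifespan simulations:
segmentation of a timeline into the three metabolic phases (I maximal
growth/fermentation, II respiro-fermentative switch with dropping
growth, III slow growth with ethanol uptake), phase-scoped enzyme
perturbations (deletion / overexpression), parameter sweeps over
(f0, r0, epsilon), cumulative enzyme-usage accounting and the chemostat
validation (growth fixed to the dilution rate, glucose minimised).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .boolean import BooleanNetwork
from .dynamics import SimParams, Timeline, simulate_lifespan
from .ecfba import MetabolicModel, solve_chemostat
from .regulation import RegulationTable

logger = logging.getLogger(__name__)

__all__ = ["PhaseTracker", "PhaseAnnotation", "PerturbationSpec",
           "segment_phases", "sweep", "chemostat", "critical_dilution",
           "cumulative_usage"]

PHASES = ("I", "II", "III")


class PhaseTracker:
    """Causal (no-lookahead) classifier of the metabolic phases.

    Phase I while the growth rate stays within ``delta_g`` of its
    initial value; phase II from the first *sustained* drop
    (``sustained`` consecutive steps below the threshold); phase III
    from the first step with ethanol exchange in the uptake direction
    beyond ``etoh_tol``.  Labels are monotone I -> II -> III.
    """

    def __init__(self, delta_g: float = 0.01, sustained: int = 3,
                 etoh_tol: float = 1e-6):
        self.delta_g = delta_g
        self.sustained = max(1, int(sustained))
        self.etoh_tol = etoh_tol
        self.g_init: Optional[float] = None
        self.phase = "I"
        self._below = 0

    def step(self, g: float, ethanol_flux: float) -> str:
        if self.g_init is None:
            self.g_init = g
        if ethanol_flux < -self.etoh_tol:
            self.phase = "III"
        if self.phase == "I":
            if g < (1.0 - self.delta_g) * self.g_init:
                self._below += 1
                if self._below >= self.sustained:
                    self.phase = "II"
            else:
                self._below = 0
        return self.phase


@dataclass(frozen=True)
class PhaseAnnotation:
    """Per-step phase labels and the two phase boundaries (times)."""

    labels: tuple[str, ...]
    t_I_II: Optional[float] = None
    t_II_III: Optional[float] = None

    def divisions_per_phase(self, timeline: Timeline) -> dict[str, int]:
        """Count division events per phase of the step they follow."""
        counts = {p: 0 for p in PHASES}
        times = [row["t"] for row in timeline.steps]
        for event in timeline.events:
            if event["kind"] != "division":
                continue
            idx = max(0, sum(1 for t in times if t < event["t"] - 1e-12) - 1)
            counts[self.labels[idx]] += 1
        return counts


def segment_phases(timeline: Timeline, delta_g: float = 0.01,
                   sustained: int = 3,
                   etoh_tol: float = 1e-6) -> PhaseAnnotation:
    """Segment a timeline into phases I/II/III (labels monotone).

    Applies the same causal criteria as the live tracker used during
    perturbed runs; degenerate (constant-growth) timelines come out as a
    single phase I.
    """
    if not timeline.steps:
        raise ValueError("timeline is empty")
    tracker = PhaseTracker(delta_g=delta_g, sustained=sustained,
                           etoh_tol=etoh_tol)
    labels = []
    t_I_II = t_II_III = None
    for row in timeline.steps:
        prev = tracker.phase
        label = tracker.step(row["g"], row.get("ethanol_exchange", 0.0))
        if prev == "I" and label != "I" and t_I_II is None:
            t_I_II = row["t"]
        if prev != "III" and label == "III" and t_II_III is None:
            t_II_III = row["t"]
        labels.append(label)
    return PhaseAnnotation(tuple(labels), t_I_II, t_II_III)


@dataclass(frozen=True)
class PerturbationSpec:
    """Enzyme deletion or overexpression, optionally scoped to a phase.

    Deletion clamps the usage of the enzymes (an isoenzyme group is just
    several ids) to zero during scoped steps; overexpression fixes the
    usage to 150% of the step's post-regulation optimal usage.
    """

    enzymes: tuple[str, ...]
    mode: str = "deletion"            # or "overexpression"
    scope: str = "life"               # "life", "I", "II" or "III"

    def __post_init__(self):
        if self.mode not in ("deletion", "overexpression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scope not in ("life",) + PHASES:
            raise ValueError(f"unknown scope {self.scope!r}")
        object.__setattr__(self, "enzymes", tuple(self.enzymes))

    def applies(self, phase: str) -> bool:
        return self.scope == "life" or phase == self.scope


def sweep(model: MetabolicModel, net: BooleanNetwork, table: RegulationTable,
          f0_values: Sequence[float], r0_values: Sequence[float],
          epsilon_values: Sequence[float],
          params: SimParams) -> pd.DataFrame:
    """One lifespan simulation per grid point over (f0, r0, epsilon).

    Returns a table with the replicative lifespan, mean generation time,
    per-phase division counts, damage at death and the censoring flag.
    Per-cell errors are logged and flagged; the sweep continues.
    """
    import dataclasses
    rows = []
    for f0, r0, eps in itertools.product(f0_values, r0_values, epsilon_values):
        row = {"f0": f0, "r0": r0, "epsilon": eps, "error": None}
        try:
            p = dataclasses.replace(params, f0=f0, r0=r0, epsilon=eps)
            tl = simulate_lifespan(model, net, table, p)
            ann = segment_phases(tl)
            per_phase = ann.divisions_per_phase(tl)
            gen = tl.generation_times
            row.update({
                "lifespan": tl.n_divisions,
                "mean_generation_time": sum(gen) / len(gen) if gen else float("nan"),
                "divisions_I": per_phase["I"],
                "divisions_II": per_phase["II"],
                "divisions_III": per_phase["III"],
                "damage_at_death": tl.steps[-1]["D"] if tl.steps else float("nan"),
                "censored": tl.censored,
            })
        except Exception as err:  # propagate per-cell, keep sweeping
            logger.error("sweep point f0=%g r0=%g eps=%g failed: %s",
                         f0, r0, eps, err)
            row["error"] = str(err)
        rows.append(row)
    return pd.DataFrame(rows)


def chemostat(model: MetabolicModel,
              rates: Iterable[float]) -> pd.DataFrame:
    """Exchange fluxes at fixed dilution rates (growth pinned, glucose
    minimised, then parsimony).  Rates above the maximal growth rate are
    flagged infeasible."""
    rows = []
    roles = ("glucose_uptake", "ethanol_exchange", "o2_uptake",
             "co2_exchange", "acetate_exchange")
    for rate in rates:
        sol = solve_chemostat(model, rate)
        row = {"dilution_rate": rate, "feasible": sol.feasible}
        for role in roles:
            rid = model.specials.get(role)
            row[role] = sol.flux.get(rid, float("nan")) if sol.feasible else float("nan")
        row["total_usage"] = sol.total_usage if sol.feasible else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def critical_dilution(model: MetabolicModel, lo: float = 0.0,
                      hi: float = 1.0, tol: float = 1e-4,
                      etoh_tol: float = 1e-6) -> Optional[float]:
    """Bisection for the dilution rate where ethanol overflow starts.

    Returns the critical rate (ethanol production switches on above it)
    or None if no switch exists in [lo, hi].
    """
    etoh_id = model.special("ethanol_exchange")

    def overflows(rate: float) -> Optional[bool]:
        sol = solve_chemostat(model, rate)
        if not sol.feasible:
            return None
        return sol.flux[etoh_id] > etoh_tol

    if overflows(lo) is None:
        return None  # even the lowest rate is infeasible
    f_hi = overflows(hi)
    if f_hi is None:
        # pull hi down to the highest feasible rate first
        a, b = lo, hi
        while b - a > tol:
            mid = 0.5 * (a + b)
            if overflows(mid) is None:
                b = mid
            else:
                a = mid
        hi, f_hi = a, overflows(a)
    if overflows(lo) or not f_hi:
        return None  # already overflowing at lo, or never overflows
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if overflows(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def cumulative_usage(timeline: Timeline,
                     annotation: Optional[PhaseAnnotation] = None,
                     phase: Optional[str] = None) -> dict[str, float]:
    """Integrated enzyme usage (sum of usage*dt) over the recorded life.

    With ``phase`` given (needs ``annotation``), only steps labelled
    with that phase contribute.
    """
    if phase is not None and annotation is None:
        raise ValueError("phase filtering requires a PhaseAnnotation")
    dt = timeline.params.dt if timeline.params else 1.0
    totals: dict[str, float] = {}
    for i, row in enumerate(timeline.steps):
        if phase is not None and annotation.labels[i] != phase:
            continue
        for key, value in row.items():
            if key.startswith("u_"):
                totals[key[2:]] = totals.get(key[2:], 0.0) + value * dt
    return totals
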