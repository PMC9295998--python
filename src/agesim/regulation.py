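"""Transcriptional regulation layer between signalling and metabolism.

Three translations happen here.  Optimal fluxes are turned into Boolean
input states by thresholding: glucose is present when the uptake flux
exceeds ``glc_cin``, oxidative stress (H2O2) when the protein-damage
production flux exceeds ``d_c``, and thioredoxin when the Trx1/2 enzyme
usage exceeds ``trx_c`` (all strict inequalities).  Steady-state
transcription-factor activities are turned into per-enzyme decisions via
signed ranks: for each enzyme the net rank is the number of active
activating TFs minus the number of active repressing TFs.  Finally the
decision tightens the enzyme's usage bounds by a fraction ``epsilon`` of
its admissible range ``delta_i`` from enzyme variability analysis:

    upregulated   (rank > 0):  e_min <- e_min + delta_i * epsilon
    downregulated (rank < 0):  e_max <- e_max - delta_i * epsilon

Ties (rank 0) regulate nothing.  Bounds are never allowed to cross; if a
tightening would push ``e_min`` past ``e_max`` both are capped at the
midpoint of the overlap.  A FIFO buffer of TF states implements the
delay of ``n_delay`` steps between a signalling event and its effect on
gene expression.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Mapping

from .boolean import BooleanNetwork, BooleanState
from .ecfba import FluxSolution, MetabolicModel, VariabilityResult

__all__ = [
    "RegulationTable",
    "InputThresholds",
    "DelayBuffer",
    "derive_inputs",
    "net_ranks",
    "regulate",
]


@dataclass(frozen=True)
class RegulationTable:
    """Signed transcription-factor -> enzyme map.

    ``entries`` maps a TF name to a set of ``(enzyme_id, sign)`` pairs
    with sign +1 (activation) or -1 (repression).
    """

    entries: Mapping[str, frozenset[tuple[str, int]]]

    def __post_init__(self):
        clean = {}
        for tf, targets in self.entries.items():
            seen_enzymes = set()
            for enzyme, sign in targets:
                if sign not in (1, -1):
                    raise ValueError(
                        f"sign for ({tf}, {enzyme}) must be +1 or -1")
                if enzyme in seen_enzymes:
                    raise ValueError(f"duplicate pair ({tf}, {enzyme})")
                seen_enzymes.add(enzyme)
            clean[tf] = frozenset(targets)
        object.__setattr__(self, "entries", clean)

    @property
    def transcription_factors(self) -> set[str]:
        return set(self.entries)

    @property
    def enzymes(self) -> set[str]:
        return {enz for targets in self.entries.values() for enz, _ in targets}

    def validate_against(self, net: BooleanNetwork,
                         model: MetabolicModel) -> None:
        comps = set(net.components)
        enz = {e.id for e in model.enzymes}
        for tf in self.transcription_factors:
            if tf not in comps:
                raise ValueError(
                    f"regulation table TF {tf!r} is not a Boolean component")
        for e in self.enzymes:
            if e not in enz:
                raise ValueError(
                    f"regulation table enzyme {e!r} is not in the metabolic model")

    def flipped(self) -> "RegulationTable":
        """Table with every sign negated (up/down swap)."""
        return RegulationTable({
            tf: frozenset((enz, -sign) for enz, sign in targets)
            for tf, targets in self.entries.items()
        })


@dataclass(frozen=True)
class InputThresholds:
    """Critical fluxes switching Boolean inputs on (strict '>')."""

    glc_cin: float = 0.1      # glucose uptake [mmol gDW^-1 h^-1]
    d_c: float = 1.5e-3       # damage-production flux
    trx_c: float = 1e-6       # Trx1/2 usage

    def __post_init__(self):
        if min(self.glc_cin, self.d_c, self.trx_c) < 0:
            raise ValueError("thresholds must be >= 0")


class DelayBuffer:
    """FIFO queue of TF-activity states of fixed length ``n_delay``.

    Pushing the current state pops and returns the state from
    ``n_delay`` steps ago; ``n_delay = 0`` is the identity.
    """

    def __init__(self, initial: BooleanState, n_delay: int):
        if n_delay < 0:
            raise ValueError("n_delay must be >= 0")
        self.n_delay = n_delay
        self._queue: deque[BooleanState] = deque(
            [initial] * n_delay, maxlen=max(n_delay, 1))

    def push(self, current: BooleanState) -> BooleanState:
        if self.n_delay == 0:
            return current
        delayed = self._queue.popleft()
        self._queue.append(current)
        return delayed

    def __len__(self) -> int:
        return self.n_delay


def derive_inputs(solution: FluxSolution, model: MetabolicModel,
                  thresholds: InputThresholds,
                  trx_enzymes: tuple[str, ...] = ("Trx1", "Trx2"),
                  extra: Mapping[str, int] | None = None,
                  trx_solution: FluxSolution | None = None) -> dict[str, int]:
    """Boolean input states derived from an ecFBA solution.

    Returns a dict with keys ``Glucose``, ``H2O2`` and ``Trx12`` (plus
    any ``extra`` inputs taken verbatim from configuration).  Glucose
    and oxidative stress are instantaneous fluxes of ``solution``; the
    thioredoxin presence reflects expressed protein, so its usage may be
    read from a different (e.g. the previous step's regulated) solution
    via ``trx_solution``.
    """
    if not solution.feasible:
        raise ValueError("cannot derive inputs from an infeasible solution")
    glc_id = model.special("glucose_uptake")
    try:
        glc_uptake = solution.flux[glc_id]
    except KeyError:
        raise KeyError(f"solution lacks glucose-uptake flux {glc_id!r}")
    trx_from = trx_solution if trx_solution is not None else solution
    trx_usage = 0.0
    for eid in trx_enzymes:
        trx_usage += trx_from.usage.get(eid, 0.0)
    inputs = {
        "Glucose": int(glc_uptake > thresholds.glc_cin),
        "H2O2": int(solution.damage_formation > thresholds.d_c),
        "Trx12": int(trx_usage > thresholds.trx_c),
    }
    if extra:
        inputs.update({k: int(v) for k, v in extra.items()})
    return inputs


def net_ranks(tf_state: BooleanState,
              table: RegulationTable) -> dict[str, int]:
    """Net regulation rank per enzyme: sum of signs over *active* TFs."""
    ranks: dict[str, int] = {}
    for tf, targets in table.entries.items():
        if tf_state[tf] != 1:
            continue
        for enzyme, sign in targets:
            ranks[enzyme] = ranks.get(enzyme, 0) + sign
    return ranks


def regulate(model: MetabolicModel, tf_state: BooleanState,
             table: RegulationTable, variability: VariabilityResult,
             epsilon: float) -> MetabolicModel:
    """Tighten enzyme bounds according to the active-TF net ranks.

    Enzymes with positive net rank get their lower usage bound raised by
    ``delta_i * epsilon``; negative net rank lowers the upper bound by
    the same amount; rank 0 leaves the enzyme untouched.  Bounds never
    cross: a tightening that would invert them is capped at the midpoint
    of the previous interval overlap.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return model
    ranks = net_ranks(tf_state, table)
    updates: dict[str, tuple[float, float]] = {}
    for eid, rank in ranks.items():
        if rank == 0:
            continue
        enzyme = model.enzyme(eid)  # KeyError for unknown enzyme
        try:
            delta = variability.delta[eid]
        except KeyError:
            raise KeyError(f"no variability range for regulated enzyme {eid!r}")
        e_min, e_max = enzyme.e_min, enzyme.e_max
        if rank > 0:
            e_min = e_min + delta * epsilon
        else:
            e_max = e_max - delta * epsilon
        if e_min > e_max:
            mid = 0.5 * (max(enzyme.e_min, e_max) + min(enzyme.e_max, e_min))
            mid = min(max(mid, enzyme.e_min), enzyme.e_max)
            e_min = e_max = mid
        updates[eid] = (e_min, e_max)
    if not updates:
        return model
    return model.with_enzyme_bounds(updates)
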