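"""Deterministic Boolean reachability twin of the stochastic simulator.

Treats the net qualitatively: a place is ON if it is an entry with tokens or
if some transition with all activating inputs ON feeds it.  Inhibition is
applied as a single demotion pass after the monotone fixpoint (iterated
negation has no unambiguous fixpoint; inhibition cycles are a documented
limitation and absent from the bundled model).  Used to validate wiring and
to cross-check that stochastic summaries are positive exactly on the
reachable outputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Marking
    from .model import PetriNetModel


@dataclass(frozen=True)
class ReachabilitySet:
    on_places: frozenset[str]
    fixpoint_iterations: int

    def __contains__(self, pid: str) -> bool:
        return pid in self.on_places


@dataclass(frozen=True)
class QualitativeCalls:
    """Active/inactive call per output place, with any oracle/simulation
    disagreements surfaced rather than silently resolved."""

    calls: dict[str, str]
    disagreements: tuple[str, ...]


def forward_closure(model: "PetriNetModel", seeds: set[str]) -> set[str]:
    """Least fixpoint of the firing rule, ignoring inhibition."""
    on = set(seeds)
    changed = True
    while changed:
        changed = False
        for t in model.transitions:
            if all(p in on for p in t.activating_inputs):
                for p in t.outputs:
                    if p not in on:
                        on.add(p)
                        changed = True
    return on


def reachable_places(model: "PetriNetModel", marking: "Marking") -> ReachabilitySet:
    """Places qualitatively ON under the marking's positive-token pattern."""
    marking.validate_against(model)
    seeds = {
        p.id for p in model.entry_places if marking.get(p.id) > 0
    }
    on = set(seeds)
    iterations = 0
    changed = True
    while changed:
        changed = False
        iterations += 1
        for t in model.transitions:
            if all(p in on for p in t.activating_inputs):
                for p in t.outputs:
                    if p not in on:
                        on.add(p)
                        changed = True
    # single demotion pass: a place loses ON status if every enabled
    # transition feeding it is blocked by an ON inhibitor
    pre = frozenset(on)
    for pid in pre:
        if pid in seeds:
            continue
        feeding = [
            t for t in model.transitions
            if pid in t.outputs and all(p in pre for p in t.activating_inputs)
        ]
        if feeding and all(
            any(i in pre for i in t.inhibitory_inputs) for t in feeding
        ):
            on.discard(pid)
    return ReachabilitySet(frozenset(on), iterations)


def qualitative_call(model: "PetriNetModel", marking: "Marking",
                     summary: dict[str, float],
                     epsilon: float = 0.0) -> QualitativeCalls:
    """Combine Boolean reachability with a simulation summary.

    A place is *active* iff it is reachable and its summary exceeds
    ``epsilon``; places where the two criteria disagree are listed in
    ``disagreements``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    rs = reachable_places(model, marking)
    calls: dict[str, str] = {}
    disagreements: list[str] = []
    for pid, value in summary.items():
        reach = pid in rs
        hot = value > epsilon
        calls[pid] = "active" if (reach and hot) else "inactive"
        if reach != hot:
            disagreements.append(pid)
    return QualitativeCalls(calls, tuple(disagreements))
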