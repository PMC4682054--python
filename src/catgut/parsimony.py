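"""Parsimony pathway inference (minimal set cover of observed KOs).

Because single ortholog groups belong to multiple pathways, the raw set
of pathways containing at least one observed KO over-reports the
community's functional potential.  The parsimony rule keeps only a
minimum-cardinality set of pathways that still covers every observed
mapped KO, discarding pathways inferred solely through shared
multi-pathway KOs.

The exact minimum cover is found by integer programming (HiGHS via
scipy); the classical greedy heuristic (repeatedly take the pathway
covering most uncovered KOs) scales to large instances and is within the
ln(max pathway size) + 1 approximation bound.  Ties break by pathway id,
so results are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tables import KeggHierarchy

__all__ = ["ParsimonyResult", "parsimony_pathways"]

log = logging.getLogger(__name__)

#: exact ILP is default up to this many candidate pathways
EXACT_LIMIT = 25


@dataclass
class ParsimonyResult:
    retained: list
    removed: list
    #: pathway -> number of observed KOs it contains
    explained: dict
    solver: str
    dropped_kos: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.retained) & set(self.removed):
            raise ValueError("retained and removed overlap")


def _greedy_cover(observed: set, pw_members: dict[str, frozenset]) -> list:
    uncovered = set(observed)
    chosen = []
    while uncovered:
        best = max(sorted(pw_members),
                   key=lambda p: (len(pw_members[p] & uncovered), ))
        gain = len(pw_members[best] & uncovered)
        if gain == 0:
            raise AssertionError("uncovered KOs remain but no pathway helps")
        # deterministic tie-break: smallest id among maximal gains
        best = min(p for p in pw_members
                   if len(pw_members[p] & uncovered) == gain)
        chosen.append(best)
        uncovered -= pw_members[best]
    return sorted(chosen)


def _exact_cover(observed: set, pw_members: dict[str, frozenset]) -> list:
    from scipy.optimize import LinearConstraint, milp

    pws = sorted(pw_members)
    kos = sorted(observed)
    A = np.zeros((len(kos), len(pws)))
    for j, p in enumerate(pws):
        for ko in pw_members[p]:
            A[kos.index(ko), j] = 1.0
    # minimise pathway count; an id-ordered perturbation (summing to < 1,
    # and large enough for solver tolerances) makes the optimum unique so
    # ties break lexicographically
    n = len(pws)
    c = np.ones(n) + np.arange(n) / (10.0 * n * n + 10.0)
    res = milp(c, constraints=LinearConstraint(A, lb=1.0),
               integrality=np.ones(len(pws)), bounds=(0, 1))
    if not res.success:
        raise RuntimeError(f"ILP set cover failed: {res.message}")
    return sorted(p for p, x in zip(pws, res.x) if x > 0.5)


def parsimony_pathways(observed_kos, h: KeggHierarchy,
                       solver: str = "auto") -> ParsimonyResult:
    """Minimum set of pathways explaining all observed mapped KOs.

    Pathways containing no observed KO are never candidates and count as
    removed.  KOs absent from the hierarchy (or mapped to no pathway)
    are dropped with a warning.  ``solver``: "exact" (ILP), "greedy", or
    "auto" (exact up to 25 candidate pathways, greedy above).
    """
    if solver not in ("auto", "greedy", "exact"):
        raise ValueError(f"unknown solver {solver!r}")
    observed = set(observed_kos)
    mapped, dropped = set(), []
    for ko in sorted(observed):
        if h.ko_to_pathways.get(ko):
            mapped.add(ko)
        else:
            dropped.append(ko)
    if dropped:
        log.warning("%d observed KOs have no pathway mapping; excluded",
                    len(dropped))

    all_members = h.pathway_to_kos()
    candidates = {p: m & mapped for p, m in all_members.items() if m & mapped}
    if not mapped:
        return ParsimonyResult([], sorted(h.pathway_to_group), {}, "none", dropped)

    if solver == "auto":
        solver = "exact" if len(candidates) <= EXACT_LIMIT else "greedy"
    members = {p: frozenset(m) for p, m in candidates.items()}
    retained = (_exact_cover(mapped, members) if solver == "exact"
                else _greedy_cover(mapped, members))

    covered = set().union(*(members[p] for p in retained)) if retained else set()
    assert covered == mapped, "cover invariant violated"
    removed = sorted(set(h.pathway_to_group) - set(retained))
    explained = {p: len(candidates.get(p, ())) for p in h.pathway_to_group}
    return ParsimonyResult(retained, removed, explained, solver, dropped)
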