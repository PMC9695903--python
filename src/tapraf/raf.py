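"""RAF (reflexively autocatalytic, food-generated) set detection.

A reaction subset R of a catalytic reaction system is an RAF when

1. every reaction in R is catalyzed by at least one molecule available
   within R (i.e. a catalyst inside the food-set closure of R), and
2. every molecule involved in R can be built from the food set using
   only reactions of R (all reactants lie in the closure of R).

The union of RAF subsets is itself an RAF, so a unique maximal RAF
(maxRAF) exists; it is computed here by the standard iterative-reduction
algorithm (alternate closure computation with removal of unsupported or
uncatalyzed reactions until a fixed point).  A brute-force enumerator
over all subsets is provided as an independent testing oracle, and a
seeded reduction procedure extracts irreducible (minimal) RAFs.

Because food species never catalyze in this model, the catalysis test
reduces to "at least one catalyst lies in the closure"; food species in
a catalyst set are rejected when the system is constructed, not silently
ignored here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .crs import CatalyticReactionSystem, CRSError, closure

__all__ = [
    "RafResult",
    "NoRafError",
    "is_raf",
    "max_raf",
    "brute_force_max_raf",
    "all_reactions_catalyzed",
    "find_minimal_raf",
]

#: Largest reaction count the brute-force oracle will enumerate (2^n subsets).
BRUTE_FORCE_CAP = 15


class NoRafError(CRSError):
    """Raised when an operation requires an RAF but none exists."""


@dataclass(frozen=True)
class RafResult:
    """A (possibly empty) RAF: reaction ids plus their molecule support.

    ``molecules`` is the union of the food set, reactants, products and
    the *available* catalysts (those inside the subset's closure) of the
    member reactions; catalysts outside the closure are not part of the
    self-sustaining set.  Both fields are empty for the empty result.
    """

    reactions: frozenset[int]
    molecules: frozenset[int]

    @property
    def is_empty(self) -> bool:
        return not self.reactions

    @property
    def size(self) -> int:
        return len(self.reactions)


def _support(
    system: CatalyticReactionSystem, reaction_ids: frozenset[int]
) -> frozenset[int]:
    if not reaction_ids:
        return frozenset()
    w = closure(system, reaction_ids)
    mols = set(system.food)
    for rid in reaction_ids:
        r = system.reaction(rid)
        mols.update(r.reactants)
        mols.add(r.product)
        mols.update(r.catalysts & w)
    return frozenset(mols)


def _result(system: CatalyticReactionSystem, ids: Iterable[int]) -> RafResult:
    ids = frozenset(ids)
    return RafResult(reactions=ids, molecules=_support(system, ids))


def is_raf(system: CatalyticReactionSystem, reaction_ids: Iterable[int]) -> bool:
    """Test RAF conditions 1 and 2 directly on a non-empty reaction subset."""
    ids = frozenset(reaction_ids)
    if not ids:
        return False
    w = closure(system, ids)
    for rid in ids:
        r = system.reaction(rid)
        if not set(r.reactants) <= w:
            return False
        if not (r.catalysts & w):
            return False
    return True


def max_raf(
    system: CatalyticReactionSystem, within: Iterable[int] | None = None
) -> RafResult:
    """Maximal RAF of the system (union of all RAF subsets); empty allowed.

    Iteratively computes the closure of the surviving reaction set and
    removes every reaction with a reactant outside the closure or no
    catalyst inside it, until no reaction is removed.

    Parameters
    ----------
    system : CatalyticReactionSystem
    within : iterable of int, optional
        Restrict the search to this reaction-id subset (used by the
        minimal-RAF reduction); defaults to the whole system.
    """
    if within is None:
        current = set(system.reaction_ids())
    else:
        current = set(within)
        unknown = current - system.reaction_ids()
        if unknown:
            raise CRSError(f"unknown reaction ids {sorted(unknown)}")
    while current:
        w = closure(system, current)
        keep = {
            rid
            for rid in current
            if set(system.reaction(rid).reactants) <= w
            and system.reaction(rid).catalysts & w
        }
        if keep == current:
            break
        current = keep
    return _result(system, current)


def brute_force_max_raf(
    system: CatalyticReactionSystem, cap: int = BRUTE_FORCE_CAP
) -> RafResult:
    """Union of all RAF subsets found by exhaustive enumeration.

    Tests the two RAF conditions directly on every non-empty reaction
    subset; intended as an independent oracle for :func:`max_raf` on
    small systems.  Refuses systems with more than ``cap`` reactions.
    """
    ids = sorted(system.reaction_ids())
    n = len(ids)
    if n > cap:
        raise CRSError(
            f"brute-force enumeration refused: {n} reactions exceeds cap {cap}"
        )
    union: set[int] = set()
    for mask in range(1, 1 << n):
        subset = [ids[k] for k in range(n) if mask >> k & 1]
        if is_raf(system, subset):
            union.update(subset)
    return _result(system, union)


def all_reactions_catalyzed(system: CatalyticReactionSystem) -> bool:
    """True iff every reaction carries at least one catalyst.

    For TAP-generated systems (which are food-generated by construction,
    every product tracing back to the food set through its own creation
    history) this is exactly the event that the *entire* network is an
    RAF.  Vacuously true for a system with no reactions.
    """
    return all(r.catalysts for r in system.reactions)


def find_minimal_raf(system: CatalyticReactionSystem, seed: int) -> RafResult:
    """An irreducible RAF, found by seeded random reduction of the maxRAF.

    Repeatedly attempts to drop one reaction (in seeded-shuffle order)
    and recomputes the maxRAF of the remainder; a drop is kept whenever a
    non-empty RAF survives.  The result is an RAF from which no single
    reaction can be removed without destroying the RAF property.  Which
    minimal RAF is returned depends on the seed.
    """
    base = max_raf(system)
    if base.is_empty:
        raise NoRafError("no RAF exists in this system")
    rng = np.random.default_rng(seed)
    current = set(base.reactions)
    reduced = True
    while reduced:
        reduced = False
        order = sorted(current)
        rng.shuffle(order)
        for rid in order:
            if rid not in current:
                continue
            survivor = max_raf(system, within=current - {rid})
            if not survivor.is_empty:
                current = set(survivor.reactions)
                reduced = True
                break
    return _result(system, current)
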