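"""Catalytic reaction systems (CRS).

A CRS is the structural object RAF analysis operates on: a food set of
freely available molecular species, a collection of single-product
reactions, and a catalysis map assigning (non-food) species as catalysts
of reactions.  The systems produced by the TAP simulator have one
distinguishing structural property: every non-food species is the product
of exactly one reaction, so the number of reactions always equals the
number of species minus the food-set size.  That invariant is enforced at
construction time.

Species are labeled by positive integers; the food set is always
``{1, ..., M0}`` and newly created species continue the numbering in
creation order.  Food species never act as catalysts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "CRSError",
    "Species",
    "Reaction",
    "CatalyticReactionSystem",
    "closure",
]


class CRSError(ValueError):
    """Raised when a catalytic reaction system violates its invariants."""


@dataclass(frozen=True)
class Species:
    """A molecular species: an integer label plus its food-set membership."""

    id: int
    is_food: bool


@dataclass(frozen=True)
class Reaction:
    """A single-product reaction.

    Parameters
    ----------
    id : int
        Reaction label, unique within a system.  TAP-generated systems
        number reactions in creation order, reaction ``k`` producing
        species ``M0 + k``.
    reactants : tuple of int
        Reactant species, multiset-like: a species may appear more than
        once (e.g. ``1 + 1 -> a``).  Closure semantics only require each
        *distinct* reactant species to be available.
    product : int
        The single species produced.  Never a food species.
    catalysts : frozenset of int
        Species catalyzing this reaction.  Food species cannot catalyze.
    """

    id: int
    reactants: tuple[int, ...]
    product: int
    catalysts: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.reactants) == 0:
            raise CRSError(f"reaction {self.id}: empty reactant list")
        if any(r < 1 for r in self.reactants):
            raise CRSError(f"reaction {self.id}: species labels must be positive")
        if self.product < 1:
            raise CRSError(f"reaction {self.id}: species labels must be positive")
        if not isinstance(self.catalysts, frozenset):
            object.__setattr__(self, "catalysts", frozenset(self.catalysts))
        if not isinstance(self.reactants, tuple):
            object.__setattr__(self, "reactants", tuple(self.reactants))


@dataclass(frozen=True)
class CatalyticReactionSystem:
    """A food set plus single-product reactions with catalysis assignments.

    Invariants enforced on construction:

    * the food set is exactly ``{1, ..., M0}``;
    * every non-food species is the product of exactly one reaction, so
      ``|reactions| == |species| - |food|``;
    * products are never food species;
    * catalysts are never food species and always exist in the system;
    * every reactant is a species of the system (food or some product).
    """

    food: frozenset[int]
    reactions: tuple[Reaction, ...]
    _by_id: Mapping[int, Reaction] = field(
        init=False, repr=False, compare=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        food = frozenset(self.food)
        object.__setattr__(self, "food", food)
        reactions = tuple(sorted(self.reactions, key=lambda r: r.id))
        object.__setattr__(self, "reactions", reactions)
        self._validate()
        object.__setattr__(self, "_by_id", {r.id: r for r in reactions})

    def _validate(self) -> None:
        if not self.food:
            raise CRSError("food set is empty")
        m0 = len(self.food)
        if self.food != frozenset(range(1, m0 + 1)):
            raise CRSError(f"food set must be exactly 1..{m0}, got {sorted(self.food)}")
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            raise CRSError("duplicate reaction ids")
        products = [r.product for r in self.reactions]
        if len(set(products)) != len(products):
            raise CRSError("a species is the product of more than one reaction")
        prod_set = frozenset(products)
        if prod_set & self.food:
            bad = sorted(prod_set & self.food)
            raise CRSError(f"food species cannot be reaction products: {bad}")
        species = self.food | prod_set
        for r in self.reactions:
            missing = set(r.reactants) - species
            if missing:
                raise CRSError(
                    f"reaction {r.id}: unknown reactant species {sorted(missing)}"
                )
            if r.catalysts & self.food:
                bad = sorted(r.catalysts & self.food)
                raise CRSError(f"reaction {r.id}: food species cannot catalyze: {bad}")
            unknown = r.catalysts - species
            if unknown:
                raise CRSError(
                    f"reaction {r.id}: unknown catalyst species {sorted(unknown)}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def species_ids(self) -> frozenset[int]:
        """All species labels: food plus every reaction product."""
        return self.food | frozenset(r.product for r in self.reactions)

    @property
    def species(self) -> tuple[Species, ...]:
        return tuple(
            Species(id=s, is_food=s in self.food) for s in sorted(self.species_ids)
        )

    @property
    def n_species(self) -> int:
        return len(self.food) + len(self.reactions)

    def reaction(self, rid: int) -> Reaction:
        try:
            return self._by_id[rid]
        except KeyError:
            raise CRSError(f"unknown reaction id {rid}") from None

    def reaction_ids(self) -> frozenset[int]:
        return frozenset(self._by_id)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)


def closure(
    system: CatalyticReactionSystem, reaction_ids: Iterable[int] | None = None
) -> frozenset[int]:
    """Food-set closure of a reaction subset.

    Returns the smallest superset ``W`` of the food set such that whenever
    every (distinct) reactant of a reaction in the subset lies in ``W``,
    its product lies in ``W``.  Computed by support-counting propagation,
    linear in the total reactant arity of the subset.

    Parameters
    ----------
    system : CatalyticReactionSystem
    reaction_ids : iterable of int, optional
        Subset of the system's reaction ids; defaults to all reactions.
    """
    if reaction_ids is None:
        subset = list(system.reactions)
    else:
        subset = [system.reaction(rid) for rid in set(reaction_ids)]

    # For each reaction: number of distinct reactant species not yet in W.
    pending: dict[int, int] = {}
    needed_by: dict[int, list[int]] = defaultdict(list)  # species -> reaction idx
    w = set(system.food)
    ready: list[int] = []
    for idx, r in enumerate(subset):
        need = set(r.reactants) - w
        pending[idx] = len(need)
        for s in need:
            needed_by[s].append(idx)
        if not need:
            ready.append(idx)

    while ready:
        idx = ready.pop()
        prod = subset[idx].product
        if prod in w:
            continue
        w.add(prod)
        for jdx in needed_by.get(prod, ()):
            pending[jdx] -= 1
            if pending[jdx] == 0:
                ready.append(jdx)
    return frozenset(w)
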