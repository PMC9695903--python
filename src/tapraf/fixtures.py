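"""Small catalytic reaction systems with known RAF structure.

Hand-built and seeded-random systems used as test inputs and CLI demo
material.  The ``nested_raf`` system is a synthetic analogue of the
classic nested-autocatalytic-network picture: its maxRAF strictly
contains at least two distinct smaller RAFs, one of them inside the
other's union.  None of these claims to reproduce a published network —
they exhibit the named structural property by construction.
"""

from __future__ import annotations

import numpy as np

from .crs import CatalyticReactionSystem, Reaction

__all__ = ["make_test_fixture", "random_crs", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("nested_raf", "no_raf", "full_raf", "random_small")


def random_crs(
    seed: int,
    n_reactions: int = 8,
    M0: int = 3,
    max_arity: int = 3,
    catalysis_prob: float = 0.2,
) -> CatalyticReactionSystem:
    """A random small CRS: random reactant wiring, random catalysis.

    Reaction ``k`` produces species ``M0 + k``; reactants are drawn from
    *all* species labels (forward references allowed, creating cyclic
    dependency structure the RAF machinery must handle); each non-food
    species independently catalyzes each reaction with probability
    ``catalysis_prob``.
    """
    rng = np.random.default_rng(seed)
    n_species = M0 + n_reactions
    nonfood = np.arange(M0 + 1, n_species + 1)
    reactions = []
    for k in range(1, n_reactions + 1):
        arity = min(int(rng.integers(1, max_arity + 1)), n_species)
        reactants = tuple(
            sorted(int(s) for s in rng.choice(n_species, size=arity, replace=False) + 1)
        )
        cats = frozenset(
            int(y) for y in nonfood[rng.random(len(nonfood)) < catalysis_prob]
        )
        reactions.append(
            Reaction(id=k, reactants=reactants, product=M0 + k, catalysts=cats)
        )
    return CatalyticReactionSystem(
        food=frozenset(range(1, M0 + 1)), reactions=tuple(reactions)
    )


def _nested_raf() -> CatalyticReactionSystem:
    # maxRAF = {r1..r6}; smaller RAFs include {r1,r2}, {r5,r6} and
    # {r1,r2,r3,r4} — nested and mutually distinct.
    reactions = (
        Reaction(1, (1, 2), 3, frozenset({4})),
        Reaction(2, (3,), 4, frozenset({3})),
        Reaction(3, (2, 4), 5, frozenset({6})),
        Reaction(4, (3, 5), 6, frozenset({5})),
        Reaction(5, (1,), 7, frozenset({8})),
        Reaction(6, (7,), 8, frozenset({7})),
    )
    return CatalyticReactionSystem(food=frozenset({1, 2}), reactions=reactions)


def _no_raf() -> CatalyticReactionSystem:
    # r2 is uncatalyzed and r1's only catalyst needs r2's product.
    reactions = (
        Reaction(1, (1,), 2, frozenset({3})),
        Reaction(2, (2,), 3, frozenset()),
    )
    return CatalyticReactionSystem(food=frozenset({1}), reactions=reactions)


def _full_raf() -> CatalyticReactionSystem:
    reactions = (
        Reaction(1, (1, 1), 2, frozenset({2})),
        Reaction(2, (1, 2), 3, frozenset({2, 3})),
    )
    return CatalyticReactionSystem(food=frozenset({1}), reactions=reactions)


def make_test_fixture(kind: str, seed: int = 0) -> CatalyticReactionSystem:
    """Return a small CRS with the named RAF property.

    ``kind`` is one of ``nested_raf`` (maxRAF strictly containing at
    least two distinct smaller RAFs), ``no_raf`` (empty maxRAF),
    ``full_raf`` (the whole network is an RAF) or ``random_small``
    (seeded random wiring, at most 12 reactions).
    """
    if kind == "nested_raf":
        return _nested_raf()
    if kind == "no_raf":
        return _no_raf()
    if kind == "full_raf":
        return _full_raf()
    if kind == "random_small":
        rng = np.random.default_rng(seed)
        return random_crs(seed=seed, n_reactions=int(rng.integers(4, 13)))
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
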