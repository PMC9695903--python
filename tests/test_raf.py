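"""RAF detection: maxRAF algorithm against the brute-force oracle."""

import pytest

from tapraf import (
    CatalyticReactionSystem,
    NoRafError,
    Reaction,
    all_reactions_catalyzed,
    brute_force_max_raf,
    find_minimal_raf,
    is_raf,
    max_raf,
    random_crs,
    run_tap,
    TapParams,
)
from tapraf.crs import CRSError


def _crs(food, reactions):
    return CatalyticReactionSystem(
        food=frozenset(food),
        reactions=tuple(Reaction(*r) for r in reactions),
    )


class TestMaxRaf:
    def test_self_catalyzed_food_reaction(self):
        sys_ = _crs({1}, [(1, (1, 1), 2, frozenset({2}))])
        assert max_raf(sys_).reactions == {1}

    def test_uncatalyzed_reaction_gives_empty(self):
        sys_ = _crs({1}, [(1, (1,), 2, frozenset())])
        result = max_raf(sys_)
        assert result.is_empty
        assert result.molecules == frozenset()

    def test_mutual_catalysis_pair(self):
        # r1: 1->a cat b, r2: a->b cat a; brute force over the three
        # non-empty subsets confirms {r1, r2} is the unique RAF.
        sys_ = _crs(
            {1},
            [(1, (1,), 2, frozenset({3})), (2, (2,), 3, frozenset({2}))],
        )
        assert max_raf(sys_).reactions == {1, 2}
        assert brute_force_max_raf(sys_).reactions == {1, 2}
        assert not is_raf(sys_, [1])
        assert not is_raf(sys_, [2])

    def test_support_molecules(self, full_raf_system):
        result = max_raf(full_raf_system)
        assert result.molecules == {1, 2, 3}

    def test_catalyst_outside_closure_not_in_support(self):
        # r2 has two catalysts but only species 2 is producible; the
        # unproducible catalyst 4 is not part of the self-sustaining set.
        sys_ = _crs(
            {1},
            [
                (1, (1,), 2, frozenset({2})),
                (2, (1,), 3, frozenset({2, 4})),
                (3, (3, 3), 4, frozenset()),
            ],
        )
        result = max_raf(sys_)
        assert result.reactions == {1, 2}
        assert 4 not in result.molecules

    def test_idempotent_under_restriction(self):
        for seed in range(30):
            sys_ = random_crs(seed, n_reactions=10)
            first = max_raf(sys_)
            again = max_raf(sys_, within=first.reactions)
            assert again.reactions == first.reactions

    def test_monotone_under_catalysis_addition(self):
        for seed in range(20):
            sys_ = random_crs(seed, n_reactions=8, catalysis_prob=0.15)
            before = max_raf(sys_).reactions
            nonfood = sorted(sys_.species_ids - sys_.food)
            for r in sys_.reactions:
                extra = frozenset(r.catalysts | {nonfood[seed % len(nonfood)]})
                bumped = CatalyticReactionSystem(
                    food=sys_.food,
                    reactions=tuple(
                        Reaction(q.id, q.reactants, q.product,
                                 extra if q.id == r.id else q.catalysts)
                        for q in sys_.reactions
                    ),
                )
                assert max_raf(bumped).reactions >= before

    def test_unknown_restriction_rejected(self, full_raf_system):
        with pytest.raises(CRSError, match="unknown reaction ids"):
            max_raf(full_raf_system, within={99})


class TestBruteForceOracle:
    def test_agreement_on_200_random_systems(self):
        for seed in range(200):
            sys_ = random_crs(seed, n_reactions=5 + seed % 8)
            assert max_raf(sys_).reactions == brute_force_max_raf(sys_).reactions, seed

    def test_zero_catalysis_is_empty(self):
        sys_ = random_crs(3, n_reactions=6, catalysis_prob=0.0)
        assert brute_force_max_raf(sys_).is_empty

    def test_cap_guard(self):
        sys_ = random_crs(0, n_reactions=16)
        with pytest.raises(CRSError, match="exceeds cap"):
            brute_force_max_raf(sys_)
        assert not brute_force_max_raf(sys_, cap=16).reactions - sys_.reaction_ids()


class TestAllReactionsCatalyzed:
    def test_fully_catalyzed(self, full_raf_system):
        assert all_reactions_catalyzed(full_raf_system)

    def test_one_uncatalyzed_reaction(self, no_raf_system):
        assert not all_reactions_catalyzed(no_raf_system)

    def test_equals_full_maxraf_on_simulated_systems(self):
        # On TAP-generated networks the all-reactions-catalyzed event is
        # exactly "the maxRAF covers every reaction".
        hits = 0
        for seed in range(100):
            run = run_tap(TapParams(M=40, M0=5, p=0.08, seed=seed))
            full = max_raf(run.system).size == len(run.system)
            assert all_reactions_catalyzed(run.system) == full
            hits += full
        assert 0 < hits < 100  # both outcomes exercised


class TestMinimalRaf:
    def test_irreducible_maxraf_returned_unchanged(self, full_raf_system):
        # Removing either reaction of the pair destroys the RAF, so the
        # maxRAF is already minimal.
        sys_ = _crs(
            {1},
            [(1, (1,), 2, frozenset({3})), (2, (2,), 3, frozenset({2}))],
        )
        assert find_minimal_raf(sys_, seed=0).reactions == {1, 2}

    def test_two_singleton_rafs_reduce_to_size_one(self):
        sys_ = _crs(
            {1},
            [(1, (1,), 2, frozenset({2})), (2, (1,), 3, frozenset({3}))],
        )
        assert brute_force_max_raf(sys_).reactions == {1, 2}
        result = find_minimal_raf(sys_, seed=0)
        assert result.size == 1
        assert result.reactions in ({1}, {2})

    def test_result_is_always_a_raf_and_irreducible(self):
        checked = 0
        for seed in range(60):
            sys_ = random_crs(seed, n_reactions=9, catalysis_prob=0.3)
            if max_raf(sys_).is_empty:
                continue
            checked += 1
            result = find_minimal_raf(sys_, seed=seed)
            assert is_raf(sys_, result.reactions)
            for rid in result.reactions:
                assert max_raf(sys_, within=result.reactions - {rid}).is_empty
        assert checked >= 10

    def test_empty_maxraf_raises(self, no_raf_system):
        with pytest.raises(NoRafError, match="no RAF"):
            find_minimal_raf(no_raf_system, seed=0)

    def test_seed_determinism(self, nested_raf_system):
        a = find_minimal_raf(nested_raf_system, seed=7)
        b = find_minimal_raf(nested_raf_system, seed=7)
        assert a == b


class TestFixtures:
    def test_nested_raf_structure(self, nested_raf_system):
        # The maxRAF covers all six reactions and strictly contains at
        # least two distinct smaller RAFs.
        full = max_raf(nested_raf_system)
        assert full.size == len(nested_raf_system)
        assert is_raf(nested_raf_system, {1, 2})
        assert is_raf(nested_raf_system, {5, 6})
        assert is_raf(nested_raf_system, {1, 2, 3, 4})
        mini = find_minimal_raf(nested_raf_system, seed=1)
        assert mini.size < full.size

    def test_no_raf_fixture(self, no_raf_system):
        assert max_raf(no_raf_system).is_empty

    def test_full_raf_fixture(self, full_raf_system):
        assert max_raf(full_raf_system).size == len(full_raf_system)
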