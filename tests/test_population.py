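import numpy as np
import pytest
from scipy import stats

from hawkdove.population import (
    DemographyParams,
    Population,
    ReproductionOutcome,
    attempt_reproduction,
    build_population,
    draw_lifespan,
    draw_lifespans,
    fission_group,
    fuse_group,
    maintain_groups,
    place_offspring,
)

HAWK, DOVE = 1, 0


class TestDrawLifespan:
    def test_degenerate_sd_is_exact(self, rng):
        assert all(
            draw_lifespan(150, 0, rng) == 150 for _ in range(100)
        )

    def test_moments_at_default_parameters(self, rng):
        draws = draw_lifespans(10_000, 150, 15, rng)
        assert 148.5 <= draws.mean() <= 151.5
        assert 13.5 <= draws.std() <= 16.5

    def test_clamped_at_one(self, rng):
        draws = draw_lifespans(10_000, 1, 100, rng)
        assert (draws >= 1).all()

    def test_values_are_integers(self, rng):
        assert draw_lifespans(10, 150, 15, rng).dtype == np.int64


class TestAttemptReproduction:
    def _pop(self, resources, capacity=100):
        return build_population(
            [[HAWK, DOVE, DOVE]], capacity=capacity, resources=resources
        )

    def test_below_threshold_changes_nothing(self, rng):
        pop = self._pop(29.9)
        out = attempt_reproduction(
            pop.agent(0), pop, DemographyParams(), rng
        )
        assert out is ReproductionOutcome.NOT_ELIGIBLE
        assert pop.resources[0] == 29.9
        assert pop.n == 3

    def test_rejected_at_capacity_still_costs_threshold(self, rng):
        pop = build_population(
            [[HAWK, DOVE, DOVE]], capacity=3, resources=31.0
        )
        out = attempt_reproduction(
            pop.agent(0), pop, DemographyParams(), rng
        )
        assert out is ReproductionOutcome.OFFSPRING_REJECTED
        assert pop.resources[0] == pytest.approx(1.0)
        assert pop.n == 3

    def test_placed_offspring_starts_fresh(self, rng):
        pop = self._pop(45.0)
        out = attempt_reproduction(
            pop.agent(1), pop, DemographyParams(m_r=0), rng
        )
        assert out is ReproductionOutcome.OFFSPRING_PLACED
        assert pop.n == 4
        child = pop.agent(3)
        assert child.strategy == DOVE
        assert child.age == 0
        assert child.resources == 0.0
        assert child.lifespan >= 1
        assert pop.resources[1] == pytest.approx(15.0)

    @pytest.mark.parametrize("m_r,expected", [(0.0, HAWK), (1.0, DOVE)])
    def test_mutation_boundary_cases(self, rng, m_r, expected):
        params = DemographyParams(m_r=m_r)
        for _ in range(200):
            pop = self._pop(30.0)
            attempt_reproduction(pop.agent(0), pop, params, rng)
            assert pop.agent(pop.n - 1).strategy == expected


class TestPlaceOffspring:
    def _pop_with_groups(self, n_groups, capacity=100_000):
        return build_population(
            [[DOVE, DOVE] for _ in range(n_groups)], capacity=capacity
        )

    def _place_many(self, pop, d, n, rng, **kw):
        natal = pop.group(0)
        hits = 0
        for _ in range(n):
            idx = pop.add_agents(
                np.array([DOVE], dtype=np.uint8),
                np.array([150]),
                np.array([0]),
            )[0]
            g = place_offspring(pop.agent(idx), natal, pop, d, rng, **kw)
            hits += g.id == 0
        return hits

    def test_no_dispersal_always_natal(self, rng):
        pop = self._pop_with_groups(10)
        assert self._place_many(pop, 0.0, 200, rng) == 200

    def test_full_dispersal_excludes_natal_group(self, rng):
        pop = self._pop_with_groups(400)
        assert self._place_many(pop, 1.0, 10_000, rng) == 0

    def test_half_dispersal_rate(self, rng):
        pop = self._pop_with_groups(50)
        frac = self._place_many(pop, 0.5, 10_000, rng) / 10_000
        assert 0.48 <= frac <= 0.52

    def test_single_group_degenerate_case(self, rng):
        pop = self._pop_with_groups(1)
        assert self._place_many(pop, 1.0, 50, rng) == 50

    def test_include_natal_convention(self, rng):
        pop = self._pop_with_groups(4)
        hits = self._place_many(
            pop, 1.0, 4000, rng, exclude_natal=False
        )
        # natal group drawn ~1/4 of the time
        assert 0.2 <= hits / 4000 <= 0.3


class TestFissionGroup:
    def test_even_split(self, rng):
        pop = build_population([[HAWK] * 12], capacity=100)
        g1, g2 = fission_group(pop.group(0), pop, rng)
        assert g1.size == 6 and g2.size == 6
        assert pop.group(0).size == 0
        assert pop.n == 12

    def test_odd_split_floor_ceil(self, rng):
        pop = build_population([[DOVE] * 13], capacity=100)
        g1, g2 = fission_group(pop.group(0), pop, rng)
        assert {g1.size, g2.size} == {6, 7}

    def test_too_small_to_split(self, rng):
        pop = build_population([[DOVE]], capacity=100)
        with pytest.raises(ValueError):
            fission_group(pop.group(0), pop, rng)

    def test_hypergeometric_composition(self, rng):
        # splitting 6 hawks + 6 doves: hawks per daughter follow
        # Hypergeometric(N=12, K=6, n=6)
        counts = []
        for _ in range(1000):
            pop = build_population(
                [[HAWK] * 6 + [DOVE] * 6], capacity=100
            )
            g1, _ = fission_group(pop.group(0), pop, rng)
            counts.append(
                int((pop.strategy[g1.member_indices] == HAWK).sum())
            )
        counts = np.asarray(counts)
        ref = stats.hypergeom(12, 6, 6)
        assert counts.mean() == pytest.approx(ref.mean(), abs=0.15)
        assert counts.var() == pytest.approx(ref.var(), rel=0.10)


class TestFuseGroup:
    def test_merges_into_exactly_one_other(self, rng):
        groups = [[DOVE, DOVE]] + [[HAWK] * 5 for _ in range(50)]
        pop = build_population(groups, capacity=1000)
        n_groups_before = pop.n_groups
        merged = fuse_group(pop.group(0), pop, rng)
        assert pop.group(0).size == 0
        assert merged.size == 7
        assert pop.n_groups == n_groups_before - 1
        assert pop.n == 2 + 250

    def test_single_group_is_noop(self, rng):
        pop = build_population([[DOVE, DOVE]], capacity=100)
        merged = fuse_group(pop.group(0), pop, rng)
        assert merged.id == 0
        assert pop.n_groups == 1


class TestMaintainGroups:
    def test_fusion_overflow_triggers_immediate_fission(self, rng):
        params = DemographyParams(GS_max=12, GS_min=3)
        # a group of 2 plus a group of 11: fusion makes 13 >= GS_max,
        # which must immediately fission into 6 + 7
        pop = build_population(
            [[DOVE] * 2, [HAWK] * 11], capacity=100
        )
        n_fiss, n_fus = maintain_groups(pop, params, rng)
        assert (n_fiss, n_fus) == (1, 1)
        gids, counts = pop.group_sizes()
        assert sorted(counts.tolist()) == [6, 7]
        assert pop.n == 13

    def test_all_bounds_restored(self, rng):
        params = DemographyParams(GS_max=12, GS_min=3)
        pop = build_population(
            [[DOVE] * 30, [HAWK] * 2, [DOVE] * 5, [HAWK] * 1],
            capacity=1000,
        )
        maintain_groups(pop, params, rng)
        _, counts = pop.group_sizes()
        assert counts.max() < 12
        assert (counts > 3).all()  # default fuses at size <= GS_min
        assert pop.n == 38

    def test_fuse_strictly_below_threshold_variant(self, rng):
        params = DemographyParams(
            GS_max=12, GS_min=3, fuse_at_or_below=False
        )
        pop = build_population(
            [[DOVE] * 3, [HAWK] * 5], capacity=100
        )
        n_fiss, n_fus = maintain_groups(pop, params, rng)
        assert (n_fiss, n_fus) == (0, 0)  # size 3 not below GS_min
        assert pop.n_groups == 2

    def test_single_undersized_group_left_alone(self, rng):
        params = DemographyParams(GS_max=12, GS_min=3)
        pop = build_population([[DOVE, DOVE]], capacity=100)
        maintain_groups(pop, params, rng)
        assert pop.n_groups == 1
        assert pop.n == 2

    def test_agents_conserved_under_random_churn(self, rng):
        params = DemographyParams(GS_max=12, GS_min=3)
        sizes = rng.integers(1, 30, size=40)
        pop = build_population(
            [
                list(rng.integers(0, 2, size=s))
                for s in sizes
            ],
            capacity=10_000,
        )
        total = pop.n
        hawks = pop.n_hawks
        maintain_groups(pop, params, rng)
        assert pop.n == total
        assert pop.n_hawks == hawks
        assert np.unique(pop.ids).size == total
        pop.validate()


class TestPopulationInvariants:
    def test_capacity_enforced_on_add(self):
        pop = build_population([[DOVE, DOVE]], capacity=2)
        with pytest.raises(ValueError):
            pop.add_agents(
                np.array([DOVE], dtype=np.uint8),
                np.array([150]),
                np.array([0]),
            )

    def test_initial_population_cannot_exceed_capacity(self):
        with pytest.raises(ValueError):
            build_population([[DOVE] * 5], capacity=4)

    def test_ids_stay_unique_through_churn(self, rng):
        pop = build_population([[DOVE] * 6, [HAWK] * 6], capacity=50)
        params = DemographyParams(T=1.0, m_r=0.5)
        pop.resources[:] = 5.0
        for _ in range(20):
            for i in range(pop.n):
                attempt_reproduction(pop.agent(i), pop, params, rng)
            kill = rng.random(pop.n) < 0.2
            pop.remove(kill)
            pop.validate()

    def test_demography_params_validation(self):
        with pytest.raises(ValueError, match="GS_max"):
            DemographyParams(GS_max=3, GS_min=3)
        with pytest.raises(ValueError, match="m_r"):
            DemographyParams(m_r=1.5)
        with pytest.raises(ValueError, match="d"):
            DemographyParams(d=-0.1)
        with pytest.raises(ValueError, match="T"):
            DemographyParams(T=0)

    def test_group_proxy_members(self):
        pop = build_population([[HAWK, DOVE], [DOVE]], capacity=10)
        assert pop.group(0).size == 2
        assert pop.group(1).size == 1
        assert set(pop.group(0).member_indices) == {0, 1}

    def test_strategy_closure_without_mutation(self, rng):
        # all-dove population with m_r=0 can never spawn a hawk
        pop = build_population([[DOVE] * 6], capacity=1000)
        pop.resources[:] = 100.0
        params = DemographyParams(m_r=0.0)
        for _ in range(3):
            for i in range(pop.n):
                attempt_reproduction(pop.agent(i), pop, params, rng)
        assert pop.n_hawks == 0
        assert pop.n > 6
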