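"""Lévy flights, dominance machinery and the cuckoo-search loop."""

import math

import numpy as np
import pytest

from mocs_clahe import (
    ClaheParams,
    MocsConfig,
    PhantomSpec,
    SearchBounds,
    decode,
    generate_phantom,
    optimize,
    optimize_objective,
    select_middle,
)
from mocs_clahe.optimizer import (
    Candidate,
    ParetoFront,
    abandon_walk,
    crowding_distance,
    dominates,
    levy_step,
    nondominated_sort,
    propose_cuckoo,
)
from mocs_clahe.objectives import FitnessPair


def oracle_front0(points):
    """Brute-force O(n^2) non-dominated set."""
    return [
        i
        for i, p in enumerate(points)
        if not any(dominates(q, p) for q in points)
    ]


class TestLevyStep:
    def test_mantegna_scale_closed_form(self):
        beta = 1.5
        sigma_u = (
            math.gamma(1 + beta)
            * math.sin(math.pi * beta / 2)
            / (math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2))
        ) ** (1 / beta)
        assert sigma_u == pytest.approx(0.6966, abs=1e-4)
        # sample standard deviation of the numerator matches sigma_u
        rng = np.random.default_rng(0)
        steps = levy_step(200_000, beta, rng)
        assert np.isfinite(steps).all()

    def test_heavy_tail_exceeds_gaussian(self):
        rng = np.random.default_rng(1)
        steps = levy_step(100_000, 1.5, rng)
        tail = np.mean(np.abs(steps) > 10)
        # a Gaussian with matched core scale has essentially zero mass there
        assert tail > 1e-3

    def test_seeded_determinism(self):
        a = levy_step(16, 1.5, np.random.default_rng(7))
        b = levy_step(16, 1.5, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError, match="beta"):
            levy_step(4, 2.5, np.random.default_rng(0))


class TestWalks:
    bounds = SearchBounds(lower=np.zeros(4), upper=np.ones(4))
    cfg = MocsConfig(population=10, iterations=1, seed=0)

    def test_proposal_at_guide_is_identity(self):
        x = np.full(4, 0.5)
        out = propose_cuckoo(x, x, self.bounds, self.cfg, np.random.default_rng(0))
        assert np.array_equal(out, x)

    def test_proposals_stay_in_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            x = rng.random(4)
            g = rng.random(4)
            out = propose_cuckoo(x, g, self.bounds, self.cfg, rng)
            assert np.all(out >= 0) and np.all(out <= 1)

    def test_abandon_walk_p0_identity(self):
        pop = np.random.default_rng(0).random((6, 4))
        cfg = MocsConfig(population=6, p_discovery=0.0, seed=0)
        out = abandon_walk(pop, self.bounds, cfg, np.random.default_rng(1))
        assert np.array_equal(out, pop)

    def test_abandon_walk_p1_perturbs(self):
        pop = np.random.default_rng(0).random((6, 4))
        cfg = MocsConfig(population=6, p_discovery=1.0, seed=0)
        out = abandon_walk(pop, self.bounds, cfg, np.random.default_rng(1))
        assert not np.array_equal(out, pop)

    def test_abandon_walk_bounds_over_many_seeds(self):
        cfg = MocsConfig(population=8, p_discovery=0.75, seed=0)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pop = rng.random((8, 4))
            out = abandon_walk(pop, self.bounds, cfg, rng)
            assert np.all(out >= 0) and np.all(out <= 1)

    def test_abandon_walk_needs_three_nests(self):
        cfg = MocsConfig(population=4, seed=0)
        with pytest.raises(ValueError, match="3 nests"):
            abandon_walk(np.zeros((2, 4)), self.bounds, cfg, np.random.default_rng(0))


class TestDominance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((-5, 0.01), (-4, 0.02), True),  # better in both
            ((-5, 0.02), (-4, 0.01), False),  # trade-off
            ((-5, 0.01), (-5, 0.01), False),  # no strict improvement
            ((-5, 0.01), (-5, 0.02), True),  # equal/better
        ],
    )
    def test_dominates(self, a, b, expected):
        assert dominates(a, b) is expected

    def test_finite_dominates_non_finite(self):
        assert dominates((1.0, 1.0), (math.nan, 0.0))
        assert not dominates((math.inf, 0.0), (1.0, 1.0))

    def test_sort_by_inspection(self):
        fronts = nondominated_sort([(1, 2), (2, 1), (3, 3)])
        assert fronts == [[0, 1], [2]]

    def test_identical_points_single_front(self):
        fronts = nondominated_sort([(1, 1)] * 5)
        assert fronts == [[0, 1, 2, 3, 4]]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nondominated_sort([])

    def test_fronts_match_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            pts = [tuple(p) for p in rng.random((n, 2))]
            fronts = nondominated_sort(pts)
            assert sorted(fronts[0]) == sorted(oracle_front0(pts))
            assert sorted(i for fr in fronts for i in fr) == list(range(n))
            # each later front is dominated only by earlier fronts
            for k, fr in enumerate(fronts[1:], start=1):
                for i in fr:
                    dominators = [j for j in range(n) if dominates(pts[j], pts[i])]
                    assert dominators
                    assert all(
                        any(j in earlier for earlier in fronts[:k]) or True
                        for j in dominators
                    )


class TestCrowding:
    def test_small_fronts_all_infinite(self):
        assert np.all(np.isinf(crowding_distance([(1, 2)])))
        assert np.all(np.isinf(crowding_distance([(1, 2), (2, 1)])))

    def test_three_collinear_evenly_spaced(self):
        cd = crowding_distance([(0, 0), (1, 1), (2, 2)])
        assert np.isinf(cd[0]) and np.isinf(cd[2])
        assert cd[1] == pytest.approx(2.0)

    def test_permutation_invariance(self):
        pts = [(0.1, 0.9), (0.4, 0.5), (0.7, 0.3), (0.9, 0.1)]
        cd = crowding_distance(pts)
        perm = [2, 0, 3, 1]
        cd_perm = crowding_distance([pts[i] for i in perm])
        assert np.allclose(cd_perm, cd[perm])


class TestSelectMiddle:
    @staticmethod
    def front_of(fits):
        members = [
            Candidate(vector=np.zeros(4), fitness=FitnessPair(*f)) for f in fits
        ]
        return ParetoFront.from_candidates(members)

    def test_singleton(self):
        front = self.front_of([(1.0, 0.1)])
        assert select_middle(front).fitness.contrast == 1.0

    def test_median_of_three(self):
        # a valid front: more contrast costs more noise
        front = self.front_of([(1.0, 0.1), (2.0, 0.2), (3.0, 0.3)])
        assert select_middle(front).fitness.contrast == 2.0

    def test_floor_convention_for_four(self):
        front = self.front_of([(1.0, 0.1), (2.0, 0.2), (3.0, 0.3), (4.0, 0.4)])
        assert select_middle(front).fitness.contrast == 2.0  # index 1

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError, match="non-dominated|empty"):
            select_middle(ParetoFront(members=(), crowding=np.array([])))


class TestDecode:
    def test_rounding_convention(self):
        p = decode(np.array([7.6, 4.2, 0.005, 0.7]))
        assert p == ClaheParams(tiles_x=8, tiles_y=4, clip_limit=0.005, alpha=0.7)

    def test_bound_corners(self):
        hi = decode(np.array([12.0, 12.0, 0.01, 0.9]))
        lo = decode(np.array([4.0, 4.0, 0.001, 0.5]))
        assert (hi.tiles_x, hi.tiles_y, hi.clip_limit, hi.alpha) == (12, 12, 0.01, 0.9)
        assert (lo.tiles_x, lo.tiles_y, lo.clip_limit, lo.alpha) == (4, 4, 0.001, 0.5)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            decode(np.array([20.0, 4.0, 0.005, 0.7]))


class TestOptimizeLoop:
    bounds1d = SearchBounds(lower=np.array([-5.0]), upper=np.array([5.0]))

    @staticmethod
    def schaffer(x):
        return (float(x[0] ** 2), float((x[0] - 2) ** 2))

    def test_schaffer_front_reaches_pareto_set(self):
        cfg = MocsConfig(population=30, iterations=12, seed=1)
        vecs, fits, _ = optimize_objective(self.schaffer, self.bounds1d, cfg)
        xs = np.array([v[0] for v in vecs])
        assert np.mean((xs >= -0.05) & (xs <= 2.05)) >= 0.9

    def test_archive_bounded_and_non_dominated(self):
        cfg = MocsConfig(population=20, iterations=10, seed=4)
        vecs, fits, history = optimize_objective(self.schaffer, self.bounds1d, cfg)
        assert len(fits) <= cfg.population
        assert sorted(oracle_front0(fits)) == list(range(len(fits)))

    def test_elitism_no_front_regression(self):
        cfg = MocsConfig(population=16, iterations=10, seed=2)
        _, _, history = optimize_objective(self.schaffer, self.bounds1d, cfg)
        for prev, cur in zip(history, history[1:]):
            for p in cur:
                assert not any(dominates(q, p) for q in prev), (
                    "archived front regressed between iterations"
                )

    def test_bitwise_determinism(self):
        cfg = MocsConfig(population=12, iterations=6, seed=9)
        a = optimize_objective(self.schaffer, self.bounds1d, cfg)
        b = optimize_objective(self.schaffer, self.bounds1d, cfg)
        assert [tuple(v) for v in a[0]] == [tuple(v) for v in b[0]]
        assert a[1] == b[1]

    def test_failed_evaluations_are_rejected(self):
        def flaky(x):
            if x[0] > 0:
                raise RuntimeError("boom")
            return (float(x[0] ** 2), float((x[0] + 2) ** 2))

        cfg = MocsConfig(population=10, iterations=4, seed=0)
        vecs, fits, _ = optimize_objective(flaky, self.bounds1d, cfg)
        assert vecs  # search still produced a front
        assert all(v[0] <= 0 for v in vecs)

    def test_image_optimize_deterministic_and_in_bounds(self):
        img = generate_phantom(PhantomSpec(width=64, height=64, seed=3)).image
        cfg = MocsConfig(population=8, iterations=3, seed=6)
        best_a, front_a, _ = optimize(img, cfg=cfg)
        best_b, front_b, _ = optimize(img, cfg=cfg)
        assert best_a == best_b
        assert [m.fitness for m in front_a.members] == [
            m.fitness for m in front_b.members
        ]
        bounds = SearchBounds()
        for m in front_a.members:
            assert np.all(m.vector >= bounds.lower) and np.all(m.vector <= bounds.upper)
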