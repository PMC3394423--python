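import numpy as np
import pytest

from frogbic import (
    EpsArchive,
    Memeplex,
    SFLConfig,
    generate_synthetic,
    run,
)
from frogbic.engine import (
    FrogIndividual,
    _masked_fitness,
    evaluate_frog,
    grow_population,
    improve_worst_frog,
    initialize_population,
    partition_memeplexes,
    position_update,
    repair_position,
    shrink_population,
    velocity_update,
)
from frogbic.errors import ParameterError, ValidationError
from frogbic.pareto import dominates


@pytest.fixture
def matrix():
    m, _ = generate_synthetic(40, 10, ("normal", 0.0, 1.0), [], seed=3)
    return m


def small_cfg(**kw):
    defaults = dict(delta=1.0, n_generations=4, ga_individuals=20, ga_generations=3,
                    pop_min=12, pop_max=30, n_frogs=18, n_memeplexes=3,
                    cycles_per_memeplex=3, spawn_climb_trials=10, seed=1)
    defaults.update(kw)
    return SFLConfig(**defaults)


def make_frogs(matrix, cfg, rng, k):
    frogs = []
    for _ in range(k):
        pos = (rng.random(matrix.n + matrix.m) < 0.4).astype(np.uint8)
        frogs.append(evaluate_frog(FrogIndividual(pos, np.zeros(matrix.n + matrix.m)),
                                   matrix, cfg, rng))
    return frogs


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(delta=0.0),
        dict(n_memeplexes=0),
        dict(n_frogs=3, n_memeplexes=6),
        dict(mutation_rate=1.5),
        dict(selection_ratio=-0.1),
        dict(pop_min=0),
        dict(crossover_type="triple"),
        dict(epsilon=(0.1, 0.1)),
        dict(step_acceptance="maybe"),
        dict(active_objectives=()),
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ParameterError):
            SFLConfig(**bad)

    def test_published_defaults(self):
        cfg = SFLConfig()
        assert (cfg.n_frogs, cfg.n_memeplexes, cfg.cycles_per_memeplex) == (60, 6, 10)
        assert (cfg.c1, cfg.c2, cfg.c3) == (2.0, 2.0, 2.0)
        assert (cfg.mu1, cfg.mu2) == (0.5, 0.5)
        assert (cfg.ga_individuals, cfg.ga_generations) == (50, 20)

    def test_omega_schedule_endpoints(self):
        cfg = SFLConfig(n_generations=11)
        assert cfg.omega(0) == pytest.approx(0.9)
        assert cfg.omega(10) == pytest.approx(0.4)
        assert cfg.omega(5) == pytest.approx(0.65)


class TestInitialization:
    def test_population_size_and_validity(self, matrix):
        cfg = small_cfg()
        rng = np.random.default_rng(0)
        pop = initialize_population(matrix, cfg, rng)
        assert len(pop) == cfg.ga_individuals
        for frog in pop:
            assert frog.position[: matrix.n].any()
            assert frog.position[matrix.n:].any()
            assert frog.objectives is not None

    def test_deterministic(self, matrix):
        cfg = small_cfg()
        a = initialize_population(matrix, cfg, np.random.default_rng(5))
        b = initialize_population(matrix, cfg, np.random.default_rng(5))
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.position, fb.position)

    def test_zero_ga_generations_is_random_init(self, matrix):
        cfg = small_cfg(ga_generations=0)
        pop = initialize_population(matrix, cfg, np.random.default_rng(2))
        assert len(pop) == cfg.ga_individuals


class TestPartition:
    def test_round_robin_sizes(self, matrix):
        cfg = small_cfg()
        frogs = make_frogs(matrix, cfg, np.random.default_rng(1), 12)
        plexes = partition_memeplexes(frogs, 3)
        assert [len(p.frogs) for p in plexes] == [4, 4, 4]

    def test_sixty_frogs_six_memeplexes(self, matrix):
        cfg = small_cfg()
        frogs = make_frogs(matrix, cfg, np.random.default_rng(2), 60)
        plexes = partition_memeplexes(frogs, 6)
        assert [len(p.frogs) for p in plexes] == [10] * 6

    def test_single_memeplex_keeps_global_ranking_head(self, matrix):
        cfg = small_cfg()
        frogs = make_frogs(matrix, cfg, np.random.default_rng(3), 9)
        plex = partition_memeplexes(frogs, 1)[0]
        # the dealt head is globally non-dominated
        head = plex.best
        assert not any(dominates(f.objectives, head.objectives) for f in frogs)

    def test_too_few_frogs_rejected(self, matrix):
        cfg = small_cfg()
        frogs = make_frogs(matrix, cfg, np.random.default_rng(4), 2)
        with pytest.raises(ValidationError):
            partition_memeplexes(frogs, 3)


class TestVelocityPosition:
    def test_no_pull_means_zero_velocity(self):
        cfg = SFLConfig()
        x = np.array([1, 0, 1, 0], dtype=np.uint8)
        frog = FrogIndividual(x.copy(), np.zeros(4))
        v = velocity_update(frog, x, x, x, cfg, omega=1.0,
                            rng=np.random.default_rng(0))
        np.testing.assert_allclose(v, 0.0)

    def test_unit_pull_bounds(self):
        # x=0, all guides 1: v' = ξ(c1 r1 + k μ1 c2 r2 + μ2 c3 r3) ∈ ξ·(−1, 4]
        cfg = SFLConfig(xi=1.0, v_max=10.0)
        rng = np.random.default_rng(0)
        x = np.zeros(1, dtype=np.uint8)
        ones = np.ones(1, dtype=np.uint8)
        draws = [velocity_update(FrogIndividual(x.copy(), np.zeros(1)),
                                 ones, ones, ones, cfg, 1.0, rng)[0]
                 for _ in range(300)]
        assert max(draws) <= 4.0 and min(draws) >= -1.0

    def test_clamped_to_v_max(self):
        cfg = SFLConfig(v_max=0.5)
        x = np.zeros(6, dtype=np.uint8)
        ones = np.ones(6, dtype=np.uint8)
        v = velocity_update(FrogIndividual(x.copy(), np.full(6, 100.0)),
                            ones, ones, ones, cfg, 1.0, np.random.default_rng(1))
        assert (np.abs(v) <= 0.5).all()

    def test_length_mismatch_rejected(self):
        cfg = SFLConfig()
        frog = FrogIndividual(np.zeros(4, dtype=np.uint8), np.zeros(4))
        with pytest.raises(ValidationError):
            velocity_update(frog, np.zeros(3, dtype=np.uint8),
                            np.zeros(4, dtype=np.uint8), np.zeros(4, dtype=np.uint8),
                            cfg, 1.0, np.random.default_rng(0))

    @pytest.mark.parametrize("x,v,expected", [
        (0, 0.0, 1),     # boundary is inclusive
        (0, -0.1, 0),
        (1, 0.3, 1),
        (1, -1.5, 0),
    ])
    def test_position_threshold(self, x, v, expected):
        out = position_update(np.array([x], dtype=np.uint8), np.array([v]))
        assert out[0] == expected

    def test_position_length_mismatch(self):
        with pytest.raises(ValidationError):
            position_update(np.zeros(3, dtype=np.uint8), np.zeros(4))


class TestImproveWorst:
    def test_worst_never_worsens_without_random_step(self, matrix):
        cfg = small_cfg(use_random_step=False, use_mutation_step=False,
                        use_crossover_step=False, step_acceptance="dominates")
        rng = np.random.default_rng(7)
        frogs = make_frogs(matrix, cfg, rng, 6)
        plex = Memeplex(frogs)
        for _ in range(10):
            worst_before = sorted(f.objectives.tolist() for f in plex.frogs)
            improve_worst_frog(plex, plex.best.position, matrix, cfg, 0.7, rng)
            for frog in plex.frogs:
                assert frog.position[: matrix.n].any()
                assert frog.position[matrix.n:].any()
            # with only the dominance-gated move enabled, no frog is replaced
            # by anything its old position dominated
            assert len(plex.frogs) == 6

    def test_random_step_replaces_on_total_failure(self, matrix):
        # all acceptance paths disabled except the unconditional random step
        cfg = small_cfg(use_mutation_step=False, use_crossover_step=False,
                        step_acceptance="dominates")
        rng = np.random.default_rng(8)
        frogs = make_frogs(matrix, cfg, rng, 5)
        plex = Memeplex(frogs)
        before = {f.position.tobytes() for f in plex.frogs}
        changed = False
        for _ in range(12):
            improve_worst_frog(plex, plex.best.position, matrix, cfg, 0.7, rng)
            after = {f.position.tobytes() for f in plex.frogs}
            if after != before:
                changed = True
        assert changed

    def test_repair_guarantees_validity(self, matrix):
        rng = np.random.default_rng(9)
        pos = np.zeros(matrix.n + matrix.m, dtype=np.uint8)
        repaired = repair_position(pos, matrix.n, matrix.m, rng)
        assert repaired[: matrix.n].sum() == 1 and repaired[matrix.n:].sum() == 1


class TestDynamicPopulation:
    def _archive(self, matrix, cfg, rng, k=10):
        archive = EpsArchive(cfg.epsilon)
        for frog in make_frogs(matrix, cfg, rng, k):
            archive.add(frog.objectives, payload={"position": frog.position.copy()})
        return archive

    def test_grow_noop_at_pop_max(self, matrix):
        cfg = small_cfg()
        rng = np.random.default_rng(10)
        frogs = make_frogs(matrix, cfg, rng, cfg.pop_max)
        assert grow_population(frogs, self._archive(matrix, cfg, rng), matrix, cfg, rng) is frogs

    def test_grow_with_empty_archive_spawns_random(self, matrix):
        cfg = small_cfg()
        rng = np.random.default_rng(11)
        frogs = make_frogs(matrix, cfg, rng, cfg.pop_max - 5)
        out = grow_population(frogs, EpsArchive(cfg.epsilon), matrix, cfg, rng)
        assert len(out) == cfg.pop_max
        for frog in out:
            assert frog.objectives is not None

    def test_grow_never_exceeds_pop_max(self, matrix):
        cfg = small_cfg()
        rng = np.random.default_rng(12)
        frogs = make_frogs(matrix, cfg, rng, 5)
        out = grow_population(frogs, self._archive(matrix, cfg, rng), matrix, cfg, rng)
        assert len(out) == cfg.pop_max

    def test_shrink_noop_at_pop_min(self, matrix):
        cfg = small_cfg()
        rng = np.random.default_rng(13)
        frogs = make_frogs(matrix, cfg, rng, cfg.pop_min)
        out = shrink_population(frogs, self._archive(matrix, cfg, rng), cfg, rng)
        assert len(out) == cfg.pop_min

    def test_shrink_noop_with_zero_ratio(self, matrix):
        cfg = small_cfg(selection_ratio=0.0)
        rng = np.random.default_rng(14)
        frogs = make_frogs(matrix, cfg, rng, 25)
        assert len(shrink_population(frogs, self._archive(matrix, cfg, rng), cfg, rng)) == 25

    def test_shrink_expected_removals_binomial(self, matrix):
        """~half of the selection_ratio candidates go, on average."""
        cfg = small_cfg(selection_ratio=0.2, pop_min=5, pop_max=200)
        rng = np.random.default_rng(15)
        frogs = make_frogs(matrix, cfg, rng, 50)
        archive = self._archive(matrix, cfg, rng)
        removed = [50 - len(shrink_population(frogs, archive, cfg, rng))
                   for _ in range(300)]
        # candidates = floor(0.2·50) = 10, each dropped w.p. 0.5 → mean 5
        sem = np.sqrt(10 * 0.25 / 300)
        assert abs(np.mean(removed) - 5.0) < 4 * sem + 0.05


class TestRun:
    def test_zero_generations_is_filtered_initial_population(self, matrix):
        cfg = small_cfg(n_generations=0)
        result = run(matrix, cfg)
        rng = np.random.default_rng(cfg.seed)
        expected = EpsArchive(cfg.epsilon)
        for frog in initialize_population(matrix, cfg, rng):
            expected.add(frog.objectives)
        got = sorted(map(tuple, result.archive.objectives_array().tolist()))
        want = sorted(map(tuple, expected.objectives_array().tolist()))
        assert got == want

    def test_bit_identical_under_seed(self, matrix):
        cfg = small_cfg(n_generations=3)
        a, b = run(matrix, cfg), run(matrix, cfg)
        np.testing.assert_array_equal(a.archive.objectives_array(),
                                      b.archive.objectives_array())
        for ma, mb in zip(a.archive.members, b.archive.members):
            np.testing.assert_array_equal(ma.payload["position"], mb.payload["position"])
        assert a.log.equals(b.log)

    def test_population_bounds_and_archive_validity(self, matrix):
        cfg = small_cfg(n_generations=5)
        result = run(matrix, cfg)
        assert result.log["population"].between(cfg.pop_min, cfg.pop_max).all()
        for member in result.archive.members:
            pos = member.payload["position"]
            assert pos[: matrix.n].any() and pos[matrix.n:].any()
            np.testing.assert_allclose(member.objectives,
                                       _masked_fitness(matrix, pos, cfg))

    def test_single_objective_reduction_is_monotone(self, matrix):
        """Canonical discrete SFL: with mutation/crossover/random replacement
        and population dynamics off and only the size objective active, the
        population's best objective never increases across shuffles."""
        cfg = small_cfg(n_generations=12, use_mutation_step=False,
                        use_crossover_step=False, use_random_step=False,
                        dynamic_population=False, active_objectives=(0,),
                        step_acceptance="dominates")
        result = run(matrix, cfg)
        best = result.log["best_f1"].to_numpy()
        assert (np.diff(best) <= 1e-12).all()
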