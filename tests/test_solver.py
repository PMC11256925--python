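import numpy as np
import pytest

from crossbic import Params, SearchConfig, beam_search, exhaustive_search, iterative_runs
from crossbic.objective import ObjectiveEngine
from crossbic.preprocess import cpm_normalize, filter_genes, log_transform
from crossbic.synthetic import SimulationConfig, f1_score, generate_mixture, plant_population
from _helpers import make_expression, planted_block_instance, random_instance


class TestExhaustiveSearch:
    def test_one_gene_two_cells(self):
        m, sm = make_expression([[2.0, -1.0]], ["A", "A"])
        b = exhaustive_search(m, sm, Params(kappa=1.0, mu=0.0))
        assert b.cells.tolist() == [0]
        assert b.genes.tolist() == [0]
        assert b.objective == pytest.approx(2.0)

    def test_all_negative_matrix_returns_empty(self):
        m, sm = make_expression(np.full((3, 5), -1.0), ["A"] * 3 + ["B"] * 2)
        b = exhaustive_search(m, sm, Params(kappa=1.0))
        assert b.is_empty and b.objective == 0.0

    def test_too_many_cells_rejected(self):
        m, sm = make_expression(np.ones((2, 20)), ["A"] * 20)
        with pytest.raises(ValueError, match="beam_search"):
            exhaustive_search(m, sm, Params(kappa=1.0))


class TestBeamSearch:
    def test_recovers_planted_block_optimum(self):
        m, sm, truth = planted_block_instance()
        params = Params(kappa=1.0, mu=0.1)
        ex = exhaustive_search(m, sm, params)
        bm = beam_search(m, sm, SearchConfig(params=params))
        assert bm.bicluster.objective == pytest.approx(ex.objective)
        assert bm.bicluster.cells.tolist() == sorted(truth["spread_cells"])

    def test_never_exceeds_exhaustive_optimum(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            m, sm, params = random_instance(rng)
            ex = exhaustive_search(m, sm, params)
            bm = beam_search(m, sm, SearchConfig(params=params))
            assert bm.bicluster.objective <= ex.objective + 1e-9

    def test_empty_pool_rejected(self):
        m, sm = make_expression(np.ones((2, 2)), ["A", "B"])
        with pytest.raises(ValueError, match="pool"):
            beam_search(m, sm, SearchConfig(excluded_cells=frozenset({0, 1})))

    def test_deterministic_bit_identical(self):
        cfg = SimulationConfig(n_cells=120, n_rare=8, n_genes=150, n_marker_genes=15, seed=5)
        ds = generate_mixture(cfg)
        m = filter_genes(log_transform(cpm_normalize(ds.counts)), 0.25)
        r1 = beam_search(m, ds.sample_map, SearchConfig())
        r2 = beam_search(m, ds.sample_map, SearchConfig())
        assert r1.bicluster.cells.tolist() == r2.bicluster.cells.tolist()
        assert r1.bicluster.objective == r2.bicluster.objective  # bitwise
        assert r1.trace == r2.trace

    def test_recovers_planted_rare_cells(self):
        cfg = SimulationConfig(n_cells=200, n_rare=10, n_genes=200, n_marker_genes=20, seed=7)
        ds = generate_mixture(cfg)
        m = filter_genes(log_transform(cpm_normalize(ds.counts)), 0.25)
        res = beam_search(m, ds.sample_map, SearchConfig())
        assert res.bicluster.cells.tolist() == ds.rare_cells.tolist()

    def test_work_linear_in_cells(self):
        """Candidate evaluations are bounded by width * samples * steps * |C|."""
        counts = {}
        for n_cells in (120, 240):
            cfg = SimulationConfig(
                n_cells=n_cells, n_rare=8, n_genes=150, n_marker_genes=15, seed=9
            )
            ds = generate_mixture(cfg)
            m = filter_genes(log_transform(cpm_normalize(ds.counts)), 0.25)
            sc = SearchConfig()
            engine = ObjectiveEngine(m, ds.sample_map, sc.params)
            engine.set_fixed_penalty([])
            res = beam_search(m, ds.sample_map, sc)
            steps = len(res.trace)
            # re-run through the public path while counting evaluations
            engine2 = ObjectiveEngine(m, ds.sample_map, sc.params)
            from crossbic.solver import _pool, _run_beam

            pool = _pool(m.n_cells, None, ())
            engine2.set_fixed_penalty([])
            seed_cells = {
                s: pool[ds.sample_map.codes[pool] == s_i]
                for s_i, s in enumerate(ds.sample_map.samples)
            }
            _run_beam(engine2, pool, sc, seed_cells)
            bound = sc.beam_width * ds.sample_map.n_samples * (steps + 1) * n_cells + n_cells
            counts[n_cells] = engine2.cells_scored
            assert engine2.cells_scored <= bound
        # doubling the cell count at fixed planted size scales work ~linearly
        assert counts[240] <= 3.5 * counts[120]


@pytest.fixture(scope="module")
def two_population_dataset():
    cfg = SimulationConfig(n_cells=400, n_rare=14, n_genes=300, n_marker_genes=30, seed=3)
    ds = generate_mixture(cfg)
    rng = np.random.default_rng(99)
    cells2 = np.sort(
        rng.choice(np.setdiff1d(np.arange(400), ds.rare_cells), 10, replace=False)
    )
    genes2 = np.sort(
        rng.choice(np.setdiff1d(np.arange(300), ds.marker_genes), 25, replace=False)
    )
    ds2 = plant_population(ds, cells2, genes2, rate=4.0, seed=100)
    m = filter_genes(log_transform(cpm_normalize(ds2.counts)), 0.25)
    return m, ds2, ds.rare_cells, cells2


class TestIterativeRuns:
    def test_two_runs_recover_both_disjoint_populations(self, two_population_dataset):
        m, ds2, truth1, truth2 = two_population_dataset
        runs = iterative_runs(m, ds2.sample_map, n_runs=2, config=SearchConfig())
        assert len(runs) == 2
        sets = [set(r.bicluster.cells.tolist()) for r in runs]
        assert not (sets[0] & sets[1])
        # the higher-objective population is found first
        assert runs[0].bicluster.objective > runs[1].bicluster.objective
        assert f1_score(sets[0], set(truth1))[2] == pytest.approx(1.0)
        assert f1_score(sets[1], set(truth2))[2] == pytest.approx(1.0)

    def test_later_run_after_exhausting_signal_scores_lower(self, two_population_dataset):
        m, ds2, _, _ = two_population_dataset
        runs = iterative_runs(m, ds2.sample_map, n_runs=3, config=SearchConfig())
        if len(runs) == 3:  # a noise cluster may terminate the loop instead
            assert runs[2].bicluster.objective < runs[1].bicluster.objective

    def test_single_run_equals_beam_search(self, two_population_dataset):
        m, ds2, _, _ = two_population_dataset
        solo = beam_search(m, ds2.sample_map, SearchConfig())
        runs = iterative_runs(m, ds2.sample_map, n_runs=1, config=SearchConfig())
        assert runs[0].bicluster.cells.tolist() == solo.bicluster.cells.tolist()
        assert runs[0].bicluster.objective == solo.bicluster.objective

    def test_excluded_cells_still_penalized(self):
        """Excluded cells keep weighing on the out-of-cluster penalty term."""
        # gene 0 expressed in cells 0-3; excluding 2,3 must keep their
        # positive expression in omega's penalty for J = {0, 1}
        m, sm = make_expression([[2.0, 2.0, 2.0, 2.0, -1.0, -1.0]], ["A"] * 3 + ["B"] * 3)
        params = Params(kappa=0.5)
        engine = ObjectiveEngine(m, sm, params)
        b = engine.select_genes([0, 1])
        # omega_A = 4 - 0.5*2, omega_B = -0.5*2; excluding cells 2,3 from the
        # pool must not change this exact evaluation
        assert b.gene_stats[0].omega_per_sample["A"] == pytest.approx(3.0)
        assert b.gene_stats[0].omega_per_sample["B"] == pytest.approx(-1.0)
        res = beam_search(
            m,
            sm,
            SearchConfig(params=params, excluded_cells=frozenset({2, 3})),
        )
        assert 2 not in res.bicluster.cells and 3 not in res.bicluster.cells
        for gs in res.bicluster.gene_stats:
            # penalty of the excluded expressing cells is charged
            assert gs.omega_per_sample["A"] < 4.0

    def test_exclude_genes_mode_yields_disjoint_gene_sets(self, two_population_dataset):
        m, ds2, _, _ = two_population_dataset
        runs = iterative_runs(
            m, ds2.sample_map, n_runs=2, config=SearchConfig(), exclude="genes"
        )
        g = [set(r.bicluster.genes.tolist()) for r in runs]
        assert len(runs) == 2 and not (g[0] & g[1])
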