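"""Genetic-algorithm search: fitness, recovery, convergence, mapping."""

import numpy as np
import pytest

from coformer_scout import (
    ConstraintSet,
    CoformerFeaturizer,
    CoformerLibrary,
    CoformerRecord,
    GAConfig,
    GeneratorConfig,
    detect_convergence,
    fitness,
    generate_candidate_pool,
    map_to_candidate,
    run_ga,
)


class TestFitness:
    def test_feasible_chromosome_scores_its_probability(self):
        cs = ConstraintSet(bounds={"mw": (100.0, 300.0)}, lam=1.0)
        assert fitness(0.73, {"mw": 200.0}, cs) == pytest.approx(0.73)

    def test_full_span_violation_costs_one(self):
        # mw exceeds the upper bound by the bound's whole span; lam = 1
        cs = ConstraintSet(bounds={"mw": (100.0, 300.0)}, lam=1.0)
        assert fitness(0.73, {"mw": 500.0}, cs) == pytest.approx(0.73 - 1.0)

    def test_lambda_zero_disables_constraints(self):
        rng = np.random.default_rng(0)
        cs = ConstraintSet(bounds={"mw": (100.0, 300.0)}, lam=0.0)
        for _ in range(100):
            p, mw = rng.uniform(), rng.uniform(0, 1000)
            assert fitness(p, {"mw": mw}, cs) == p

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(bounds={"mw": (300.0, 100.0)})


class _QuadraticModel:
    """Stub model: concave quadratic 'probability' with a known argmax."""

    def __init__(self, argmax):
        self.argmax = np.asarray(argmax, dtype=float)
        self.n_features_in_ = len(self.argmax)

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return 1.0 - 0.001 * np.sum((X - self.argmax) ** 2, axis=1)


def _identity_featurizer(features):
    fz = CoformerFeaturizer(features=features)
    fz.columns_ = tuple(features)
    fz.means_ = np.zeros(len(features))
    fz.sds_ = np.ones(len(features))
    return fz


@pytest.fixture(scope="module")
def screen(trained_screen):
    model, featurizer, *_ = trained_screen
    return model, featurizer


class TestRunGADiscrete:
    def test_elitism_preserves_an_early_optimum(self, screen):
        model, featurizer = screen
        pool = generate_candidate_pool(GeneratorConfig(seed=7), 5)
        probs = model.predict_proba(featurizer.transform(pool))
        best_id = pool[int(np.argmax(probs))].id
        cfg = GAConfig(population=50, crossover_rate=0.0, mutation_rate=0.0,
                       generations=20, seed=0)
        res = run_ga(model, featurizer, ConstraintSet(), cfg, pool=pool)
        assert res.best_record.id == best_id
        assert res.trace.best == pytest.approx([max(probs)] * len(res.trace.best))

    def test_best_fitness_monotone_under_elitism(self, screen):
        model, featurizer = screen
        pool = generate_candidate_pool(GeneratorConfig(seed=8), 300)
        for seed in range(5):
            res = run_ga(model, featurizer, ConstraintSet(),
                         GAConfig(generations=40, seed=seed), pool=pool)
            assert np.all(np.diff(res.trace.best) >= 0)

    def test_seed_determinism(self, screen):
        model, featurizer = screen
        pool = generate_candidate_pool(GeneratorConfig(seed=9), 200)
        a = run_ga(model, featurizer, ConstraintSet(), GAConfig(seed=4), pool=pool)
        b = run_ga(model, featurizer, ConstraintSet(), GAConfig(seed=4), pool=pool)
        assert a.best_record.id == b.best_record.id
        assert a.trace.best == b.trace.best and a.trace.mean == b.trace.mean

    def test_empty_pool_rejected(self, screen):
        model, featurizer = screen
        with pytest.raises(ValueError, match="empty"):
            run_ga(model, featurizer, ConstraintSet(), GAConfig(), pool=CoformerLibrary([]))

    def test_feasible_best_preferred_when_feasible_exists(self, screen):
        model, featurizer = screen
        pool = generate_candidate_pool(GeneratorConfig(seed=10), 300)
        constraints = ConstraintSet(bounds={"mw": (100.0, 260.0), "tyr_inhib": (0.5, 1.0)})
        res = run_ga(model, featurizer, constraints, GAConfig(seed=1), pool=pool)
        assert res.best_feasible
        assert 100.0 <= res.best_record.mw <= 260.0
        assert res.best_record.tyr_inhib >= 0.5


class TestRunGAContinuous:
    def test_recovers_known_quadratic_argmax(self):
        features = ("mw", "hbd", "tpsa", "tyr_inhib")
        argmax = np.array([150.0, 2.0, 60.0, 0.9])
        model = _QuadraticModel(argmax)
        fz = _identity_featurizer(features)
        bounds = {"mw": (75.0, 400.0), "hbd": (0.0, 6.0),
                  "tpsa": (0.0, 150.0), "tyr_inhib": (0.0, 1.0)}
        res = run_ga(model, fz, ConstraintSet(), GAConfig(seed=0), bounds=bounds)
        spans = np.array([325.0, 6.0, 150.0, 1.0])
        assert np.all(np.abs(res.best_vector - argmax) <= 0.05 * spans)

    def test_smiles_encoding_features_rejected(self, screen):
        model, featurizer = screen  # fitted with smiles_enc in the spec
        with pytest.raises(ValueError, match="scalar"):
            run_ga(model, featurizer, ConstraintSet(), GAConfig(),
                   bounds={"mw": (0, 1)})


class TestConvergence:
    def test_constant_trace_converges_at_zero(self):
        assert detect_convergence([1.0] * 30, window=10, tol=1e-4) == 0

    def test_steadily_improving_trace_never_converges(self):
        trace = list(np.arange(50) * 1.0)  # increments far above tol
        assert detect_convergence(trace, window=10, tol=1e-4) is None

    def test_plateau_from_generation_sixty(self):
        trace = [g * 0.01 for g in range(60)] + [0.60] * 40
        assert detect_convergence(trace, window=10, tol=1e-4) == 60

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_convergence([1.0, 1.0], window=10, tol=1e-4)


class TestMapToCandidate:
    def _pool(self):
        recs = [
            CoformerRecord(id="A", smiles="CO", mw=100.0, hbd=1, tpsa=30.0, tyr_inhib=0.2),
            CoformerRecord(id="B", smiles="CO", mw=200.0, hbd=3, tpsa=60.0, tyr_inhib=0.6),
            CoformerRecord(id="C", smiles="CO", mw=300.0, hbd=5, tpsa=90.0, tyr_inhib=1.0),
        ]
        return CoformerLibrary(recs)

    def test_exact_match_returns_that_record(self):
        fz = _identity_featurizer(("mw", "hbd", "tpsa", "tyr_inhib"))
        rec = map_to_candidate([200.0, 3.0, 60.0, 0.6], self._pool(), fz)
        assert rec.id == "B"

    def test_equidistant_tie_takes_smaller_id(self):
        fz = _identity_featurizer(("mw",))
        recs = [
            CoformerRecord(id="zz", smiles="CO", mw=100.0, hbd=0, tpsa=0.0, tyr_inhib=0.0),
            CoformerRecord(id="aa", smiles="CO", mw=200.0, hbd=0, tpsa=0.0, tyr_inhib=0.0),
        ]
        rec = map_to_candidate([150.0], CoformerLibrary(recs), fz)
        assert rec.id == "aa"

    def test_agrees_with_linear_scan(self):
        features = ("mw", "hbd", "tpsa", "tyr_inhib")
        pool = generate_candidate_pool(GeneratorConfig(seed=13), 100)
        fz = CoformerFeaturizer(features=features).fit(pool)
        raw = np.array([[getattr(r, f) for f in features] for r in pool])
        Z = fz.transform_raw(raw)
        rng = np.random.default_rng(0)
        for _ in range(500):
            q = np.array([rng.uniform(75, 400), rng.uniform(0, 6),
                          rng.uniform(0, 150), rng.uniform(0, 1)])
            zq = fz.transform_raw(q.reshape(1, -1))[0]
            expected = pool[int(np.argmin(np.linalg.norm(Z - zq, axis=1)))].id
            assert map_to_candidate(q, pool, fz).id == expected

    def test_empty_pool_rejected(self):
        fz = _identity_featurizer(("mw",))
        with pytest.raises(ValueError, match="empty"):
            map_to_candidate([1.0], CoformerLibrary([]), fz)
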