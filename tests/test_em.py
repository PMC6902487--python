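"""EM engine: initialization, M/E steps, full fits."""

import numpy as np
import pytest

from cytogate import (
    EMConfig,
    EventTable,
    MixtureModel,
    ResponsibilityMatrix,
    e_step,
    init_responsibilities,
    m_step,
    run_em,
)
from cytogate.synthetic import SyntheticComponent, SyntheticSpec, generate


def three_cluster_events(n=3000, seed=7):
    spec = SyntheticSpec(
        components=[
            SyntheticComponent(0.5, [10000, 10000], [[1e6, 0], [0, 1e6]]),
            SyntheticComponent(0.3, [40000, 15000], [[2e6, 5e5], [5e5, 1e6]]),
            SyntheticComponent(0.2, [25000, 50000], [[1.5e6, -3e5], [-3e5, 2e6]]),
        ],
        n_events=n,
        seed=seed,
    )
    return generate(spec)[0], spec


class TestInitResponsibilities:
    def test_single_component_is_all_ones(self, rng):
        r = init_responsibilities(37, 1, alpha=1.0, rng=rng)
        assert np.array_equal(r.values, np.ones((37, 1)))

    def test_rows_on_simplex(self, rng):
        r = init_responsibilities(1000, 5, alpha=1.0, rng=rng)
        assert np.allclose(r.values.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(r.values >= 0)

    def test_symmetric_dirichlet_column_means(self):
        """Law of large numbers: each column mean is ~1/c within 3 SE.
        Var of one Dirichlet(1,..,1) coordinate with c=4 is 3/80."""
        rng = np.random.default_rng(99)
        n, c = 100_000, 4
        r = init_responsibilities(n, c, alpha=1.0, rng=rng)
        se = np.sqrt(3.0 / 80.0 / n)
        assert np.all(np.abs(r.values.mean(axis=0) - 0.25) <= 3 * se)

    def test_reproducible_under_seed(self):
        a = init_responsibilities(50, 3, 1.0, np.random.default_rng(5))
        b = init_responsibilities(50, 3, 1.0, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_invalid_shapes(self, rng):
        with pytest.raises(ValueError):
            init_responsibilities(0, 2, 1.0, rng)


class TestMStep:
    def test_one_hot_reduces_to_group_statistics(self):
        X = np.array([[0.0, 0], [2, 2], [10, 10], [14, 10]])
        ev = EventTable(X, ("a", "b"))
        R = ResponsibilityMatrix(np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]]))
        model = m_step(ev, R)
        assert np.allclose(model.weights, [0.5, 0.5])
        assert np.allclose(model.means, [[1, 1], [12, 10]])

    def test_single_component_is_sample_mle(self, rng):
        X = rng.normal(size=(50, 2)) * 100 + 500
        ev = EventTable(X, ("a", "b"))
        R = ResponsibilityMatrix(np.ones((50, 1)))
        model = m_step(ev, R)
        assert np.allclose(model.means[0], X.mean(axis=0))
        assert np.allclose(
            model.covariances[0], np.cov(X, rowvar=False, bias=True), rtol=1e-6
        )

    def test_matches_weighted_moment_loop(self, rng):
        """Naive per-component loop over weighted moments is the oracle."""
        X = rng.uniform(0, 1000, size=(20, 2))
        raw = rng.uniform(0.01, 1, size=(20, 3))
        R = raw / raw.sum(axis=1, keepdims=True)
        model = m_step(EventTable(X, ("a", "b")), ResponsibilityMatrix(R))
        for j in range(3):
            w = R[:, j]
            mean = (w[:, None] * X).sum(axis=0) / w.sum()
            cov = np.zeros((2, 2))
            for i in range(20):
                d = (X[i] - mean)[:, None]
                cov += w[i] * (d @ d.T)
            cov /= w.sum()
            assert model.weights[j] == pytest.approx(w.mean(), rel=1e-10)
            assert np.allclose(model.means[j], mean, rtol=1e-10)
            assert np.allclose(model.covariances[j], cov, rtol=1e-6)

    def test_dead_component_reborn_not_nan(self, rng):
        X = rng.uniform(0, 1000, size=(30, 2))
        R = np.zeros((30, 2))
        R[:, 0] = 1.0  # component 1 has zero mass
        model = m_step(EventTable(X, ("a", "b")), ResponsibilityMatrix(R), rng=rng)
        assert np.all(np.isfinite(model.means))
        assert np.all(np.isfinite(model.covariances))
        model.validate()


class TestEStep:
    def test_single_component_all_ones(self, five_events):
        model = MixtureModel(
            weights=[1.0], means=[[20000.0, 30000.0]], covariances=[[[1e6, 0], [0, 1e6]]]
        )
        resp, _ = e_step(five_events, model)
        assert np.array_equal(resp.values, np.ones((5, 1)))

    def test_event_at_mean_dominates(self, two_component_model):
        ev = EventTable(two_component_model.means[:1].copy(), ("FSC", "DAPI"))
        resp, _ = e_step(ev, two_component_model)
        assert resp.values[0, 0] > 0.999

    def test_naive_oracle(self, five_events, two_component_model):
        from test_core import brute_force_mvn_logdensity

        m = two_component_model
        resp, loglik = e_step(five_events, m)
        expected = np.zeros((5, 2))
        total = 0.0
        for i, x in enumerate(five_events.values):
            dens = [
                m.weights[j]
                * np.exp(brute_force_mvn_logdensity(x, m.means[j], m.covariances[j]))
                for j in range(2)
            ]
            expected[i] = np.array(dens) / sum(dens)
            total += np.log(sum(dens))
        assert np.allclose(resp.values, expected, rtol=1e-9)
        assert loglik == pytest.approx(total, rel=1e-10)

    def test_rows_sum_to_one(self, five_events, two_component_model):
        resp, _ = e_step(five_events, two_component_model)
        resp.validate()


class TestRunEM:
    def test_c1_converges_to_closed_form(self, rng):
        X = rng.normal(size=(200, 2)) * 50 + 1000
        ev = EventTable(X, ("a", "b"))
        fit = run_em(ev, 1, EMConfig(n_starts=1, seed=0))
        assert fit.model.iterations <= 2
        assert fit.model.converged
        assert np.allclose(fit.model.means[0], X.mean(axis=0))
        assert np.allclose(
            fit.model.covariances[0], np.cov(X, rowvar=False, bias=True), rtol=1e-6
        )

    def test_recovers_separated_components(self):
        ev, spec = three_cluster_events()
        fit = run_em(ev, 3, EMConfig(n_starts=5, seed=3))
        true_means = np.array([c.mean for c in spec.components])
        # greedy match each true mean to the closest recovered mean
        tol = 0.02 * 65536
        for tm in true_means:
            d = np.linalg.norm(fit.model.means - tm, axis=1)
            assert d.min() <= tol

    def test_trace_monotone_nondecreasing(self):
        ev, _ = three_cluster_events(n=1000)
        fit = run_em(ev, 3, EMConfig(n_starts=3, seed=11))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-6)
        assert fit.loglik_trace[-1] == fit.model.loglik

    def test_seed_determinism_bit_identical(self):
        ev, _ = three_cluster_events(n=800)
        cfg = EMConfig(n_starts=2, seed=21)
        a = run_em(ev, 3, cfg)
        b = run_em(ev, 3, cfg)
        assert np.array_equal(a.model.weights, b.model.weights)
        assert np.array_equal(a.model.means, b.model.means)
        assert np.array_equal(a.model.covariances, b.model.covariances)
        assert a.model.loglik == b.model.loglik
        assert a.start_index == b.start_index

    def test_multistart_never_worse_than_single(self):
        ev, _ = three_cluster_events(n=800)
        multi = run_em(ev, 3, EMConfig(n_starts=5, seed=4))
        # each single start with the same master seed is one of the candidates
        single_logliks = []
        for s in range(5):
            streams = np.random.SeedSequence(4).spawn(5)
            from cytogate.em import _em_once

            fit = _em_once(
                ev, 3, EMConfig(n_starts=1, seed=4), np.random.default_rng(streams[s]), None
            )
            single_logliks.append(fit.model.loglik)
        assert multi.model.loglik >= max(single_logliks) - 1e-9

    def test_prior_permutation_leaves_loglik_unchanged(self):
        ev, spec = three_cluster_events(n=600)
        base = MixtureModel(
            weights=[c.weight for c in spec.components],
            means=[c.mean for c in spec.components],
            covariances=[c.covariance for c in spec.components],
        )
        perm = MixtureModel(
            weights=base.weights[::-1].copy(),
            means=base.means[::-1].copy(),
            covariances=base.covariances[::-1].copy(),
        )
        cfg = EMConfig(seed=0)
        a = run_em(ev, 3, cfg, prior=base)
        b = run_em(ev, 3, cfg, prior=perm)
        assert a.model.loglik == pytest.approx(b.model.loglik, abs=1e-6)

    def test_agrees_with_reference_em_shared_start(self):
        """With identical initial parameters, final log-likelihood matches
        scikit-learn's EM within 1e-3 (500 events, c=3)."""
        from sklearn.mixture import GaussianMixture

        ev, _ = three_cluster_events(n=500, seed=42)
        rng = np.random.default_rng(0)
        resp = init_responsibilities(500, 3, 1.0, rng)
        model0 = m_step(ev, resp)
        ours = run_em(ev, 3, EMConfig(epsilon=1e-6, n_starts=1, seed=0), prior=model0)
        gm = GaussianMixture(
            n_components=3,
            covariance_type="full",
            weights_init=model0.weights,
            means_init=model0.means,
            precisions_init=np.array([np.linalg.inv(c) for c in model0.covariances]),
            tol=1e-10,
            reg_covar=0,
            max_iter=5000,
        )
        gm.fit(ev.values)
        ref = gm.score(ev.values) * ev.n_events
        assert ours.model.loglik == pytest.approx(ref, abs=1e-3)

    def test_too_few_events_rejected(self, rng):
        ev = EventTable(rng.uniform(size=(10, 2)), ("a", "b"))
        with pytest.raises(ValueError, match="at least"):
            run_em(ev, 3, EMConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EMConfig(epsilon=0)
        with pytest.raises(ValueError):
            EMConfig(alpha=-1)
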