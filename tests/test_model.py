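"""ICAR structure, likelihood, DIC, and the MCMC sampler's basic contracts."""

import numpy as np
import pandas as pd
import pytest
import sympy

import mnhcov as m
from mnhcov.bym import bernoulli_loglik, dic_from_draws


def path_graph(ids=("a", "b", "c")):
    adjacency = {
        ids[0]: frozenset({ids[1]}),
        ids[1]: frozenset({ids[0], ids[2]}),
        ids[2]: frozenset({ids[1]}),
    }
    return m.DistrictGraph(
        district_ids=tuple(ids),
        adjacency=adjacency,
        components=(frozenset(ids),),
    )


def sympy_loglik(y, eta, digits=60):
    """Arbitrary-precision oracle for sum y*eta - log(1 + exp(eta))."""
    total = sympy.Integer(0)
    for yi, ei in zip(y, eta):
        e = sympy.Float(ei, digits)
        total += yi * e - sympy.log(1 + sympy.exp(e))
    return float(total.evalf(digits))


class TestIcarPrecision:
    def test_path_graph_matrix(self):
        st = m.icar_precision(path_graph())
        expected = np.array([[1, -1, 0], [-1, 2, -1], [0, -1, 1]], dtype=float)
        assert np.array_equal(st.Q.toarray(), expected)

    def test_single_node_island(self):
        g = m.DistrictGraph(("solo",), {"solo": frozenset()}, (frozenset({"solo"}),))
        st = m.icar_precision(g)
        assert st.Q.toarray() == np.zeros((1, 1))
        assert st.islands == ("solo",)
        assert st.scaling[0] == 0.0

    def test_3x3_grid_rank_and_row_sums(self, structure33):
        Q = structure33.Q.toarray()
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        vals = np.linalg.eigvalsh(Q)
        assert vals.min() >= -1e-10  # positive semidefinite
        assert (vals > vals.max() * 1e-10).sum() == 8  # rank n - 1

    def test_scaled_marginal_variances_geometric_mean_one(self, structure33):
        s = structure33.scaling[0]
        gen_var = np.linalg.pinv(s * structure33.Q.toarray(), hermitian=True)
        marg = np.diag(gen_var)
        assert abs(np.exp(np.mean(np.log(marg))) - 1.0) < 1e-6


class TestLogLikelihood:
    def test_eta_zero_gives_n_log_two(self):
        y = np.array([0, 1, 1, 0, 1])
        X = np.zeros((5, 2))
        b = np.zeros(2)
        ll = m.log_likelihood(np.zeros(2), b, X, y, np.zeros(5, dtype=int))
        assert np.isclose(ll, -5 * np.log(2))

    def test_certain_success_limit(self):
        # y=1 with eta -> +inf approaches log-likelihood 0; stable at |eta|=700
        assert bernoulli_loglik(np.array([1]), np.array([700.0])) > -1e-300
        assert np.isfinite(bernoulli_loglik(np.array([0]), np.array([700.0])))
        assert bernoulli_loglik(np.array([1]), np.array([np.inf])) == 0.0

    def test_matches_arbitrary_precision_oracle(self):
        y = np.array([1, 0, 1])
        eta = np.array([0.3, -1.7, 2.4])
        ours = bernoulli_loglik(y, eta)
        assert np.isclose(ours, sympy_loglik(y, eta), rtol=1e-14, atol=1e-14)

    def test_rejects_non_binary_outcome(self):
        with pytest.raises(ValueError, match="binary"):
            m.log_likelihood(
                np.zeros(1), np.zeros(1), np.zeros((2, 1)), np.array([0, 2]),
                np.zeros(2, dtype=int),
            )


class TestDic:
    def test_identical_draws_pd_zero(self):
        X = np.array([[1.0, 0.5], [1.0, -0.2]])
        y = np.array([1, 0])
        dix = np.array([0, 0])
        beta = np.tile([0.3, -0.1], (4, 1))
        b = np.tile([0.2], (4, 1))
        dic, pd_ = dic_from_draws(beta, b, X, y, dix)
        assert abs(pd_) < 1e-12
        assert np.isclose(dic, -2 * m.log_likelihood(beta[0], b[0], X, y, dix))

    def test_two_draw_hand_set_matches_oracle(self):
        X = np.array([[1.0, 2.0], [1.0, -1.0]])
        y = np.array([1, 0])
        dix = np.array([0, 1])
        beta = np.array([[0.5, -0.3], [-0.2, 0.4]])
        b = np.array([[0.1, -0.6], [0.7, 0.2]])
        dic, pd_ = dic_from_draws(beta, b, X, y, dix)

        def dev(bet, bb):
            eta = [X[i] @ bet + bb[dix[i]] for i in range(2)]
            return -2 * sympy_loglik(y, eta)

        mean_dev = (dev(beta[0], b[0]) + dev(beta[1], b[1])) / 2
        dev_at_mean = dev(beta.mean(axis=0), b.mean(axis=0))
        assert np.isclose(pd_, mean_dev - dev_at_mean, atol=1e-12)
        assert np.isclose(dic, mean_dev + (mean_dev - dev_at_mean), atol=1e-12)

    def test_replicating_data_doubles_mean_deviance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2))
        y = np.array([0, 1, 1, 0, 1, 0])
        dix = np.array([0, 0, 1, 1, 0, 1])
        beta = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        dic1, pd1 = dic_from_draws(beta, b, X, y, dix)
        dic2, pd2 = dic_from_draws(
            beta, b, np.vstack([X, X]), np.tile(y, 2), np.tile(dix, 2)
        )
        assert np.isclose(dic2 - pd2, 2 * (dic1 - pd1))


class TestFit:
    def test_single_class_raises_separation_error(self, structure33, small_survey):
        data, _ = small_survey
        degenerate = data.copy()
        degenerate["sba"] = 1
        with pytest.raises(m.SeparationError, match="sba"):
            m.fit(m.ModelSpec("sba"), degenerate, structure33)

    def test_draw_shapes_and_supports(self, small_fit):
        assert small_fit.draws["beta"].shape == (2, 500, 6)
        assert small_fit.draws["b"].shape == (2, 500, 9)
        phi = small_fit.flat("phi")
        sigma = small_fit.flat("sigma_b")
        assert ((phi >= 0) & (phi <= 1)).all()
        assert (sigma >= 0).all()
        for arr in small_fit.draws.values():
            assert np.isfinite(arr).all()

    def test_summaries_are_deterministic_functions_of_draws(self, small_fit):
        beta0 = small_fit.flat("beta")[:, 0]
        row = small_fit.summaries.loc["beta[intercept]"]
        assert np.isclose(row["mean"], beta0.mean())
        assert np.isclose(row["q025"], np.quantile(beta0, 0.025))
        assert np.isclose(row["q975"], np.quantile(beta0, 0.975))

    def test_sum_to_zero_constraint_holds_in_draws(self, small_fit):
        u = small_fit.flat("u")
        assert np.abs(u.sum(axis=1)).max() < 1e-10

    def test_save_load_round_trip(self, small_fit, tmp_path):
        small_fit.save(tmp_path / "fit")
        back = m.PosteriorFit.load(tmp_path / "fit")
        assert np.allclose(back.flat("beta"), small_fit.flat("beta"))
        assert np.isclose(back.dic, small_fit.dic)
        assert back.district_ids == small_fit.district_ids

    def test_compute_dic_matches_fit(self, small_fit, small_survey):
        data, _ = small_survey
        dic, pd_ = m.compute_dic(small_fit, data)
        assert np.isclose(dic, small_fit.dic)
        assert np.isclose(pd_, small_fit.dic_pd)

    def test_label_invariance_of_posterior(self, grid33, small_survey):
        """Relabeling districts (and data) leaves posterior summaries unchanged."""
        data, _ = small_survey
        rename = {d: f"z{i:02d}" for i, d in enumerate(reversed(grid33.district_ids))}
        g2 = m.DistrictGraph(
            district_ids=tuple(sorted(rename[d] for d in grid33.district_ids)),
            adjacency={
                rename[d]: frozenset(rename[k] for k in nbrs)
                for d, nbrs in grid33.adjacency.items()
            },
            components=tuple(
                frozenset(rename[d] for d in comp) for comp in grid33.components
            ),
        )
        data2 = data.copy()
        data2["district_id"] = data2["district_id"].map(rename)
        mcmc = m.McmcSettings(chains=2, iters=800, warmup=300, seed=7)
        f1 = m.fit(m.ModelSpec("sba"), data, m.icar_precision(grid33), mcmc)
        f2 = m.fit(m.ModelSpec("sba"), data2, m.icar_precision(g2), mcmc)
        for name in f1.beta_names:
            a = f1.summaries.loc[f"beta[{name}]"]
            b = f2.summaries.loc[f"beta[{name}]"]
            # same posterior up to Monte Carlo error
            tol = 4 * max(a["sd"], b["sd"]) / np.sqrt(50)
            assert abs(a["mean"] - b["mean"]) < max(tol, 0.08), name
        s1 = f1.summaries.loc["sigma_b", "mean"]
        s2 = f2.summaries.loc["sigma_b", "mean"]
        assert abs(s1 - s2) < 0.15
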