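"""District prevalence summaries and absolute change between surveys."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import mnhcov as m


def toy_fit(beta_draws, b_draws, district_ids, outcome="sba"):
    """Hand-built posterior: beta_draws (M, 6), b_draws (M, J)."""
    beta_draws = np.asarray(beta_draws, dtype=float)
    b_draws = np.asarray(b_draws, dtype=float)
    M, J = b_draws.shape
    zeros = np.zeros((1, M, J))
    return m.PosteriorFit(
        outcome=outcome,
        district_ids=tuple(district_ids),
        beta_names=["intercept", "urban", "education", "wealth", "age_std", "parity_std"],
        draws={
            "beta": beta_draws[None, :, :],
            "b": b_draws[None, :, :],
            "u": zeros.copy(),
            "v": zeros.copy(),
            "sigma_b": np.zeros((1, M)),
            "phi": np.full((1, M), 0.5),
        },
        summaries=pd.DataFrame(),
        diagnostics=pd.DataFrame(),
        dic=np.nan,
        dic_pd=np.nan,
        seed=0,
    )


def woman(district, urban=False, education="none", wealth=1, age=30.0, parity=2, sba=0):
    return {
        "district_id": district,
        "urban": urban,
        "education": education,
        "wealth_quintile": wealth,
        "maternal_age": age,
        "parity": parity,
        "sba": sba,
    }


class TestDistrictPrevalence:
    def test_single_woman_draw_constant_half(self):
        data = pd.DataFrame([woman("d1")])
        fit = toy_fit(np.zeros((3, 6)), np.zeros((3, 1)), ["d1"])
        est = m.district_prevalence(fit, data)
        row = est.table.loc["d1"]
        assert row["mean"] == 0.5 and row["sd"] == 0.0 and not row["extrapolated"]

    def test_two_women_average_of_predicted_probabilities(self):
        # urban effect separates the two women at p=0.2 and p=0.6
        beta = np.zeros(6)
        beta[0] = logit(0.2)
        beta[1] = logit(0.6) - logit(0.2)
        data = pd.DataFrame([woman("d1", urban=False), woman("d1", urban=True)])
        fit = toy_fit(np.tile(beta, (2, 1)), np.zeros((2, 1)), ["d1"])
        est = m.district_prevalence(fit, data)
        assert np.isclose(est.table.loc["d1", "mean"], 0.4)

    def test_three_draws_two_districts_matches_enumeration(self):
        rng = np.random.default_rng(5)
        beta_draws = rng.normal(scale=0.5, size=(3, 6))
        b_draws = rng.normal(scale=0.5, size=(3, 2))
        data = pd.DataFrame(
            [
                woman("a", urban=True, wealth=3, age=20, parity=1),
                woman("a", education="primary", wealth=5, age=40, parity=4),
                woman("b", urban=True, education="secondary+", age=25, parity=2),
            ]
        )
        fit = toy_fit(beta_draws, b_draws, ["a", "b"])
        est = m.district_prevalence(fit, data)
        X, _ = m.build_design(data)
        jdx = {"a": 0, "b": 1}
        expected = np.empty((3, 2))
        for d in range(3):  # brute-force enumeration over draws and women
            p = [expit(X[i] @ beta_draws[d] + b_draws[d, jdx[row]])
                 for i, row in enumerate(data["district_id"])]
            expected[d, 0] = (p[0] + p[1]) / 2
            expected[d, 1] = p[2]
        assert np.allclose(est.draws, expected)
        assert np.allclose(est.table["mean"].to_numpy(), expected.mean(axis=0))
        assert np.allclose(
            est.table["q975"].to_numpy(), np.quantile(expected, 0.975, axis=0)
        )

    def test_unobserved_district_extrapolated_and_flagged(self):
        data = pd.DataFrame([woman("a"), woman("a", urban=True)])
        fit = toy_fit(np.zeros((4, 6)), np.zeros((4, 3)), ["a", "b", "c"])
        est = m.district_prevalence(fit, data)
        assert not est.table.loc["a", "extrapolated"]
        assert est.table.loc["b", "extrapolated"] and est.table.loc["c", "extrapolated"]
        assert est.table.loc["b", "n_obs"] == 0
        assert 0.0 < est.table.loc["b", "mean"] < 1.0

    def test_stochastic_ordering_in_beta(self):
        rng = np.random.default_rng(6)
        beta_draws = rng.normal(size=(5, 6))
        b_draws = rng.normal(size=(5, 2))
        data = pd.DataFrame([woman("a"), woman("b", urban=True, wealth=4)])
        lo = m.district_prevalence(toy_fit(beta_draws, b_draws, ["a", "b"]), data)
        shifted = beta_draws.copy()
        shifted[:, 0] += 0.7  # raise the intercept in every draw
        hi = m.district_prevalence(toy_fit(shifted, b_draws, ["a", "b"]), data)
        assert (hi.table["mean"] > lo.table["mean"]).all()

    def test_csv_export_columns(self, tmp_path):
        data = pd.DataFrame([woman("d1")])
        est = m.district_prevalence(toy_fit(np.zeros((2, 6)), np.zeros((2, 1)), ["d1"]), data)
        est.to_csv(tmp_path / "est.csv")
        back = pd.read_csv(tmp_path / "est.csv")
        assert {"district_id", "outcome", "year", "mean", "median", "sd",
                "q025", "q975", "n_obs", "extrapolated"} <= set(back.columns)


def estimate_set(means, outcome="sba", label="", draws=None):
    ids = [f"d{i}" for i in range(len(means))]
    means = np.asarray(means, dtype=float)
    spread = 0.05
    table = pd.DataFrame(
        {
            "mean": means,
            "median": means,
            "sd": spread,
            "q025": means - spread,
            "q975": means + spread,
            "n_obs": 10,
            "extrapolated": False,
        },
        index=pd.Index(ids, name="district_id"),
    )
    return m.DistrictEstimateSet(
        outcome=outcome, label=label, district_ids=tuple(ids), table=table,
        draws=draws if draws is not None else means[None, :],
    )


class TestAbsoluteChange:
    def test_simple_difference(self):
        first = estimate_set([0.40], label="2000")
        last = estimate_set([0.60], label="2011")
        change = m.absolute_change(first, last)
        assert np.isclose(change.table.loc["d0", "change"], 0.20)

    def test_identical_sets_give_zero_and_antisymmetry(self):
        a = estimate_set([0.3, 0.5, 0.7])
        assert (m.absolute_change(a, a).table["change"] == 0.0).all()
        b = estimate_set([0.5, 0.2, 0.9])
        ab = m.absolute_change(a, b).table["change"]
        ba = m.absolute_change(b, a).table["change"]
        assert np.allclose(ab, -ba)

    def test_large_decline(self):
        change = m.absolute_change(estimate_set([0.80]), estimate_set([0.25]))
        assert np.isclose(change.table.loc["d0", "change"], -0.55)

    def test_mismatched_districts_error_lists_difference(self):
        a = estimate_set([0.3, 0.5])
        b = estimate_set([0.3, 0.5, 0.7])
        with pytest.raises(ValueError, match="d2"):
            m.absolute_change(a, b)

    def test_overlap_flag(self):
        first = estimate_set([0.40, 0.40])
        last = estimate_set([0.43, 0.90])  # first overlaps, second does not
        t = m.absolute_change(first, last).table
        assert bool(t.loc["d0", "uncertain"]) and not bool(t.loc["d1", "uncertain"])
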