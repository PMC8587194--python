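"""The simulated-likelihood machinery and its independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import carechoice as cc
from carechoice.mixed_logit import (
    EstimationData,
    ModelSpec,
    conditional_choice_prob,
    fit_conditional_logit,
    gh_loglik,
    make_draws,
    simulated_loglik,
)
from conftest import subset_patients


class TestConditionalChoiceProb:
    def test_single_alternative(self):
        assert conditional_choice_prob([2.3]) == pytest.approx([1.0])

    def test_closed_form(self):
        p = conditional_choice_prob([0.0, np.log(3.0)])
        assert p == pytest.approx([0.25, 0.75])

    @given(
        u=st.lists(st.floats(-30, 30), min_size=1, max_size=8),
        c=st.floats(-100, 100),
    )
    def test_location_invariance_and_normalization(self, u, c):
        p = conditional_choice_prob(u)
        q = conditional_choice_prob([x + c for x in u])
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(p, q, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            conditional_choice_prob([])


class TestDraws:
    def test_halton_is_seed_invariant_pseudo_is_not(self):
        a = make_draws(5, 3, 16, method="halton", seed=1)
        b = make_draws(5, 3, 16, method="halton", seed=2)
        assert np.array_equal(a.z, b.z)
        c = make_draws(5, 3, 16, method="pseudo", seed=1)
        d = make_draws(5, 3, 16, method="pseudo", seed=2)
        assert not np.array_equal(c.z, d.z)
        assert np.array_equal(
            c.z, make_draws(5, 3, 16, method="pseudo", seed=1).z
        )

    def test_halton_marginals_are_standard_normal(self):
        z = make_draws(50, 2, 200, method="halton").z
        flat = z.reshape(-1, 2)
        assert np.abs(flat.mean(axis=0)).max() < 0.02
        assert np.abs(flat.std(axis=0) - 1.0).max() < 0.02


def _tiny_dataset(n_patients=2, seed=0):
    """Hand-sized dataset with one random attribute (distance) and nothing else."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        n_alt = 2
        chosen = rng.integers(0, n_alt)
        for j in range(n_alt):
            rows.append(
                {
                    "patient_id": f"P{p}",
                    "chosen": int(j == chosen),
                    "distance": float(rng.uniform(0, 10)),
                }
            )
    return pd.DataFrame(rows)


TINY_SPEC = ModelSpec(random_attrs=("distance",), fixed_attrs=(), fe_key=None)


class TestLikelihoodOracles:
    def test_sigma_zero_equals_conditional_logit_any_drawset(self, small_long):
        data = EstimationData(subset_patients(small_long, 120), ModelSpec())
        cl = fit_conditional_logit(data)
        theta = np.concatenate(
            [cl.params.iloc[: data.n_rand], np.zeros(data.n_rand),
             cl.params.iloc[data.n_rand :]]
        )
        for method, R in (("halton", 8), ("pseudo", 32)):
            ds = make_draws(data.n_patients, data.n_rand, R, method=method, seed=4)
            assert simulated_loglik(theta, data, ds) == pytest.approx(
                cl.loglik, abs=1e-10
            )

    def test_gh_equals_conditional_logit_at_sigma_zero(self):
        data = EstimationData(_tiny_dataset(30), TINY_SPEC)
        cl = fit_conditional_logit(data)
        theta = np.array([float(cl.params.iloc[0]), 0.0])
        for nodes in (3, 16, 64):
            assert gh_loglik(theta, data, nodes) == pytest.approx(cl.loglik, abs=1e-10)

    def test_gh_refuses_more_than_two_random_attributes(self, small_data):
        with pytest.raises(ValueError):
            gh_loglik(np.zeros(small_data.n_params), small_data)

    def test_gh_node_convergence_ladder(self):
        data = EstimationData(_tiny_dataset(20), TINY_SPEC)
        theta = np.array([-0.3, 0.4])
        g16 = gh_loglik(theta, data, 16)
        g32 = gh_loglik(theta, data, 32)
        g64 = gh_loglik(theta, data, 64)
        sll = simulated_loglik(theta, data, make_draws(data.n_patients, 1, 200))
        assert abs(g64 - g32) <= abs(g32 - g16) + 1e-12
        assert abs(g64 - g32) < max(abs(sll - g64), 1e-8)

    def test_gh_matches_naive_monte_carlo(self):
        """Second independent oracle: brute-force Monte Carlo with 10^6
        pseudo-normal draws agrees with the quadrature within 3 SEs."""
        data = EstimationData(_tiny_dataset(2, seed=3), TINY_SPEC)
        theta = np.array([-0.25, 0.5])
        rng = np.random.default_rng(123)
        R = 1_000_000
        z = rng.standard_normal(R)
        ll_mc, var_log = 0.0, 0.0
        for p in range(data.n_patients):
            lo = data.starts[p]
            hi = lo + data.sizes[p]
            x = data.X_rand[lo:hi, 0]
            beta = theta[0] + theta[1] * z  # (R,)
            u = np.outer(x, beta)
            u -= u.max(axis=0)
            prob = np.exp(u)
            prob /= prob.sum(axis=0)
            pc = prob[data.chosen_rows[p] - lo]
            m = pc.mean()
            ll_mc += np.log(m)
            var_log += pc.var() / (R * m**2)
        gh = gh_loglik(theta, data, 64)
        assert abs(gh - ll_mc) < 3.0 * np.sqrt(var_log)

    def test_row_order_invariance(self, small_long):
        df = subset_patients(small_long, 60)
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = EstimationData(df, ModelSpec())
        b = EstimationData(shuffled, ModelSpec())
        ds = make_draws(a.n_patients, a.n_rand, 16)
        theta = a.pack(mu={"distance": -0.2}, sigma={"no_online": 0.5})
        assert simulated_loglik(theta, a, ds) == pytest.approx(
            simulated_loglik(theta, b, ds), abs=1e-9
        )


class TestConditionalLogit:
    def test_matches_statsmodels(self, small_long):
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = subset_patients(small_long, 100)
        spec = ModelSpec(fixed_attrs=("bed_size", "teaching"), fe_key=None)
        data = EstimationData(df, spec)
        mine = fit_conditional_logit(data)
        X = np.hstack([data.X_rand, data.X_fixed])
        sm_fit = ConditionalLogit(
            data.frame["chosen"].to_numpy(), X, groups=data.frame["patient_id"].to_numpy()
        ).fit(disp=False, method="newton", tol=1e-12, maxiter=200)
        assert np.allclose(mine.params.to_numpy(), sm_fit.params, atol=1e-4)

    def test_perfect_separation_rejected(self, small_long):
        df = subset_patients(small_long, 80).copy()
        df["winner"] = df["chosen"].astype(float)
        spec = ModelSpec(random_attrs=("distance", "winner"), fixed_attrs=(), fe_key=None)
        with pytest.raises(ValueError, match="winner"):
            fit_conditional_logit(EstimationData(df, spec))

    def test_collinear_covariates_named(self, small_long):
        df = subset_patients(small_long, 80).copy()
        df["distance_twice"] = 2.0 * df["distance"]
        spec = ModelSpec(
            random_attrs=("distance", "distance_twice"), fixed_attrs=(), fe_key=None
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_conditional_logit(EstimationData(df, spec))

    def test_location_shift_of_attribute_leaves_estimates_unchanged(self, small_long):
        df = subset_patients(small_long, 150)
        shifted = df.copy()
        shifted["cicu"] = shifted["cicu"] + 5.0
        a = fit_conditional_logit(EstimationData(df, ModelSpec()))
        b = fit_conditional_logit(EstimationData(shifted, ModelSpec()))
        for attr in cc.RANDOM_ATTRS:
            assert a.params[f"mu:{attr}"] == pytest.approx(
                b.params[f"mu:{attr}"], abs=1e-6
            )


class TestMixedFit:
    def test_nests_conditional_logit(self, small_data, small_fit):
        cl = fit_conditional_logit(small_data)
        assert small_fit.loglik >= cl.loglik - 1e-6

    def test_sigma_reported_non_negative_and_vcov_sane(self, small_fit):
        for a in small_fit.spec.random_attrs:
            assert small_fit.sd(a) >= 0.0
        v = small_fit.vcov.to_numpy()
        assert np.allclose(v, v.T, atol=1e-10)
        assert np.allclose(
            small_fit.se.to_numpy(), np.sqrt(np.clip(np.diag(v), 0, None))
        )

    def test_draw_count_stability(self, small_long):
        df = subset_patients(small_long, 250)
        spec = ModelSpec(fixed_attrs=("bed_size", "teaching"), fe_key=None)
        f1 = cc.fit(df, spec, draws=48, seed=0, tol=1e-4, compute_se=True,
                    hessian_scheme="forward")
        f2 = cc.fit(df, spec, draws=96, seed=0, tol=1e-4, compute_se=False)
        diff = (f1.params - f2.params).abs()
        assert (diff <= f1.se.replace(0, np.inf)).all()

    def test_duplicating_patients_preserves_estimates_and_shrinks_se(self, small_long):
        df = subset_patients(small_long, 200)
        spec = ModelSpec(random_attrs=("no_online", "distance"), fixed_attrs=(), fe_key=None)
        doubled = pd.concat(
            [df, df.assign(patient_id="dup_" + df["patient_id"])],
            ignore_index=True,
        )
        f1 = cc.fit(df, spec, draws=48, seed=0, tol=1e-4, hessian_scheme="forward")
        f2 = cc.fit(doubled, spec, draws=48, seed=0, tol=1e-4, hessian_scheme="forward")
        assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=0.06)
        ratio = (f2.se / f1.se).to_numpy()
        mu_ratio = ratio[: 2]  # mean parameters are well identified
        assert np.all(mu_ratio < 0.85) and np.all(mu_ratio > 0.55)

    def test_degenerate_attribute_rejected(self, small_long):
        df = subset_patients(small_long, 50).copy()
        df["flat"] = 1.0
        spec = ModelSpec(random_attrs=("distance", "flat"), fixed_attrs=(), fe_key=None)
        with pytest.raises(ValueError, match="flat"):
            cc.fit(df, spec, draws=8)

    def test_summary_table_mentions_every_random_attr(self, small_fit):
        table = small_fit.summary_table()
        for a in small_fit.spec.random_attrs:
            assert a in table

    def test_json_round_trip(self, small_fit, tmp_path):
        import json

        path = tmp_path / "fit.json"
        small_fit.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["loglik"] == pytest.approx(small_fit.loglik)
        assert payload["params"]["mu:distance"] == pytest.approx(
            small_fit.mu("distance")
        )
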