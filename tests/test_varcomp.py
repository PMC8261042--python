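"""Gibbs variance components: conditional exactness, diagnostics, parameter maps."""

import numpy as np
import pandas as pd
import pytest

from tickblup import kinship as km
from tickblup import ssgblup, varcomp

from conftest import random_pedigree


@pytest.fixture(scope="module")
def small_system():
    rng = np.random.default_rng(5150)
    n = 40
    sire, dam = random_pedigree(n, rng, 16)
    ids = [f"a{i}" for i in range(n)]
    breed = np.array(["A"] * 20 + ["B"] * 20)
    Ainv = km.build_A_inverse(sire, dam, ids)
    y = rng.normal(0, 1, n)
    rec = pd.DataFrame({"animal": ids, "breed": breed, "value": y})
    spec = ssgblup.ModelSpec(breeds=["A", "B"], cg_column=None, intercept=False)
    return rng, n, sire, dam, ids, breed, Ainv, rec, spec


def _state(n, Sigma, s2e):
    return {
        "sigma_u": np.asarray(Sigma, dtype=float), "sigma2_e": np.asarray(s2e, dtype=float),
        "sigma2_pe": np.zeros(0), "beta": np.zeros(0),
        "u": np.zeros((n, 2)), "pe": np.zeros(0),
    }


class TestConditionalExactness:
    def test_location_draws_match_dense_gaussian_posterior(self, small_system):
        # variances frozen: u | y ~ N(C^-1 r, C^-1) exactly
        _, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        Sigma = np.array([[0.3, 0.12], [0.12, 0.4]])
        comps = varcomp.CovarianceComponents(
            breeds=["A", "B"], Sigma_u=Sigma, sigma2_e={"A": 0.7, "B": 0.6}
        )
        system = ssgblup.assemble_mme(rec, spec, comps, Ainv)
        Cinv = np.linalg.inv(system.C.toarray())
        mean_exact = Cinv @ system.rhs
        chain = varcomp.gibbs_sample(
            rec, spec, Ainv, n_cycles=12_000, burn_in=1_000, thinning=2, seed=5,
            initial_state=_state(n, Sigma, [0.7, 0.6]),
            update_variances=False, store_location_draws=True,
        )
        U = chain.location_draws
        assert np.abs(U.mean(axis=0) - mean_exact).max() < 0.05
        assert np.abs(U.std(axis=0) - np.sqrt(np.diag(Cinv))).max() < 0.03

    def test_location_draws_exact_with_pe_on_second_trait(self, small_system):
        # PE on a trait that is not first in the layout: the PE level must
        # use its own breed's residual variance, not the PE-array index
        rng, n, sire, dam, ids, breed, Ainv, rec, _ = small_system
        rec2 = pd.concat([rec, rec[rec["breed"] == "B"]], ignore_index=True)  # repeats for B
        spec = ssgblup.ModelSpec(breeds=["A", "B"], cg_column=None, intercept=False,
                                 pe_breeds=("B",))
        Sigma = np.array([[0.3, 0.1], [0.1, 0.4]])
        comps = varcomp.CovarianceComponents(
            breeds=["A", "B"], Sigma_u=Sigma,
            sigma2_pe={"B": 0.2}, sigma2_e={"A": 0.9, "B": 0.4},
        )
        system = ssgblup.assemble_mme(rec2, spec, comps, Ainv)
        Cinv = np.linalg.inv(system.C.toarray())
        mean_exact = Cinv @ system.rhs
        n_pe = system.meta["n_pe"]
        st = _state(n, Sigma, [0.9, 0.4])
        st["sigma2_pe"] = np.array([0.2])
        st["pe"] = np.zeros(n_pe)
        chain = varcomp.gibbs_sample(
            rec2, spec, Ainv, n_cycles=12_000, burn_in=1_000, thinning=2, seed=15,
            initial_state=st, update_variances=False, store_location_draws=True,
        )
        # compare the breeding-value block (first n*t equations after fixed)
        U = chain.location_draws
        assert np.abs(U.mean(axis=0) - mean_exact[: 2 * n]).max() < 0.05

    def test_covariance_draw_matches_inverse_wishart_closed_form(self, small_system):
        rng, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        u_fix = rng.normal(0, 0.5, (n, 2))
        st = _state(n, 0.25 * np.eye(2), [0.7, 0.7])
        st["u"] = u_fix
        priors = varcomp.GibbsPriors(S_u=0.1 * np.eye(2), s2_e={"A": 0.5, "B": 0.5})
        chain = varcomp.gibbs_sample(
            rec, spec, Ainv, priors=priors, n_cycles=20_000, burn_in=0, thinning=1,
            seed=6, initial_state=st, update_locations=False,
        )
        scale = 0.1 * np.eye(2) + u_fix.T @ (Ainv.values.toarray() @ u_fix)
        df = 4 + n  # nu0 = t + 2 plus q animals
        mean_th = scale / (df - 2 - 1)
        d = chain.draws
        assert d["cov_u[A,A]"].mean() == pytest.approx(mean_th[0, 0], rel=0.03)
        assert d["cov_u[A,B]"].mean() == pytest.approx(mean_th[0, 1], abs=0.03 * mean_th[0, 0])
        assert d["cov_u[B,B]"].mean() == pytest.approx(mean_th[1, 1], rel=0.03)
        # residual full conditionals: scaled inverse chi-square means
        tix = (breed == "B").astype(int)
        for k, b in enumerate(["A", "B"]):
            sse = ((rec["value"].to_numpy() - u_fix[np.arange(n), tix])[breed == b] ** 2).sum()
            th = (3 * 0.5 + sse) / (3 + (breed == b).sum() - 2)
            assert d[f"var_e[{b}]"].mean() == pytest.approx(th, rel=0.03)


class TestChainBehaviour:
    def test_seeded_determinism_and_record_order_invariance(self, small_system):
        _, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        kw = dict(n_cycles=300, burn_in=100, thinning=2, seed=9)
        c1 = varcomp.gibbs_sample(rec, spec, Ainv, **kw)
        c2 = varcomp.gibbs_sample(rec, spec, Ainv, **kw)
        pd.testing.assert_frame_equal(c1.draws, c2.draws)
        shuffled = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        c3 = varcomp.gibbs_sample(shuffled, spec, Ainv, **kw)
        pd.testing.assert_frame_equal(c1.draws, c3.draws)

    def test_zero_heritability_recovered(self):
        # no genetic signal: posterior h2 mass near zero, sigma2_e near truth
        rng = np.random.default_rng(8)
        nf, nrec = 600, 3_000
        n = nf + nrec
        sire = np.full(n, -1)
        dam = np.full(n, -1)
        for i in range(nf, n):
            s, d = rng.choice(nf, 2, replace=False)
            sire[i], dam[i] = s, d
        ids = [f"a{i}" for i in range(n)]
        Ainv = km.build_A_inverse(sire, dam, ids)
        rec = pd.DataFrame(
            {"animal": ids[nf:], "breed": "X", "value": rng.normal(0.0, 1.0, nrec)}
        )
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        chain = varcomp.gibbs_sample(rec, spec, Ainv, n_cycles=4_000, burn_in=1_000,
                                     thinning=5, seed=10)
        d = chain.draws
        assert d["var_e[X]"].mean() == pytest.approx(1.0, rel=0.05)
        h2 = d["cov_u[X,X]"] / (d["cov_u[X,X]"] + d["var_e[X]"])
        assert h2.median() < 0.05

    def test_invalid_chain_config_rejected(self, small_system):
        _, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        with pytest.raises(ValueError):
            varcomp.gibbs_sample(rec, spec, Ainv, n_cycles=100, burn_in=100)

    def test_trait_without_records_needs_proper_prior(self, small_system):
        _, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        only_a = rec[rec["breed"] == "A"]
        priors = varcomp.GibbsPriors(nu_u=3.0)  # improper for t = 2
        with pytest.raises(ValueError, match="proper prior"):
            varcomp.gibbs_sample(only_a, spec, Ainv, priors=priors, n_cycles=50, burn_in=10)


class TestPosteriorSummary:
    def test_mean_and_constant_chain_conventions(self):
        draws = pd.DataFrame({"p": np.arange(1.0, 13.0), "c": np.ones(12)})
        s = varcomp.posterior_summary(draws).set_index("parameter")
        assert s.loc["p", "mean"] == pytest.approx(6.5)
        assert s.loc["c", "ts_se"] == 0.0
        assert s.loc["c", "ess"] == 12.0
        assert s.loc["c", "geweke_z"] == 0.0

    def test_white_noise_ess_close_to_n(self):
        rng = np.random.default_rng(2)
        draws = pd.DataFrame({"x": rng.standard_normal(2_000)})
        ess = varcomp.posterior_summary(draws)["ess"].iloc[0]
        assert ess == pytest.approx(2_000, rel=0.2)

    def test_ar1_ess_matches_closed_form(self):
        rng = np.random.default_rng(3)
        phi, n = 0.9, 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n) * np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + innov[i]
        ess = varcomp.posterior_summary(pd.DataFrame({"x": x}))["ess"].iloc[0]
        assert ess == pytest.approx(n * (1 - phi) / (1 + phi), rel=0.3)

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError, match="10"):
            varcomp.posterior_summary(pd.DataFrame({"x": [1.0, 2.0]}))


class TestDeriveParameters:
    def test_point_arithmetic(self):
        comps = varcomp.CovarianceComponents(
            breeds=["A", "B"],
            Sigma_u=np.array([[0.3, 0.5 * np.sqrt(0.3)], [0.5 * np.sqrt(0.3), 1.0]]),
            sigma2_pe={"A": 0.1},
            sigma2_e={"A": 0.6, "B": 0.5},
        )
        out = varcomp.derive_parameters(comps).set_index("parameter")["mean"]
        assert out["h2[A]"] == pytest.approx(0.3)
        assert out["repeatability[A]"] == pytest.approx(0.4)
        assert out["r_g[A,B]"] == pytest.approx(0.5)

    def test_draw_wise_bounds(self, small_system):
        _, n, sire, dam, ids, breed, Ainv, rec, spec = small_system
        chain = varcomp.gibbs_sample(rec, spec, Ainv, n_cycles=400, burn_in=100,
                                     thinning=2, seed=12)
        d = chain.draws
        h2 = d["cov_u[A,A]"] / (d["cov_u[A,A]"] + d["var_e[A]"])
        rg = d["cov_u[A,B]"] / np.sqrt(d["cov_u[A,A]"] * d["cov_u[B,B]"])
        assert ((h2 > 0) & (h2 < 1)).all()
        assert ((rg >= -1) & (rg <= 1)).all()
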