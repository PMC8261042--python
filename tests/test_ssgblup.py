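"""Mixed-model equations: assembly, PCG solutions, reduction identities."""

import numpy as np
import pandas as pd
import pytest

from tickblup import kinship as km
from tickblup import ssgblup, varcomp

from conftest import random_pedigree


def _components(breeds, Sigma, s2e, s2p=None):
    return varcomp.CovarianceComponents(
        breeds=breeds, Sigma_u=np.atleast_2d(Sigma),
        sigma2_pe=s2p or {}, sigma2_e=s2e,
    )


def _pedigree_records(rng, n=60, h2=0.3, n_founders=15):
    sire, dam = random_pedigree(n, rng, n_founders)
    ids = [f"a{i}" for i in range(n)]
    A = km.build_A(sire, dam, ids).toarray()
    u = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.standard_normal(n) * np.sqrt(h2)
    recorded = list(range(n_founders, n))
    y = 1.0 + u[recorded] + rng.normal(0, np.sqrt(1 - h2), len(recorded))
    rec = pd.DataFrame({"animal": [ids[i] for i in recorded], "breed": "X", "value": y})
    return sire, dam, ids, A, rec, u


class TestScalarClosedForm:
    def test_single_animal_shrinkage(self):
        # mean + animal model, one animal, one record, variance ratio lam:
        # MME: [[1, 1], [1, 1 + lam]] [mu, u] = [y, y]  =>  u = 0
        # with TWO animals sharing the mean, each u shrinks its deviation
        lam = 0.7 / 0.3
        rec = pd.DataFrame({"animal": ["a", "b"], "breed": "X", "value": [2.0, 4.0]})
        Ainv = km.build_A_inverse(np.array([-1, -1]), np.array([-1, -1]), ["a", "b"])
        comps = _components(["X"], [[0.3]], {"X": 0.7})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        sol = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv), tol=1e-12)
        u = sol.breeding_values()["X"]
        # closed form: u_i = (y_i - mu) / (1 + lam), mu = 3
        assert u["a"] == pytest.approx((2.0 - 3.0) / (1 + lam), abs=1e-8)
        assert u["b"] == pytest.approx((4.0 - 3.0) / (1 + lam), abs=1e-8)

    def test_zero_rhs_gives_zero_solution(self):
        rec = pd.DataFrame({"animal": ["a", "b"], "breed": "X", "value": [0.0, 0.0]})
        Ainv = km.build_A_inverse(np.array([-1, -1]), np.array([-1, -1]), ["a", "b"])
        comps = _components(["X"], [[0.3]], {"X": 0.7})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        sol = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv))
        assert np.allclose(sol.table["estimate"], 0.0)


class TestSolver:
    def test_matches_dense_solve(self, rng):
        sire, dam, ids, A, rec, _ = _pedigree_records(rng)
        Ainv = km.build_A_inverse(sire, dam, ids)
        comps = _components(["X"], [[0.3]], {"X": 0.7})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        system = ssgblup.assemble_mme(rec, spec, comps, Ainv)
        sol = ssgblup.solve_mme(system, tol=1e-12)
        dense = np.linalg.solve(system.C.toarray(), system.rhs)
        assert np.abs(sol.table.sort_values("eq")["estimate"].to_numpy() - dense).max() < 1e-8

    def test_nonconvergence_raises(self, rng):
        sire, dam, ids, A, rec, _ = _pedigree_records(rng)
        Ainv = km.build_A_inverse(sire, dam, ids)
        comps = _components(["X"], [[0.3]], {"X": 0.7})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        system = ssgblup.assemble_mme(rec, spec, comps, Ainv)
        with pytest.raises(RuntimeError, match="converge"):
            ssgblup.solve_mme(system, tol=1e-14, max_iter=2)

    def test_pedigree_blup_matches_dense_gls(self, rng):
        # u_hat = sigma2_u A Z' V^-1 (y - X beta_gls): the classical GLS oracle
        sire, dam, ids, A, rec, _ = _pedigree_records(rng, n=50, n_founders=12)
        n = len(ids)
        recorded = [ids.index(a) for a in rec["animal"]]
        Z = np.zeros((len(rec), n))
        Z[np.arange(len(rec)), recorded] = 1.0
        X = np.ones((len(rec), 1))
        s2u, s2e = 0.3, 0.7
        V = s2u * Z @ A @ Z.T + s2e * np.eye(len(rec))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ rec["value"].to_numpy())
        u_gls = s2u * A @ Z.T @ Vi @ (rec["value"].to_numpy() - X @ beta)

        Ainv = km.build_A_inverse(sire, dam, ids)
        comps = _components(["X"], [[s2u]], {"X": s2e})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        sol = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv), tol=1e-12)
        u_mme = sol.breeding_values()["X"].loc[ids].to_numpy()
        assert np.abs(u_mme - u_gls).max() < 1e-6


class TestMultiTrait:
    def _two_breed_setup(self, rng, rg):
        sire, dam = random_pedigree(80, rng, 20)
        ids = [f"a{i}" for i in range(80)]
        Ainv = km.build_A_inverse(sire, dam, ids)
        breed = np.where(np.arange(80) % 2 == 0, "X", "Y")
        recorded = np.arange(20, 80)
        y = rng.normal(0, 1, len(recorded))
        rec = pd.DataFrame(
            {"animal": [ids[i] for i in recorded], "breed": breed[recorded], "value": y}
        )
        Sigma = np.array([[0.3, rg * np.sqrt(0.3 * 0.4)], [rg * np.sqrt(0.3 * 0.4), 0.4]])
        comps = _components(["X", "Y"], Sigma, {"X": 0.7, "Y": 0.6})
        spec = ssgblup.ModelSpec(breeds=["X", "Y"], cg_column=None, intercept=True)
        return rec, comps, spec, Ainv, ids

    def test_zero_genetic_correlation_equals_univariate(self, rng):
        rec, comps, spec, Ainv, ids = self._two_breed_setup(rng, rg=0.0)
        multi = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv), tol=1e-12)
        for b in ("X", "Y"):
            uni = ssgblup.predict_univariate(rec, spec, comps, Ainv, b, tol=1e-12)
            um = multi.breeding_values()[b].loc[ids].to_numpy()
            uu = uni.breeding_values()[b].loc[ids].to_numpy()
            assert np.abs(um - uu).max() < 1e-6

    def test_trait_order_invariance(self, rng):
        rec, comps, spec, Ainv, ids = self._two_breed_setup(rng, rg=0.6)
        sol_xy = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv), tol=1e-12)
        comps_yx = _components(
            ["Y", "X"], comps.Sigma_u[::-1, ::-1].copy(), dict(comps.sigma2_e)
        )
        spec_yx = ssgblup.ModelSpec(breeds=["Y", "X"], cg_column=None, intercept=True)
        sol_yx = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec_yx, comps_yx, Ainv), tol=1e-12)
        for b in ("X", "Y"):
            assert np.allclose(
                sol_xy.breeding_values()[b].loc[ids],
                sol_yx.breeding_values()[b].loc[ids],
                atol=1e-7,
            )

    def test_near_zero_genetic_variance_shrinks_to_zero(self, rng):
        rec, comps, spec, Ainv, ids = self._two_breed_setup(rng, rg=0.0)
        tiny = _components(["X", "Y"], 1e-8 * np.eye(2), dict(comps.sigma2_e))
        sol = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, tiny, Ainv), tol=1e-12)
        assert np.abs(sol.breeding_values().to_numpy()).max() < 1e-4


class TestValidation:
    def test_record_breed_outside_layout_rejected(self, rng):
        rec = pd.DataFrame({"animal": ["a"], "breed": "Z", "value": [1.0]})
        Ainv = km.build_A_inverse(np.array([-1]), np.array([-1]), ["a"])
        comps = _components(["X"], [[0.3]], {"X": 0.7})
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        with pytest.raises(ValueError, match="breeds outside"):
            ssgblup.assemble_mme(rec, spec, comps, Ainv)

    def test_non_spd_sigma_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            _components(["X", "Y"], np.array([[1.0, 2.0], [2.0, 1.0]]),
                        {"X": 0.5, "Y": 0.5})

    def test_accuracy_responds_to_variance_input(self, rng):
        sire, dam, ids, A, rec, u = _pedigree_records(rng, n=400, h2=0.3, n_founders=100)
        Ainv = km.build_A_inverse(sire, dam, ids)
        spec = ssgblup.ModelSpec(breeds=["X"], cg_column=None, intercept=True)
        accs = {}
        for s2u in (0.3, 0.01):
            comps = _components(["X"], [[s2u]], {"X": 0.7})
            sol = ssgblup.solve_mme(ssgblup.assemble_mme(rec, spec, comps, Ainv))
            uh = sol.breeding_values()["X"].loc[ids].to_numpy()
            accs[s2u] = np.corrcoef(uh, u)[0, 1]
        assert accs[0.3] > accs[0.01]
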