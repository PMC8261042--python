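"""Multi-trait (breed-as-trait) single-step GBLUP mixed-model equations.

Each breed's tick-infestation measurement is treated as a separate trait;
an animal belongs to exactly one breed, so residual and permanent-
environment effects are uncorrelated between traits while additive
genetic effects are linked across breeds through the t x t genetic
covariance and the joint relationship matrix H (pedigree + genomic).

The additive prior contributes H^-1 kron Sigma_u^-1 to the coefficient
matrix (animal-major equation ordering), PE blocks are I/sigma2_p(b), and
records are weighted by 1/sigma2_e of their breed. The system is solved
by Jacobi-preconditioned conjugate gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kinship import RelationshipMatrix

__all__ = ["ModelSpec", "MMESystem", "Solutions", "assemble_mme", "solve_mme", "predict_univariate"]


@dataclass
class ModelSpec:
    """Fixed- and random-effect layout of the evaluation model.

    Per trait the fixed part is the contemporary-group factor plus the
    listed covariates (with an optional age column entering linear +
    quadratic after centering/scaling). ``pe_breeds`` lists the traits
    with repeated records, which carry a permanent-environment term.
    With ``intercept=True`` the first level of each factor is constrained
    to zero; without an intercept all CG levels are estimable as-is.
    """

    breeds: list
    cg_column: str | None = "cg"
    covariates: list = field(default_factory=list)
    age_column: str | None = None
    pe_breeds: tuple = ()
    intercept: bool = False

    def __post_init__(self):
        bad = [b for b in self.pe_breeds if b not in self.breeds]
        if bad:
            raise ValueError(f"pe_breeds not in trait layout: {bad}")


@dataclass
class MMESystem:
    """Sparse symmetric MME with its effect-block index."""

    C: sp.csr_matrix
    rhs: np.ndarray
    index: pd.DataFrame  # columns: effect, trait, level, eq
    animal_ids: list
    breeds: list
    meta: dict = field(default_factory=dict)


@dataclass
class Solutions:
    """MME solutions keyed by the effect-block index."""

    table: pd.DataFrame  # effect, trait, level, estimate
    diagnostics: dict

    def breeding_values(self) -> pd.DataFrame:
        u = self.table[self.table["effect"] == "animal"]
        return u.pivot(index="level", columns="trait", values="estimate")


def _fixed_design(records: pd.DataFrame, spec: ModelSpec):
    """Per-trait fixed-effect design; returns sparse X, labels, trait of each column."""
    n = len(records)
    cols, names, traits = [], [], []
    breed = records["breed"].to_numpy()
    for b in spec.breeds:
        sel = breed == b
        if not sel.any():
            continue  # trait without records contributes no fixed effects
        if spec.intercept:
            v = np.zeros(n)
            v[sel] = 1.0
            cols.append(v)
            names.append(("intercept", b, "1"))
            traits.append(b)
        if spec.cg_column is not None and spec.cg_column in records:
            levels = sorted(records.loc[sel, spec.cg_column].astype(str).unique())
            if spec.intercept and levels:
                levels = levels[1:]  # first level constrained to zero
            for lv in levels:
                v = np.zeros(n)
                v[sel & (records[spec.cg_column].astype(str) == lv).to_numpy()] = 1.0
                cols.append(v)
                names.append(("cg", b, lv))
                traits.append(b)
        for c in spec.covariates:
            v = np.zeros(n)
            v[sel] = records.loc[sel, c].to_numpy(dtype=float)
            cols.append(v)
            names.append(("covariate", b, c))
            traits.append(b)
        if spec.age_column is not None:
            age = records.loc[sel, spec.age_column].to_numpy(dtype=float)
            mu, sd = age.mean(), age.std() if age.std() > 0 else 1.0
            z = (age - mu) / sd
            for lab, vals in (("age", z), ("age2", z * z)):
                v = np.zeros(n)
                v[sel] = vals
                cols.append(v)
                names.append(("covariate", b, lab))
                traits.append(b)
    X = sp.csc_matrix(np.column_stack(cols)) if cols else sp.csc_matrix((n, 0))
    return X, names, traits


def assemble_mme(
    records: pd.DataFrame,
    spec: ModelSpec,
    components,
    H_inv: RelationshipMatrix,
) -> MMESystem:
    """Assemble the single-step mixed-model equations.

    ``records`` needs columns ``animal``, ``breed``, ``value`` plus the
    fixed-effect columns named in ``spec``. ``components`` supplies
    ``Sigma_u`` (t x t, trait order = spec.breeds), ``sigma2_pe`` and
    ``sigma2_e`` dicts. ``H_inv`` must cover every recorded animal.
    """
    t = len(spec.breeds)
    Sigma_u = np.asarray(components.Sigma_u, dtype=float)
    if Sigma_u.shape != (t, t):
        raise ValueError("Sigma_u dimension does not match the trait layout")
    eig = np.linalg.eigvalsh((Sigma_u + Sigma_u.T) / 2)
    if np.min(eig) <= 0:
        raise ValueError("Sigma_u is not symmetric positive definite")
    bad = sorted(set(records["breed"]) - set(spec.breeds))
    if bad:
        raise ValueError(f"records carry breeds outside the trait layout: {bad}")

    animal_ids = list(H_inv.ids)
    a_lookup = {a: k for k, a in enumerate(animal_ids)}
    missing = sorted(set(records["animal"]) - set(animal_ids))
    if missing:
        raise ValueError(f"recorded animals missing from H: {missing[:5]}")
    n_anim = len(animal_ids)
    n_rec = len(records)

    y = records["value"].to_numpy(dtype=float)
    breed = records["breed"].to_numpy()
    trait_of_rec = np.array([spec.breeds.index(b) for b in breed])
    anim_of_rec = np.array([a_lookup[a] for a in records["animal"]])
    sigma2_e = np.array([components.sigma2_e[b] for b in spec.breeds], dtype=float)
    if np.any(sigma2_e <= 0):
        raise ValueError("residual variances must be positive")
    rinv = 1.0 / sigma2_e[trait_of_rec]

    X, fixed_names, _ = _fixed_design(records, spec)
    n_fixed = X.shape[1]

    # incidence of additive effects: record -> equation offset + animal*t + trait
    Zu = sp.csc_matrix(
        (np.ones(n_rec), (np.arange(n_rec), anim_of_rec * t + trait_of_rec)),
        shape=(n_rec, n_anim * t),
    )
    # PE: one level per recorded animal of a PE breed
    pe_rows = [i for i in range(n_rec) if breed[i] in spec.pe_breeds]
    pe_animals = sorted({records["animal"].iloc[i] for i in pe_rows}, key=lambda a: a_lookup[a])
    pe_lookup = {a: k for k, a in enumerate(pe_animals)}
    n_pe = len(pe_animals)
    if pe_rows:
        Zp = sp.csc_matrix(
            (
                np.ones(len(pe_rows)),
                (pe_rows, [pe_lookup[records["animal"].iloc[i]] for i in pe_rows]),
            ),
            shape=(n_rec, n_pe),
        )
    else:
        Zp = sp.csc_matrix((n_rec, 0))

    W = sp.hstack([X, Zu, Zp]).tocsr()
    R = sp.diags(rinv)
    C = (W.T @ R @ W).tocsr()
    rhs = W.T @ (rinv * y)

    Sigma_inv = np.linalg.inv(Sigma_u)
    Ginv_block = sp.kron(sp.csr_matrix(H_inv.values), sp.csr_matrix(Sigma_inv), format="csr")
    prior = sp.block_diag(
        [sp.csr_matrix((n_fixed, n_fixed)), Ginv_block,
         _pe_prior(pe_animals, records, a_lookup, components)],
        format="csr",
    )
    C = C + prior

    rows = [
        {"effect": e, "trait": b, "level": lv, "eq": k}
        for k, (e, b, lv) in enumerate(fixed_names)
    ]
    for k, a in enumerate(animal_ids):
        for j, b in enumerate(spec.breeds):
            rows.append({"effect": "animal", "trait": b, "level": a, "eq": n_fixed + k * t + j})
    breed_of_animal = dict(zip(records["animal"], breed))
    for k, a in enumerate(pe_animals):
        rows.append({"effect": "pe", "trait": breed_of_animal[a], "level": a,
                     "eq": n_fixed + n_anim * t + k})
    index = pd.DataFrame(rows)
    return MMESystem(C.tocsr(), np.asarray(rhs).ravel(), index, animal_ids, list(spec.breeds),
                     meta={"n_fixed": n_fixed, "t": t, "n_pe": n_pe})


def _pe_prior(pe_animals, records, a_lookup, components):
    if not pe_animals:
        return sp.csr_matrix((0, 0))
    breed_of_animal = dict(zip(records["animal"], records["breed"]))
    vals = []
    for a in pe_animals:
        s2 = components.sigma2_pe[breed_of_animal[a]]
        if s2 <= 0:
            raise ValueError(f"non-positive PE variance for breed {breed_of_animal[a]}")
        vals.append(1.0 / s2)
    return sp.diags(vals).tocsr()


def solve_mme(system: MMESystem, tol: float = 1e-10, max_iter: int = 10000) -> Solutions:
    """Jacobi-preconditioned conjugate-gradient solve of the MME.

    Deterministic given inputs; raises on non-convergence with the
    residual trace attached rather than returning a partial answer.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    C, b = system.C, system.rhs
    bnorm = np.linalg.norm(b)
    x = np.zeros_like(b)
    trace = []
    if bnorm > 0:
        d = C.diagonal().copy()
        d[d <= 0] = 1.0
        minv = 1.0 / d
        r = b - C @ x
        z = minv * r
        p = z.copy()
        rz = r @ z
        for it in range(max_iter):
            Cp = C @ p
            alpha = rz / (p @ Cp)
            x += alpha * p
            r -= alpha * Cp
            rel = np.linalg.norm(r) / bnorm
            trace.append(rel)
            if rel <= tol:
                break
            z = minv * r
            rz_new = r @ z
            p = z + (rz_new / rz) * p
            rz = rz_new
        else:
            raise RuntimeError(
                f"PCG did not converge in {max_iter} iterations "
                f"(final relative residual {trace[-1]:.3e})"
            )
    table = system.index.copy()
    table["estimate"] = x[table["eq"].to_numpy()]
    return Solutions(table, {"iterations": len(trace), "residuals": trace})


@dataclass
class _MarginalComponents:
    Sigma_u: np.ndarray
    sigma2_pe: dict
    sigma2_e: dict


def predict_univariate(
    records: pd.DataFrame,
    spec: ModelSpec,
    components,
    H_inv: RelationshipMatrix,
    breed: str,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> Solutions:
    """Single-breed evaluation under the marginal model.

    The breed's marginal variances are extracted from the shared
    multi-trait components (u_b ~ N(0, H sigma2_ub)), records of the other
    breeds are dropped, and the same assemble/solve contract applies.
    """
    if breed not in spec.breeds:
        raise ValueError(f"breed {breed!r} not in trait layout")
    k = spec.breeds.index(breed)
    Sigma_u = np.asarray(components.Sigma_u, dtype=float)
    marg = _MarginalComponents(
        Sigma_u=np.array([[Sigma_u[k, k]]]),
        sigma2_pe=dict(getattr(components, "sigma2_pe", {})),
        sigma2_e={breed: components.sigma2_e[breed]},
    )
    sub_spec = ModelSpec(
        breeds=[breed],
        cg_column=spec.cg_column,
        covariates=list(spec.covariates),
        age_column=spec.age_column,
        pe_breeds=tuple(b for b in spec.pe_breeds if b == breed),
        intercept=spec.intercept,
    )
    sub_records = records[records["breed"] == breed]
    system = assemble_mme(sub_records, sub_spec, marg, H_inv)
    return solve_mme(system, tol=tol, max_iter=max_iter)
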