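"""LR-method validation of genomic predictions.

Compares breeding values estimated from the whole data (u_w) against a
partial run (u_p) in which the validation animals' phenotypes are masked:

* ``old-young`` — within the target breed, the oldest 2/3 of the
  phenotyped animals keep their records and the youngest 1/3 are the
  validation group (mimicking selection candidates);
* ``other-pops`` — every phenotype of the target breed is removed, so
  predictions flow exclusively through the genetic correlations with the
  other breeds.

Statistics over the validation animals: rho_w,p = corr(u_w, u_p), which
estimates acc_p/acc_w (relative accuracy); predictive ability
r(y*, u_p) with y* the phenotype adjusted for fixed and PE effects from
the whole-data fit; and the dispersion slope beta_w,p of the regression
of u_w on u_p (1 = unbiased, < 1 = inflated partial predictions). With
simulation truth available, population accuracies corr(u_hat, u_true)
are reported as well.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Partition", "make_partition", "lr_statistics", "accuracy_from_truth"]


@dataclass
class Partition:
    strategy: str  # old-young | other-pops
    target_breed: str
    reference_records: pd.DataFrame  # the partial data
    validation_ids: list
    cut_date: str | None = None


def make_partition(
    phenotypes: pd.DataFrame,
    pedigree_table: pd.DataFrame,
    strategy: str,
    target_breed: str,
) -> Partition:
    """Split phenotypes into partial (reference) data and validation animals.

    ``old-young``: animals of the target breed sorted by birth date (ties
    by id); the oldest floor(2n/3) stay in the reference, the youngest
    ceil(n/3) have all phenotypes masked. Other breeds are fully retained.
    ``other-pops``: every target-breed phenotype is masked. Masked animals
    keep their genotypes and pedigree links — only records are removed.
    """
    tgt = phenotypes[phenotypes["breed"] == target_breed]
    animals = sorted(tgt["animal"].unique())
    if len(animals) < 3:
        raise ValueError("need at least 3 phenotyped animals in the target breed")
    if strategy == "old-young":
        birth = pedigree_table.set_index("id")["birthdate"]
        missing = [a for a in animals if a not in birth.index or pd.isna(birth[a])]
        if missing:
            raise ValueError(f"missing birth dates for old-young: {missing[:5]}")
        order = sorted(animals, key=lambda a: (str(birth[a]), a))
        n_ref = (2 * len(order)) // 3
        validation = order[n_ref:]
        cut = str(birth[validation[0]])
    elif strategy == "other-pops":
        validation = animals
        cut = None
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    mask = phenotypes["animal"].isin(validation) & (phenotypes["breed"] == target_breed)
    return Partition(
        strategy=strategy,
        target_breed=target_breed,
        reference_records=phenotypes[~mask].reset_index(drop=True),
        validation_ids=list(validation),
        cut_date=cut,
    )


def _corr(x, y):
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def lr_statistics(
    u_whole: pd.Series,
    u_partial: pd.Series,
    y_star: pd.Series,
    validation_ids: list,
) -> dict:
    """LR statistics over the validation animals.

    ``u_whole`` / ``u_partial`` are breeding-value estimates indexed by
    animal id; ``y_star`` holds adjusted phenotypes (repeated records
    already averaged per animal). Returns rho_w,p, predictive ability
    r(y*, u_p), the dispersion slope beta_w,p = cov(u_w, u_p)/var(u_p),
    and n. Undefined statistics (zero variance) are reported as NaN.
    """
    ids = [a for a in validation_ids]
    missing = [a for a in ids if a not in u_whole.index or a not in u_partial.index]
    if missing:
        raise ValueError(f"validation animals without estimates: {missing[:5]}")
    uw = u_whole.loc[ids].to_numpy(dtype=float)
    up = u_partial.loc[ids].to_numpy(dtype=float)
    rho = _corr(uw, up)
    var_p = np.var(up)
    beta = float(np.cov(uw, up)[0, 1] / np.cov(up)) if var_p > 0 and len(ids) > 1 else np.nan
    ys_ids = [a for a in ids if a in y_star.index]
    pred = _corr(y_star.loc[ys_ids].to_numpy(dtype=float), u_partial.loc[ys_ids].to_numpy(dtype=float)) if ys_ids else np.nan
    return {
        "rho_wp": rho,
        "predictive_ability": pred,
        "beta_wp": beta,
        "n_validation": len(ids),
    }


def accuracy_from_truth(u_hat: pd.Series, u_true: pd.Series, validation_ids: list) -> float:
    """Population accuracy: corr(estimated, true BV) over the validation set."""
    ids = list(validation_ids)
    return _corr(u_hat.loc[ids].to_numpy(dtype=float), u_true.loc[ids].to_numpy(dtype=float))


def adjusted_phenotypes(
    records: pd.DataFrame,
    solutions,
    breed: str,
) -> pd.Series:
    """y* = y - X beta_hat - W p_hat from a whole-data fit, per animal.

    Fixed-effect and PE estimates are read from a :class:`~tickblup.ssgblup.Solutions`
    table; repeated records are averaged after adjustment.
    """
    tab = solutions.table
    rec = records[records["breed"] == breed].copy()
    adj = rec["value"].to_numpy(dtype=float).copy()
    fixed = tab[(tab["trait"] == breed) & (~tab["effect"].isin(["animal", "pe"]))]
    for _, row in fixed.iterrows():
        if row["effect"] == "cg":
            sel = (rec["cg"].astype(str) == row["level"]).to_numpy()
            adj[sel] -= row["estimate"]
        elif row["effect"] == "intercept":
            adj -= row["estimate"]
        elif row["effect"] == "covariate":
            name = row["level"]
            if name in ("age", "age2"):
                age = rec["age"].to_numpy(dtype=float)
                mu, sd = age.mean(), age.std() if age.std() > 0 else 1.0
                z = (age - mu) / sd
                adj -= row["estimate"] * (z if name == "age" else z * z)
            else:
                adj -= row["estimate"] * rec[name].to_numpy(dtype=float)
    pe = tab[(tab["effect"] == "pe") & (tab["trait"] == breed)].set_index("level")["estimate"]
    pe_term = np.array([pe.get(a, 0.0) for a in rec["animal"]])
    adj -= pe_term
    out = pd.Series(adj).groupby(rec["animal"].to_numpy()).mean()
    out.name = "y_star"
    return out
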