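"""Phenotype preparation for tick-resistance records.

Tick infestation is recorded either as adult-female tick counts (Brazilian-
and Nguni-style data) or as a 0-5 visual score (Australian-style data).
Counts are log-transformed, log10(x + 1), to approximate normality; scores
bin the underlying count onto a six-level scale. Records are grouped into
contemporary groups (CG: same farm, sex, birth year/season, management
group and evaluation date) which are size-filtered and trimmed before
modelling. Repeated-record data without pedigree support can be collapsed
to one pre-adjusted value per animal (the Nguni treatment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "log_transform_counts",
    "bin_tick_score",
    "season_from_date",
    "build_contemporary_groups",
    "preadjust_repeated_records",
    "CGReport",
]

# Upper count bound (inclusive) of score classes 0..4; counts above the last
# bound score 5.  Class k covers (bounds[k-1], bounds[k]].
_SCORE_UPPER_BOUNDS = np.array([0, 10, 30, 80, 150])


def log_transform_counts(count, base: float = 10):
    """log_base(count + 1) of a non-negative integer tick count.

    Parameters
    ----------
    count : int or array-like of int
        Raw tick count(s), must be >= 0.
    base : {10, e}
        Logarithm base; ``10`` or the string/float ``'e'``/``np.e``.
    """
    x = np.asarray(count)
    if np.any(x < 0):
        raise ValueError("tick counts must be non-negative")
    if base == 10:
        out = np.log10(x + 1.0)
    elif base in ("e", np.e):
        out = np.log(x + 1.0)
    else:
        raise ValueError("base must be 10 or 'e'")
    return out.item() if np.isscalar(count) else out


def bin_tick_score(count):
    """Bin a tick count onto the 0-5 visual score scale.

    0 = no ticks, 1 = <=10, 2 = 11-30, 3 = 31-80, 4 = 81-150, 5 = >150.
    Weakly monotone in the count.
    """
    x = np.asarray(count)
    if np.any(x < 0):
        raise ValueError("tick counts must be non-negative")
    score = np.searchsorted(_SCORE_UPPER_BOUNDS, x, side="left")
    return int(score) if np.isscalar(count) else score.astype(int)


def season_from_date(dates, boundaries: list[int] | None = None):
    """Season label (1..k) from a date's month, for contemporary-group keys.

    Default seasons are calendar quarters; ``boundaries`` gives the first
    month of each season instead (e.g. ``[10, 4]`` for a wet season
    starting in October and a dry season starting in April).
    """
    months = pd.to_datetime(pd.Series(np.atleast_1d(dates))).dt.month
    if boundaries is None:
        season = (months - 1) // 3 + 1
    else:
        b = sorted(range(len(boundaries)), key=lambda i: boundaries[i])
        starts = [boundaries[i] for i in b]
        idx = np.searchsorted(starts, months, side="right") - 1
        season = pd.Series([b[i % len(b)] + 1 for i in idx], index=months.index)
    out = season.astype(int)
    return int(out.iloc[0]) if np.isscalar(dates) or isinstance(dates, str) else out.to_numpy()


@dataclass
class CGReport:
    """Per-rule removal counts from contemporary-group filtering."""

    n_input: int = 0
    n_removed_small_cg: int = 0
    n_removed_outlier: int = 0
    n_retained: int = 0
    removed_ids: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["small_cg", "outlier", "retained"],
                "n": [self.n_removed_small_cg, self.n_removed_outlier, self.n_retained],
            }
        )


def build_contemporary_groups(
    records: pd.DataFrame,
    cg_columns: list[str],
    value_column: str = "value",
    min_size: int = 5,
    sd_limit: float = 3.5,
) -> tuple[pd.DataFrame, CGReport]:
    """Form contemporary groups, drop small CGs and trim outlying records.

    The CG label is the concatenation of the key columns. Groups with fewer
    than ``min_size`` animals are removed first; then records deviating more
    than ``sd_limit`` SD from their CG mean are removed in a single pass,
    with the SD computed on the untrimmed (post size-filter) group.

    Returns the surviving records (with a ``cg`` column added) and a
    :class:`CGReport` of removals per rule.
    """
    report = CGReport(n_input=len(records))
    if len(records) == 0:
        out = records.copy()
        out["cg"] = pd.Series([], dtype=str)
        return out, report

    rec = records.copy()
    rec["cg"] = rec[cg_columns].astype(str).agg("|".join, axis=1)

    sizes = rec.groupby("cg")["cg"].transform("size")
    small = sizes < min_size
    report.n_removed_small_cg = int(small.sum())
    rec = rec[~small]

    if len(rec):
        grp = rec.groupby("cg")[value_column]
        mean = grp.transform("mean")
        sd = grp.transform("std").fillna(0.0)
        dev = (rec[value_column] - mean).abs()
        # SD 0 (constant group) never trims: deviation is 0 as well.
        outlier = dev > sd_limit * sd
        report.n_removed_outlier = int(outlier.sum())
        rec = rec[~outlier]

    report.n_retained = len(rec)
    return rec, report


def preadjust_repeated_records(
    records: pd.DataFrame,
    animal_column: str = "animal",
    value_column: str = "value",
    factor_columns: list[str] | None = None,
    covariate_columns: list[str] | None = None,
) -> pd.Series:
    """Collapse repeated records to one fixed-effect-adjusted value per animal.

    Ordinary least squares removes the stated fixed effects (an overall mean,
    the given factors and covariates); each animal then receives the mean of
    its residuals. With a mean-only model this is the record mean minus the
    grand mean, and the n-weighted mean of the returned values is ~0.

    Raises ``ValueError`` naming the aliased columns if the design is rank
    deficient after the usual drop-first-level constraint.
    """
    factor_columns = factor_columns or []
    covariate_columns = covariate_columns or []

    y = records[value_column].to_numpy(dtype=float)
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for f in factor_columns:
        dummies = pd.get_dummies(records[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for c in covariate_columns:
        cols.append(records[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by greedy QR-style scan
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            trial = X[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient fixed-effect design; aliased columns: {aliased}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = pd.Series(resid).groupby(records[animal_column].to_numpy()).mean()
    out.name = "adjusted_value"
    return out
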