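"""Render the study-shaped summary tables.

* parameter matrix — breeds x breeds with heritabilities on the diagonal
  and genetic correlations above it (posterior mean +/- time-series SE);
* validation grid — breeds as rows, statistic x strategy column blocks;
* persistence matrix — phase persistence above / allele-frequency
  correlation below the diagonal;
* per-chromosome heatmap data as long-format CSV.

Rendering is a pure function of its inputs: identical inputs give
byte-identical CSV. Values are rounded half-even at the configured
precision; callers keep the full-precision tables alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["render_parameter_matrix", "render_validation_grid", "render_heatmap_long"]


def _fmt(mean, se=None, precision=2):
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return "NA"
    base = f"{np.round(float(mean), precision):.{precision}f}"
    if se is None or (isinstance(se, float) and np.isnan(se)):
        return base
    return f"{base} ± {np.round(float(se), precision):.{precision}f}"


def render_parameter_matrix(parameters: pd.DataFrame, breeds: list, precision: int = 2) -> pd.DataFrame:
    """Breeds x breeds table: h2 on the diagonal, r_g above, blank below.

    ``parameters`` is the output of ``varcomp.derive_parameters`` (columns
    parameter, mean, ts_se) with entries ``h2[b]`` and ``r_g[b,c]``.
    """
    lookup = parameters.set_index("parameter")
    out = pd.DataFrame("", index=breeds, columns=breeds, dtype=object)
    for i, b in enumerate(breeds):
        key = f"h2[{b}]"
        if key not in lookup.index:
            raise ValueError(f"missing heritability summary for breed {b}")
        out.loc[b, b] = _fmt(lookup.loc[key, "mean"], lookup.loc[key, "ts_se"], precision)
        for c in breeds[i + 1 :]:
            key = None
            for cand in (f"r_g[{b},{c}]", f"r_g[{c},{b}]"):
                if cand in lookup.index:
                    key = cand
                    break
            if key is None:
                raise ValueError(f"missing genetic correlation for pair ({b}, {c})")
            out.loc[b, c] = _fmt(lookup.loc[key, "mean"], lookup.loc[key, "ts_se"], precision)
    return out


def render_validation_grid(reports: pd.DataFrame, precision: int = 2) -> pd.DataFrame:
    """Validation grid: breeds as rows, statistic x strategy columns.

    ``reports`` holds one row per breed x strategy with columns breed,
    strategy, predictive_ability, beta_wp, rho_wp. Missing cells are
    emitted as NA with a warning rather than dropped.
    """
    stats = ["predictive_ability", "beta_wp", "rho_wp"]
    strategies = list(dict.fromkeys(reports["strategy"]))
    breeds = list(dict.fromkeys(reports["breed"]))
    cols = [f"{s}:{st}" for s in stats for st in strategies]
    out = pd.DataFrame(index=breeds, columns=cols, dtype=object)
    keyed = reports.set_index(["breed", "strategy"])
    for b in breeds:
        for st in strategies:
            for s in stats:
                col = f"{s}:{st}"
                try:
                    val = keyed.loc[(b, st), s]
                except KeyError:
                    val = np.nan
                if isinstance(val, float) and np.isnan(val):
                    warnings.warn(f"validation cell ({b}, {st}, {s}) undefined; emitting NA")
                    out.loc[b, col] = "NA"
                else:
                    out.loc[b, col] = _fmt(val, None, precision)
    return out


def render_heatmap_long(per_chromosome: dict) -> pd.DataFrame:
    """Long-format per-chromosome values, e.g. {('A','B'): frame} with
    columns chrom and R, flattened to (pair, chrom, value) rows."""
    rows = []
    for key, frame in per_chromosome.items():
        label = key if isinstance(key, str) else "/".join(map(str, key))
        for _, r in frame.iterrows():
            value_col = [c for c in frame.columns if c not in ("chrom", "n_pairs")][0]
            rows.append({"pair": label, "chrom": r["chrom"], "value": r[value_col]})
    return pd.DataFrame(rows)
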