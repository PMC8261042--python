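"""Sample- and marker-level genotype quality control.

Filters follow standard SNP-array practice for beef-cattle panels: samples
are dropped for low call rate, outlying heterozygosity (proportion of
heterozygous genotypes among non-missing autosomal markers, beyond a SD
window around the panel mean) and exact duplication; markers are dropped
for non-autosomal placement, low call rate, low MAF, strong Hardy-Weinberg
deviation, and same-position / highly correlated redundancy (keeping the
highest-MAF member).

Dosages are 0/1/2 counts of the A1 allele with ``-1`` (or NaN) as the
missing sentinel, samples in rows and markers in columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QCThresholds", "sample_qc", "snp_qc", "hwe_test", "dedupe_snps"]

MISSING = -1


@dataclass
class QCThresholds:
    sample_call_rate_min: float = 0.90
    het_sd_window: float = 3.0
    snp_call_rate_min: float = 0.98
    maf_min: float = 0.03
    hwe_p_floor: float = 1e-7
    duplicate_r_max: float = 0.98

    def __post_init__(self):
        for name in ("sample_call_rate_min", "snp_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.het_sd_window <= 0:
            raise ValueError("het_sd_window must be > 0")


def _mask(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages, dtype=float)
    d = np.where(d == MISSING, np.nan, d)
    return d


def sample_qc(
    dosages: np.ndarray,
    sample_ids: list[str],
    thresholds: QCThresholds | None = None,
    autosomal: np.ndarray | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply per-sample filters; returns retained ids and a per-rule report.

    Rules in order: call rate, heterozygosity window, exact duplicates
    (identical non-missing dosage vectors; the first id in input order is
    kept). Each removed sample is attributed to the first failing rule.
    """
    thr = thresholds or QCThresholds()
    if len(sample_ids) == 0:
        raise ValueError("panel has no samples")
    d = _mask(dosages)
    if autosomal is not None:
        d_auto = d[:, np.asarray(autosomal, dtype=bool)]
    else:
        d_auto = d
    nonmiss = ~np.isnan(d)
    call_rate = nonmiss.mean(axis=1)
    fail_cr = call_rate < thr.sample_call_rate_min

    with np.errstate(invalid="ignore"):
        het = np.nanmean(d_auto == 1, axis=1)
    het = np.where(np.isnan(het), 0.0, het)
    mean, sd = het.mean(), het.std(ddof=0)
    fail_het = np.abs(het - mean) > thr.het_sd_window * sd if sd > 0 else np.zeros(len(het), bool)

    # exact duplicates: identical dosage vectors including missingness pattern
    fail_dup = np.zeros(len(sample_ids), bool)
    seen: dict[bytes, int] = {}
    raw = np.where(np.isnan(d), MISSING, d).astype(np.int8)
    for i in range(raw.shape[0]):
        key = raw[i].tobytes()
        if key in seen:
            fail_dup[i] = True
        else:
            seen[key] = i

    removed_by = np.full(len(sample_ids), "", dtype=object)
    removed_by[fail_dup] = "duplicate"
    removed_by[fail_het] = "heterozygosity"
    removed_by[fail_cr] = "call_rate"  # first rule wins
    keep = removed_by == ""
    retained = [sid for sid, k in zip(sample_ids, keep) if k]
    report = pd.DataFrame(
        {
            "rule": ["call_rate", "heterozygosity", "duplicate", "retained"],
            "n": [
                int(fail_cr.sum()),
                int((fail_het & ~fail_cr).sum()),
                int((fail_dup & ~fail_cr & ~fail_het).sum()),
                len(retained),
            ],
        }
    )
    if not retained:
        raise ValueError("sample QC removed every sample")
    return retained, report


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg equilibrium.

    Expected genotype frequencies come from the sample allele frequency.
    Monomorphic input returns p = 1 by convention (nothing segregates).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def snp_qc(
    dosages: np.ndarray,
    marker_map: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    n_autosomes: int = 29,
) -> tuple[list[str], pd.DataFrame]:
    """Apply per-marker filters; returns retained marker ids and a report.

    ``marker_map`` needs columns ``snp``, ``chrom``, ``pos`` aligned with the
    dosage columns. Rules in fixed order (a marker counts against the first
    one it fails): autosome, call rate, MAF, HWE. Cattle autosomes are
    chromosomes 1..``n_autosomes``.
    """
    thr = thresholds or QCThresholds()
    d = _mask(dosages)
    chrom = pd.to_numeric(marker_map["chrom"], errors="coerce").to_numpy()
    autosomal = (chrom >= 1) & (chrom <= n_autosomes)

    nonmiss = ~np.isnan(d)
    call_rate = nonmiss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1 - p)

    hwe_p = np.ones(d.shape[1])
    for j in range(d.shape[1]):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size:
            hwe_p[j] = hwe_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))

    fail_auto = ~autosomal
    fail_cr = call_rate <= thr.snp_call_rate_min
    fail_maf = maf <= thr.maf_min
    fail_hwe = hwe_p <= thr.hwe_p_floor

    removed_by = np.full(d.shape[1], "", dtype=object)
    removed_by[fail_hwe] = "hwe"
    removed_by[fail_maf] = "maf"
    removed_by[fail_cr] = "call_rate"
    removed_by[fail_auto] = "autosome"
    keep = removed_by == ""
    snp_ids = marker_map["snp"].tolist()
    retained = [s for s, k in zip(snp_ids, keep) if k]
    report = pd.DataFrame(
        {
            "rule": ["autosome", "call_rate", "maf", "hwe", "retained"],
            "n": [
                int(fail_auto.sum()),
                int((fail_cr & ~fail_auto).sum()),
                int((fail_maf & ~fail_cr & ~fail_auto).sum()),
                int((fail_hwe & ~fail_maf & ~fail_cr & ~fail_auto).sum()),
                len(retained),
            ],
        }
    )
    return retained, report


def dedupe_snps(
    dosages: np.ndarray,
    marker_map: pd.DataFrame,
    r_max: float = 0.98,
    window: int = 1,
) -> list[str]:
    """Drop redundant markers, keeping the highest-MAF member of each clash.

    Markers at the identical (chrom, pos), and adjacent pairs within
    ``window`` map positions whose dosage correlation exceeds ``r_max`` in
    absolute value, are reduced to the single highest-MAF member (ties by
    lexicographic marker id). Markers must be sorted by (chrom, pos).
    """
    d = _mask(dosages)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    p = np.where(np.isnan(p), 0.0, p)
    maf = np.minimum(p, 1 - p)
    snp_ids = marker_map["snp"].tolist()
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    m = d.shape[1]
    drop = np.zeros(m, bool)

    def prefer(i: int, j: int) -> int:
        """Return the index to DROP from a clashing pair."""
        if maf[i] != maf[j]:
            return j if maf[i] > maf[j] else i
        return j if snp_ids[i] < snp_ids[j] else i

    for i in range(m):
        if drop[i]:
            continue
        for j in range(i + 1, min(i + window + 1, m)):
            if drop[j] or chrom[i] != chrom[j]:
                continue
            clash = pos[i] == pos[j]
            if not clash:
                xi, xj = d[:, i], d[:, j]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                if ok.sum() > 1 and np.std(xi[ok]) > 0 and np.std(xj[ok]) > 0:
                    r = np.corrcoef(xi[ok], xj[ok])[0, 1]
                    clash = abs(r) > r_max
            if clash:
                drop[prefer(i, j)] = True
    return [s for s, dr in zip(snp_ids, drop) if not dr]
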