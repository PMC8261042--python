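"""Population-genomic diagnostics: adjacent-marker LD, cross-breed
persistence of phase, allele-frequency correlations and PCA of G.

The LD statistic between adjacent markers is the haplotype-frequency
correlation

    r = (p_AB p_ab - p_Ab p_aB) / sqrt(p_A p_a p_B p_b),

squared to give r². The sign of r is defined with respect to the
dosage-counted allele at each marker, so flipping the counted allele at a
marker flips the sign of every r involving it. Persistence of phase between
breeds A and B is the Pearson correlation, across a common set of adjacent
pairs, of the signed r values — high persistence means marker effects
estimated in one breed transfer to the other.

Haplotype frequencies come from phased haplotypes when available, or from
a two-locus EM on unphased genotypes otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "adjacent_ld",
    "phase_persistence",
    "allele_freq_correlation",
    "grm_pca",
    "PhasePersistence",
]


@dataclass
class PhasePersistence:
    breed_a: str
    breed_b: str
    overall: float
    per_chromosome: pd.DataFrame  # columns: chrom, R, n_pairs
    n_pairs: int


def _r_from_hapfreq(pAB, pA, pB):
    """Signed r and r² from the AB-haplotype and marginal allele frequencies."""
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = D / np.sqrt(denom)
    return r


def _em_hapfreq(g1: np.ndarray, g2: np.ndarray, max_iter: int = 50, tol: float = 1e-8):
    """Two-locus EM estimate of the AB haplotype frequency from unphased
    dosages (vectorised over pairs: g1, g2 are n_samples x n_pairs)."""
    n = g1.shape[0]
    pA = g1.mean(axis=0) / 2.0
    pB = g2.mean(axis=0) / 2.0
    pAB = pA * pB  # start at linkage equilibrium
    # only the double-het cell is phase-ambiguous
    dh = (g1 == 1) & (g2 == 1)
    n_dh = dh.sum(axis=0)
    # definite AB counts per pair from the other 8 genotype cells:
    # each sample carries 2 haplotypes; count AB among unambiguous ones
    c_AB = ((g1 == 2) & (g2 == 2)) * 2 + ((g1 == 2) & (g2 == 1)) + ((g1 == 1) & (g2 == 2))
    n_AB_fixed = c_AB.sum(axis=0).astype(float)
    c_Ab = ((g1 == 2) & (g2 == 0)) * 2 + ((g1 == 2) & (g2 == 1)) + ((g1 == 1) & (g2 == 0))
    n_Ab_fixed = c_Ab.sum(axis=0).astype(float)
    c_aB = ((g1 == 0) & (g2 == 2)) * 2 + ((g1 == 0) & (g2 == 1)) + ((g1 == 1) & (g2 == 2))
    n_aB_fixed = c_aB.sum(axis=0).astype(float)
    c_ab = ((g1 == 0) & (g2 == 0)) * 2 + ((g1 == 0) & (g2 == 1)) + ((g1 == 1) & (g2 == 0))
    n_ab_fixed = c_ab.sum(axis=0).astype(float)

    for _ in range(max_iter):
        pAb = np.clip(pA - pAB, 1e-12, None)
        paB = np.clip(pB - pAB, 1e-12, None)
        pab = np.clip(1 - pA - pB + pAB, 1e-12, None)
        pAB_c = np.clip(pAB, 1e-12, None)
        # P(coupling | double het): AB/ab vs Ab/aB; each coupling
        # double-het contributes one AB haplotype
        w = pAB_c * pab / (pAB_c * pab + pAb * paB)
        new = (n_AB_fixed + n_dh * w) / (2 * n)
        if np.all(np.abs(new - pAB) < tol):
            pAB = new
            break
        pAB = new
    return pAB, pA, pB


def adjacent_ld(
    marker_map: pd.DataFrame,
    haplotypes: np.ndarray | None = None,
    dosages: np.ndarray | None = None,
) -> pd.DataFrame:
    """Signed r and r² for each within-chromosome adjacent marker pair.

    ``marker_map`` must be sorted by (chrom, pos) and aligned with the
    columns of ``haplotypes`` (2N x m phased allele indicators) or
    ``dosages`` (N x m unphased 0/1/2); phase is used when given.
    Monomorphic members flag the pair as undefined.

    Returns a DataFrame with chrom, i, j, snp_i, snp_j, r, r2, p_A, p_B,
    p_AB and a ``defined`` flag.
    """
    chrom = marker_map["chrom"].to_numpy()
    m = len(chrom)
    if m < 2:
        raise ValueError("need at least two markers")
    left = np.arange(m - 1)
    keep = chrom[left] == chrom[left + 1]
    i_idx, j_idx = left[keep], left[keep] + 1

    if haplotypes is not None:
        H = np.asarray(haplotypes, dtype=float)
        pA = H[:, i_idx].mean(axis=0)
        pB = H[:, j_idx].mean(axis=0)
        pAB = (H[:, i_idx] * H[:, j_idx]).mean(axis=0)
    elif dosages is not None:
        g = np.asarray(dosages)
        if g.shape[0] < 2:
            raise ValueError("need >= 2 samples for EM haplotype estimation")
        pAB, pA, pB = _em_hapfreq(g[:, i_idx], g[:, j_idx])
    else:
        raise ValueError("provide haplotypes or dosages")

    defined = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    r = np.where(defined, _r_from_hapfreq(np.clip(pAB, 0, 1), pA, pB), np.nan)
    out = pd.DataFrame(
        {
            "chrom": chrom[i_idx],
            "i": i_idx,
            "j": j_idx,
            "snp_i": marker_map["snp"].to_numpy()[i_idx],
            "snp_j": marker_map["snp"].to_numpy()[j_idx],
            "p_A": pA,
            "p_B": pB,
            "p_AB": pAB,
            "r": r,
            "r2": r * r,
            "defined": defined,
        }
    )
    return out


def phase_persistence(ld_a: pd.DataFrame, ld_b: pd.DataFrame, breed_a: str = "A", breed_b: str = "B") -> PhasePersistence:
    """Correlation of signed adjacent-marker r between two breeds.

    Both LD tables must come from :func:`adjacent_ld` on the identical
    marker list with identical allele coding. Pairs undefined in either
    breed are excluded; the overall value pools all shared pairs, and
    per-chromosome values are reported alongside.
    """
    if len(ld_a) != len(ld_b) or not np.array_equal(ld_a["snp_i"].to_numpy(), ld_b["snp_i"].to_numpy()):
        raise ValueError("LD tables are not on an identical marker list")
    ok = (ld_a["defined"] & ld_b["defined"]).to_numpy()
    ra = ld_a["r"].to_numpy()[ok]
    rb = ld_b["r"].to_numpy()[ok]
    chrom = ld_a["chrom"].to_numpy()[ok]

    def _corr(x, y):
        # constant vectors (ptp exactly 0) leave the correlation undefined
        if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
            return np.nan
        return float(np.corrcoef(x, y)[0, 1])

    overall = _corr(ra, rb)
    rows = []
    for c in pd.unique(chrom):
        sel = chrom == c
        rows.append({"chrom": c, "R": _corr(ra[sel], rb[sel]), "n_pairs": int(sel.sum())})
    return PhasePersistence(breed_a, breed_b, overall, pd.DataFrame(rows), int(ok.sum()))


def allele_freq_correlation(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Pearson correlation of allele frequencies across a shared marker list."""
    fa = np.asarray(freq_a, dtype=float)
    fb = np.asarray(freq_b, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("frequency vectors differ in length")
    if len(fa) < 2 or np.ptp(fa) == 0 or np.ptp(fb) == 0:
        return float("nan")
    return float(np.corrcoef(fa, fb)[0, 1])


def grm_pca(G: np.ndarray, n_components: int = 10, sym_tol: float = 1e-8):
    """Principal components of a genomic relationship matrix.

    Eigendecomposition with eigenvalues sorted descending; component scores
    are eigenvectors scaled by sqrt(eigenvalue) (clipped at zero), variance
    fractions are eigenvalue / trace. Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1] or G.shape[0] < 2:
        raise ValueError("G must be square with dimension >= 2")
    if np.max(np.abs(G - G.T)) > sym_tol * max(1.0, np.max(np.abs(G))):
        raise ValueError("G is not symmetric within tolerance")
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    vecs = vecs[:, :k]
    for c in range(k):
        jmax = np.argmax(np.abs(vecs[:, c]))
        if vecs[jmax, c] < 0:
            vecs[:, c] = -vecs[:, c]
    scores = vecs * np.sqrt(np.clip(vals[:k], 0, None))
    frac = vals[:k] / np.trace(G)
    return scores, frac
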