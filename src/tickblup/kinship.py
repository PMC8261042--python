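"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix A (tabular method, with
inbreeding), its sparse inverse via Henderson's rules with inbreeding
coefficients from the Meuwissen-Luo recursion, the VanRaden method-1
genomic relationship matrix G, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 (w G + (1-w) A22)^-1 - A22^-1],

with the genomic weight w defaulting to 0.95 (so 5% of A22 is blended into
G to guarantee invertibility and account for polygenic effects not captured
by markers).

Pedigrees are integer-coded: arrays ``sire`` and ``dam`` hold the row index
of each animal's parents, ``-1`` for unknown, and must be topologically
ordered (parents before offspring) — `tickblup.pipeline_io.load_pedigree`
produces this layout.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RelationshipMatrix",
    "build_A",
    "build_A_inverse",
    "inbreeding_coefficients",
    "build_G",
    "build_H_inverse",
]

UNKNOWN = -1


@dataclass
class RelationshipMatrix:
    """A relationship matrix with its id ordering and provenance tag."""

    values: np.ndarray | sp.spmatrix
    ids: list
    flavor: str  # A | A_inv | A22 | G | G_blend | H_inv
    meta: dict = field(default_factory=dict)

    def toarray(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


def _check_ordered(sire: np.ndarray, dam: np.ndarray) -> None:
    n = len(sire)
    idx = np.arange(n)
    if np.any(sire >= idx) or np.any(dam >= idx):
        raise ValueError("pedigree is not topologically ordered (parent index >= animal index)")


def build_A(
    sire: np.ndarray,
    dam: np.ndarray,
    ids: list | None = None,
    subset: list | None = None,
) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method, with inbreeding.

    ``subset`` (a list of ids, requiring ``ids``) extracts the corresponding
    rows/columns — used to form A22 for the genotyped animals.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_ordered(sire, dam)
    n = len(sire)
    ids = list(ids) if ids is not None else list(range(n))
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        if s != UNKNOWN and d != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    if subset is not None:
        lookup = {a: k for k, a in enumerate(ids)}
        missing = [a for a in subset if a not in lookup]
        if missing:
            raise ValueError(f"subset ids absent from pedigree: {missing[:10]}")
        take = np.array([lookup[a] for a in subset])
        return RelationshipMatrix(A[np.ix_(take, take)], list(subset), "A22")
    return RelationshipMatrix(A, ids, "A")


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo L-vector recursion.

    Computes F_i = A_ii - 1 one animal at a time from the Cholesky
    decomposition A = L D L', touching only each animal's ancestors, so no
    dense A is formed.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _check_ordered(sire, dam)
    n = len(sire)
    F = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else -1.0  # convention: unknown parent F = -1 in d_ii
        Fd = F[d] if d != UNKNOWN else -1.0
        D[i] = 0.5 - 0.25 * (Fs + Fd)
        if s == UNKNOWN and d == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate the L-row of animal i over its actual ancestors,
        # popped youngest-first so each coefficient is final when processed
        aii = 0.0
        L = {i: 1.0}
        heap = [-i]
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def build_A_inverse(sire: np.ndarray, dam: np.ndarray, ids: list | None = None) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Mendelian sampling variances d_i use parental inbreeding from
    :func:`inbreeding_coefficients`, so the result equals the dense inverse
    of :func:`build_A` exactly (up to floating point).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    n = len(sire)
    ids = list(ids) if ids is not None else list(range(n))
    F = inbreeding_coefficients(sire, dam)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else -1.0
        Fd = F[d] if d != UNKNOWN else -1.0
        di = 0.5 - 0.25 * (Fs + Fd)
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in (s, d):
            if p != UNKNOWN:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            if p != UNKNOWN:
                for q in (s, d):
                    if q != UNKNOWN:
                        add(p, q, 0.25 * alpha)
    Ainv = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    return RelationshipMatrix(Ainv, ids, "A_inv")


def build_G(
    dosages: np.ndarray,
    ids: list,
    breed: np.ndarray | None = None,
    freq_policy: str = "mean-of-breeds",
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G = Z Z' / (2 sum_k p_k (1 - p_k)) with Z = M - 2p, where M is the
    samples x markers dosage matrix (0/1/2, no missing values — mean-impute
    upstream) and p the current allele frequencies.

    ``freq_policy``:
      * ``"mean-of-breeds"`` — p_k is the unweighted mean of per-breed
        frequencies (frequencies averaged across breeds); requires ``breed``
        labels, falls back to pooled when absent.
      * ``"pooled"`` — p_k from all samples pooled.
    """
    M = np.asarray(dosages, dtype=float)
    if np.isnan(M).any() or (M < 0).any():
        raise ValueError("missing dosages: mean-impute before building G")
    if freq_policy == "mean-of-breeds" and breed is not None:
        breed = np.asarray(breed)
        freqs = [M[breed == b].mean(axis=0) / 2.0 for b in np.unique(breed)]
        p = np.mean(freqs, axis=0)
    elif freq_policy in ("pooled", "mean-of-breeds"):
        p = M.mean(axis=0) / 2.0
    else:
        raise ValueError(f"unknown freq_policy {freq_policy!r}")
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers fixed: zero VanRaden denominator")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, list(ids), "G", meta={"freqs": p, "denominator": denom, "freq_policy": freq_policy})


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    G: RelationshipMatrix,
    blend: tuple[float, float] = (0.95, 0.05),
) -> RelationshipMatrix:
    """Single-step H^-1: A^-1 plus the genotyped-block correction.

    The correction on the genotyped block is (w G + v A22)^-1 - A22^-1 with
    (w, v) = ``blend``. ``A22`` and ``G`` must share an identical id
    ordering, a subset of ``A_inv``'s ids.
    """
    if G is None or len(G.ids) == 0:  # no genotyped animals: H^-1 = A^-1
        return RelationshipMatrix(
            sp.csr_matrix(A_inv.values), list(A_inv.ids), "H_inv",
            meta={"genotyped_ids": [], "blend": blend,
                  "genotyped_index": np.zeros(0, dtype=np.int64),
                  "sparse_part": sp.csr_matrix(A_inv.values),
                  "correction": np.zeros((0, 0))},
        )
    if list(A22.ids) != list(G.ids):
        raise ValueError("A22 and G id orderings differ")
    lookup = {a: k for k, a in enumerate(A_inv.ids)}
    missing = [a for a in G.ids if a not in lookup]
    if missing:
        raise ValueError(f"genotyped ids absent from pedigree: {missing[:10]}")
    idx = np.array([lookup[a] for a in G.ids], dtype=np.int64)

    w, v = blend
    Gb = w * G.toarray() + v * A22.toarray()
    cond = np.linalg.cond(Gb)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(f"blended matrix near-singular (condition number {cond:.3e})")
    corr = np.linalg.inv(Gb) - np.linalg.inv(A22.toarray()) if len(idx) else np.zeros((0, 0))

    H = sp.lil_matrix(A_inv.values.shape)
    H[np.ix_(idx, idx)] = corr
    Hinv = (sp.csr_matrix(A_inv.values) + H.tocsr()).tocsr()
    # the split form (sparse A^-1 + dense genotyped-block correction) lets
    # downstream samplers handle the dense block with contiguous arithmetic
    return RelationshipMatrix(
        Hinv, list(A_inv.ids), "H_inv",
        meta={
            "genotyped_ids": list(G.ids),
            "blend": blend,
            "genotyped_index": idx,
            "sparse_part": sp.csr_matrix(A_inv.values),
            "correction": corr,
        },
    )
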