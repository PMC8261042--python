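"""Shared in-memory containers: genotype panel and pedigree."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypePanel:
    """Marker map plus per-sample genotypes for one or more breed groups.

    ``marker_map`` has columns ``snp``, ``chrom``, ``pos`` (and optionally
    ``cm``), sorted by (chrom, pos). ``haplotypes`` (2N x m, rows 2i and
    2i+1 belong to sample i) is present for phased panels; ``dosages``
    (N x m, 0/1/2 with -1 missing) is always available, derived from the
    haplotypes when phased.
    """

    marker_map: pd.DataFrame
    sample_ids: list
    breed: np.ndarray  # per-sample breed label
    haplotypes: np.ndarray | None = None
    _dosages: np.ndarray | None = None

    def __post_init__(self):
        if self.haplotypes is None and self._dosages is None:
            raise ValueError("panel needs haplotypes or dosages")
        if self.haplotypes is not None and self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows != 2 x samples")

    @property
    def dosages(self) -> np.ndarray:
        if self._dosages is not None:
            return self._dosages
        h = self.haplotypes
        return (h[0::2] + h[1::2]).astype(np.int8)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    def allele_frequencies(self, breed: str | None = None) -> np.ndarray:
        d = self.dosages.astype(float)
        d = np.where(d < 0, np.nan, d)
        if breed is not None:
            d = d[np.asarray(self.breed) == breed]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def subset(self, sample_ids=None, snp_ids=None) -> "GenotypePanel":
        sidx = np.arange(len(self.sample_ids))
        if sample_ids is not None:
            lookup = {s: k for k, s in enumerate(self.sample_ids)}
            sidx = np.array([lookup[s] for s in sample_ids])
        midx = np.arange(self.n_markers)
        if snp_ids is not None:
            mlookup = {s: k for k, s in enumerate(self.marker_map["snp"])}
            midx = np.array([mlookup[s] for s in snp_ids])
        hap = None
        if self.haplotypes is not None:
            rows = np.stack([2 * sidx, 2 * sidx + 1], axis=1).ravel()
            hap = self.haplotypes[np.ix_(rows, midx)]
        dos = None if self._dosages is None else self._dosages[np.ix_(sidx, midx)]
        return GenotypePanel(
            marker_map=self.marker_map.iloc[midx].reset_index(drop=True),
            sample_ids=[self.sample_ids[k] for k in sidx],
            breed=np.asarray(self.breed)[sidx],
            haplotypes=hap,
            _dosages=dos,
        )


@dataclass
class Pedigree:
    """Topologically ordered pedigree with integer-coded parent links.

    ``table`` has one row per animal: id, sire, dam (id strings, '0' for
    unknown), birthdate (ISO-8601), breed, and — for simulated pedigrees —
    zebu_fraction and het_coef covariates. ``sire_idx``/``dam_idx`` hold
    row indices (-1 unknown) with parents always before offspring.
    """

    table: pd.DataFrame
    sire_idx: np.ndarray
    dam_idx: np.ndarray

    def __post_init__(self):
        n = len(self.table)
        idx = np.arange(n)
        if np.any(self.sire_idx >= idx) or np.any(self.dam_idx >= idx):
            raise ValueError("pedigree not topologically ordered")

    @property
    def ids(self) -> list:
        return self.table["id"].tolist()

    def __len__(self) -> int:
        return len(self.table)
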