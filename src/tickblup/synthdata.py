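"""Forward simulation of multi-breed cattle populations.

Generates the statistical structure the tick-resistance evaluation
assumes, without attempting tick biology:

* **Founder haplotypes.** A single ancestral haplotype pool with
  autocorrelated alleles (Gaussian-copula AR(1) along each chromosome)
  provides baseline LD. Each breed drifts from it through a
  Balding-Nichols-style bottleneck: a breed pool of ~1/F haplotypes
  resampled from the ancestral pool, so the expected fixation index
  between two breeds at divergence F is ~F. Founder haplotypes are
  recombinant mosaics of the breed pool; breeds at divergence 0 share the
  ancestral pool itself, giving near-perfect cross-breed persistence of
  phase, while panels simulated from independent ancestral pools share
  none.
* **Pedigree and crosses.** Discrete random-mating generations within each
  breed, plus composite breeds formed by a dyadic crossing tree that hits
  the requested admixture fractions (e.g. a 3/8-zebu composite). Meioses
  recombine with Haldane map probabilities on a uniform 1 cM map unless
  the marker map carries a ``cm`` column. Every animal carries its
  pedigree-expected zebu fraction and expected-heterozygosity coefficient.
* **Breeding values.** A random QTL subset of the markers receives
  per-trait effects drawn from a multivariate normal with the target
  genetic correlation structure; dosage-weighted sums are rescaled per
  trait so realized within-breed genetic variances match the trait spec.
* **Phenotypes.** Records are contemporary-group effects + covariate terms
  (zebu fraction, heterozygosity, age linear and quadratic) + breeding
  value + permanent-environment deviation (repeated-record breeds) +
  residual, emitted on the latent log-count scale, binned to a 0-5 score,
  or averaged over records, per breed.

All randomness flows from one seed: ``numpy.random.SeedSequence(seed)``
spawns one child stream per stage (founders, pedigree, breeding values,
phenotypes), so module-level reruns are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import GenotypePanel, Pedigree
from .pheno import bin_tick_score

__all__ = [
    "BreedSpec",
    "TraitSpec",
    "SimOutput",
    "simulate_founder_haplotypes",
    "simulate_pedigree_and_crosses",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_study",
]


@dataclass
class BreedSpec:
    """One breed group: pure founder population or admixed composite."""

    label: str
    role: str = "founder-taurine"  # founder-taurine | founder-indicine | composite
    parents: dict = field(default_factory=dict)  # composite: {breed label: fraction}
    divergence: float = 0.1  # Fst-like drift from the ancestral pool
    n_founders: int = 200
    n_descendant_generations: int = 1

    def __post_init__(self):
        if self.role not in ("founder-taurine", "founder-indicine", "composite"):
            raise ValueError(f"unknown role {self.role!r}")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        if self.role == "composite":
            total = sum(self.parents.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError("composite admixture fractions must sum to 1")


@dataclass
class TraitSpec:
    """Breed-as-trait layout: one tick-infestation trait per breed.

    ``breeds`` fixes the trait order; all per-breed dicts are keyed by
    breed label. ``genetic_correlations`` is the t x t matrix in that
    order (symmetric, unit diagonal, PSD). ``repeatability`` entries imply
    repeated records with a permanent-environment variance; breeds absent
    from it get single records. ``phen_var`` is the phenotypic variance of
    the latent (log-count scale) value.
    """

    breeds: list
    heritability: dict
    genetic_correlations: np.ndarray
    repeatability: dict = field(default_factory=dict)
    records_per_animal: dict = field(default_factory=dict)  # breed -> (min, max)
    mode: dict = field(default_factory=dict)  # breed -> log-count | score | averaged-count
    phen_var: dict = field(default_factory=dict)
    n_contemporary_groups: dict = field(default_factory=dict)
    cg_sd: float = 0.5
    # latent-scale covariate coefficients (free parameters of the generator)
    beta_zebu: float = -0.3
    beta_het: float = -0.1
    beta_age: float = 0.1
    beta_age2: float = -0.05

    def __post_init__(self):
        C = np.asarray(self.genetic_correlations, dtype=float)
        t = len(self.breeds)
        if C.shape != (t, t) or np.max(np.abs(C - C.T)) > 1e-10 or np.max(np.abs(np.diag(C) - 1)) > 1e-10:
            raise ValueError("genetic correlation matrix must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(C)) < -1e-8:
            raise ValueError("genetic correlation matrix must be positive semi-definite")
        self.genetic_correlations = C
        for b, h2 in self.heritability.items():
            if not 0 <= h2 <= 1:
                raise ValueError(f"heritability of {b} outside [0, 1]")
            rep = self.repeatability.get(b)
            if rep is not None and not h2 <= rep <= 1:
                raise ValueError(f"repeatability of {b} must lie in [h2, 1]")

    @property
    def t(self) -> int:
        return len(self.breeds)

    def genetic_covariance(self) -> np.ndarray:
        sd = np.array(
            [np.sqrt(self.heritability[b] * self.phen_var.get(b, 1.0)) for b in self.breeds]
        )
        return self.genetic_correlations * np.outer(sd, sd)


@dataclass
class SimOutput:
    """Complete bookkeeping of one simulated study."""

    panel: GenotypePanel
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    true_bv: pd.DataFrame  # animals x breeds (trait order = TraitSpec.breeds)
    true_components: dict  # Sigma_u, sigma2_pe, sigma2_e
    seed: int


# ---------------------------------------------------------------------------
# founder haplotypes
# ---------------------------------------------------------------------------

def _uniform_map(n_markers: int, n_chrom: int) -> pd.DataFrame:
    """Uniform 1 cM marker spacing over ``n_chrom`` equally sized chromosomes."""
    per = np.full(n_chrom, n_markers // n_chrom)
    per[: n_markers % n_chrom] += 1
    rows = []
    for c, k in enumerate(per, start=1):
        for j in range(k):
            rows.append((f"snp{c}_{j}", c, (j + 1) * 1_000_000, float(j)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "cm"])


def _copula_pool(p: np.ndarray, chrom: np.ndarray, size: int, phi: float, rng) -> np.ndarray:
    """Ancestral haplotypes with AR(1)-copula LD along each chromosome."""
    m = len(p)
    z = np.empty((size, m))
    start = np.r_[True, chrom[1:] != chrom[:-1]]
    innov = rng.standard_normal((size, m))
    z[:, 0] = innov[:, 0]
    for j in range(1, m):
        if start[j]:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = phi * z[:, j - 1] + np.sqrt(1 - phi * phi) * innov[:, j]
    return (z < norm.ppf(p)[None, :]).astype(np.uint8)


def _mosaic(pool: np.ndarray, n_hap: int, switch: float, chrom: np.ndarray, rng) -> np.ndarray:
    """Recombinant mosaics of pool haplotypes (segment switch prob per interval)."""
    K, m = pool.shape
    out = np.empty((n_hap, m), dtype=np.uint8)
    state = rng.integers(0, K, size=n_hap)
    new = rng.integers(0, K, size=(n_hap, m))
    do_switch = rng.random((n_hap, m)) < switch
    start = np.r_[True, chrom[1:] != chrom[:-1]]
    for j in range(m):
        if start[j]:
            state = new[:, j]
        else:
            state = np.where(do_switch[:, j], new[:, j], state)
        out[:, j] = pool[state, j]
    return out


def simulate_founder_haplotypes(
    n_markers: int,
    breed_specs: list[BreedSpec],
    seed: int,
    n_chrom: int = 5,
    ancestral_pool_size: int = 60,
    hap_corr: float = 0.8,
    segment_switch: float = 0.05,
    marker_map: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Phased founder haplotypes for every (non-composite) breed group.

    All breeds in one call share one ancestral pool; the per-breed
    ``divergence`` F applies a bottleneck of ~1/F pool haplotypes (F = 0
    keeps the full shared pool: no drift).
    """
    if n_markers < 2:
        raise ValueError("n_markers must be >= 2")
    founder_specs = [b for b in breed_specs if b.role != "composite"]
    if not founder_specs:
        raise ValueError("need at least one founder breed")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    mm = marker_map if marker_map is not None else _uniform_map(n_markers, n_chrom)
    mm = mm.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    chrom = mm["chrom"].to_numpy()
    # keep frequencies off the boundary so nothing is fixed by construction
    p = rng.uniform(0.1, 0.9, size=len(mm))
    anc = _copula_pool(p, chrom, ancestral_pool_size, hap_corr, rng)

    haps, ids, breeds = [], [], []
    for spec in founder_specs:
        if spec.divergence > 0:
            k = max(2, round(1.0 / spec.divergence))
            pool = anc[rng.integers(0, ancestral_pool_size, size=k)]
        else:
            pool = anc
        h = _mosaic(pool, 2 * spec.n_founders, segment_switch, chrom, rng)
        haps.append(h)
        ids += [f"{spec.label}_F0_{i}" for i in range(spec.n_founders)]
        breeds += [spec.label] * spec.n_founders
    return GenotypePanel(
        marker_map=mm,
        sample_ids=ids,
        breed=np.array(breeds),
        haplotypes=np.vstack(haps),
    )


# ---------------------------------------------------------------------------
# pedigree, crosses, meiosis
# ---------------------------------------------------------------------------

def _recomb_prob(mm: pd.DataFrame) -> np.ndarray:
    """Per-interval recombination fraction (Haldane) from the cM map."""
    cm = mm["cm"].to_numpy() if "cm" in mm else np.arange(len(mm), dtype=float)
    chrom = mm["chrom"].to_numpy()
    d = np.diff(cm) / 100.0
    c = 0.5 * (1.0 - np.exp(-2.0 * np.clip(d, 0, None)))
    c = np.r_[0.5, c]
    c[np.r_[True, chrom[1:] != chrom[:-1]]] = 0.5  # free recombination across chromosomes
    return c


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, c: np.ndarray, rng) -> np.ndarray:
    """Gametes for a batch of meioses; hap_a/b are (n x m) parental haplotypes."""
    n, m = hap_a.shape
    switch = rng.random((n, m)) < c[None, :]
    phase = np.cumsum(switch, axis=1) % 2
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def _dyadic_split(fracs: dict, tol: float = 1e-9) -> tuple[dict, dict]:
    """Split admixture fractions into two halves each summing to 1/2."""
    items = sorted(fracs.items(), key=lambda kv: -kv[1])
    left, right = {}, {}
    need_left = 0.5
    for label, f in items:
        take = min(f, need_left)
        if take > tol:
            left[label] = take * 2
            need_left -= take
        if f - take > tol:
            right[label] = (f - take) * 2
    if abs(need_left) > tol:
        raise ValueError(f"admixture fractions {fracs} are not dyadic")
    return left, right


class _Cohorts:
    """Bookkeeping of animals, haplotypes and breed-fraction vectors."""

    def __init__(self, panel: GenotypePanel, recomb: np.ndarray, rng):
        self.mm = panel.marker_map
        self.recomb = recomb
        self.rng = rng
        self.hap: list[np.ndarray] = [panel.haplotypes[2 * i : 2 * i + 2] for i in range(len(panel.sample_ids))]
        self.rows: list[dict] = []
        self.fractions: list[dict] = []
        self.sire_idx: list[int] = []
        self.dam_idx: list[int] = []
        self.by_cohort: dict[tuple, list[int]] = {}
        for i, sid in enumerate(panel.sample_ids):
            b = panel.breed[i]
            self.rows.append(
                {"id": sid, "sire": "0", "dam": "0", "birthdate": "2000-01-01", "breed": b,
                 "zebu_fraction": np.nan, "het_coef": 0.0}
            )
            self.fractions.append({b: 1.0})
            self.sire_idx.append(-1)
            self.dam_idx.append(-1)
            self.by_cohort.setdefault((b, 0), []).append(i)

    def add(self, label, gen, sire, dam, hap, breed_label, zebu_roles):
        i = len(self.rows)
        fr_s, fr_d = self.fractions[sire], self.fractions[dam]
        fr = {}
        for k in set(fr_s) | set(fr_d):
            fr[k] = 0.5 * fr_s.get(k, 0.0) + 0.5 * fr_d.get(k, 0.0)
        het = 1.0 - sum(fr_s.get(k, 0.0) * fr_d.get(k, 0.0) for k in set(fr_s) & set(fr_d))
        zf = sum(f for k, f in fr.items() if zebu_roles.get(k) == "founder-indicine")
        self.rows.append(
            {"id": f"{label}_G{gen}_{i}", "sire": self.rows[sire]["id"], "dam": self.rows[dam]["id"],
             "birthdate": f"{2000 + 2 * gen}-01-01", "breed": breed_label,
             "zebu_fraction": zf, "het_coef": het}
        )
        self.fractions.append(fr)
        self.sire_idx.append(sire)
        self.dam_idx.append(dam)
        self.hap.append(hap)
        self.by_cohort.setdefault((breed_label, gen), []).append(i)
        return i


def simulate_pedigree_and_crosses(
    founder_panel: GenotypePanel,
    breed_specs: list[BreedSpec],
    generations: dict | int = 1,
    seed: int = 0,
    offspring_per_generation: dict | None = None,
) -> tuple[Pedigree, GenotypePanel]:
    """Random-mating descent with recombination, plus composite formation.

    ``generations`` is the number of discrete descendant generations per
    breed (an int applies to every breed; composites use their
    ``n_descendant_generations`` after the crossing phase). Cohort sizes
    default to each breed's ``n_founders``.

    Composites are built by a dyadic crossing tree over previously defined
    breeds, so admixture fractions must have power-of-two denominators
    (3/8, 5/8, 1/2 ...). Zebu fraction and expected heterozygosity are
    derived from parental breed-fraction vectors.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    recomb = _recomb_prob(founder_panel.marker_map)
    zebu_roles = {b.label: b.role for b in breed_specs}
    known = set(founder_panel.breed)
    co = _Cohorts(founder_panel, recomb, rng)

    def n_gen(spec):
        if isinstance(generations, dict):
            return generations.get(spec.label, spec.n_descendant_generations)
        return generations if spec.role != "composite" else spec.n_descendant_generations

    def cohort_size(spec):
        if offspring_per_generation and spec.label in offspring_per_generation:
            return offspring_per_generation[spec.label]
        return spec.n_founders

    def breed_gen(spec, parent_pool, gen, size, label):
        """One random-mating generation; returns indices of offspring."""
        sires = rng.choice(parent_pool, size=size)
        dams = rng.choice(parent_pool, size=size)
        redraw = sires == dams
        while np.any(redraw) and len(parent_pool) > 1:
            dams[redraw] = rng.choice(parent_pool, size=int(redraw.sum()))
            redraw = sires == dams
        ha = np.stack([co.hap[s][0] for s in sires])
        hb = np.stack([co.hap[s][1] for s in sires])
        gam_s = _meiosis(ha, hb, recomb, rng)
        ha = np.stack([co.hap[d][0] for d in dams])
        hb = np.stack([co.hap[d][1] for d in dams])
        gam_d = _meiosis(ha, hb, recomb, rng)
        out = []
        for k in range(size):
            out.append(co.add(label, gen, int(sires[k]), int(dams[k]),
                              np.stack([gam_s[k], gam_d[k]]), label, zebu_roles))
        return out

    for spec in breed_specs:
        if spec.role != "composite":
            if spec.label not in known:
                raise ValueError(f"founder breed {spec.label} absent from panel")
            pool = co.by_cohort[(spec.label, 0)]
            for g in range(1, n_gen(spec) + 1):
                pool = breed_gen(spec, np.array(pool), g, cohort_size(spec), spec.label)
        else:
            missing = [p for p in spec.parents if p not in known]
            if missing:
                raise ValueError(f"composite {spec.label} references undefined breeds {missing}")
            for p, f in spec.parents.items():
                if abs(round(f * 64) / 64 - f) > 1e-9:
                    raise ValueError(
                        f"composite {spec.label}: admixture fraction {f} for {p} is not "
                        "dyadic (power-of-two denominator up to 64)"
                    )
            size = spec.n_founders

            def draw_cross(fracs, gen):
                """Return index of one animal with the given breed fractions.

                Intermediate crossing-tree animals get a ``<label>.cross``
                breed tag so only the finished composites form the cohort.
                """
                labels = [k for k, f in fracs.items() if f > 1e-9]
                if len(labels) == 1:
                    pool = [i for (b, g), idxs in co.by_cohort.items() if b == labels[0] for i in idxs]
                    return int(rng.choice(pool))
                left, right = _dyadic_split(fracs)
                s = draw_cross(left, gen - 1)
                d = draw_cross(right, gen - 1)
                gam_s = _meiosis(co.hap[s][0:1], co.hap[s][1:2], recomb, rng)[0]
                gam_d = _meiosis(co.hap[d][0:1], co.hap[d][1:2], recomb, rng)[0]
                tag = spec.label if gen == 1 else f"{spec.label}.cross"
                return co.add(spec.label, gen, s, d, np.stack([gam_s, gam_d]), tag, zebu_roles)

            pool = [draw_cross(dict(spec.parents), 1) for _ in range(size)]
            known.add(spec.label)
            for g in range(2, spec.n_descendant_generations + 2):
                pool = breed_gen(spec, np.array(pool), g, cohort_size(spec), spec.label)

    table = pd.DataFrame(co.rows)
    ped = Pedigree(table=table, sire_idx=np.array(co.sire_idx), dam_idx=np.array(co.dam_idx))
    panel = GenotypePanel(
        marker_map=founder_panel.marker_map,
        sample_ids=table["id"].tolist(),
        breed=table["breed"].to_numpy(),
        haplotypes=np.vstack(co.hap),
    )
    return ped, panel


# ---------------------------------------------------------------------------
# breeding values and phenotypes
# ---------------------------------------------------------------------------

def simulate_breeding_values(
    panel: GenotypePanel,
    trait_spec: TraitSpec,
    n_qtl: int,
    seed: int = 0,
    scale_ids: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """True breeding values from a random QTL subset of the markers.

    QTL effects are multivariate normal across traits with the target
    genetic correlation; per-animal values are dosage-weighted effect sums
    rescaled per trait so the realized genetic variance within the trait's
    own breed matches ``h2 * phen_var``. ``scale_ids`` overrides the
    scaling population (e.g. the pedigree founders, so the target variance
    refers to the evaluation model's base population instead of the
    recorded cohort). Returns (BV table, qtl info).
    """
    if n_qtl > panel.n_markers:
        raise ValueError("n_qtl exceeds the number of markers")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    t = trait_spec.t
    C = trait_spec.genetic_correlations
    qtl = np.sort(rng.choice(panel.n_markers, size=n_qtl, replace=False))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(t))
    effects = rng.standard_normal((n_qtl, t)) @ L.T
    M = panel.dosages[:, qtl].astype(float)
    raw = M @ effects  # animals x traits
    breed = np.asarray(panel.breed)
    if scale_ids is not None:
        in_scale = np.isin(np.asarray(panel.sample_ids), np.asarray(scale_ids))
        if not in_scale.any():
            raise ValueError("scale_ids match no panel samples")
    scale = np.zeros(t)
    for k, b in enumerate(trait_spec.breeds):
        target = trait_spec.heritability[b] * trait_spec.phen_var.get(b, 1.0)
        own = raw[in_scale, k] if scale_ids is not None else raw[breed == b, k]
        if own.size == 0:
            own = raw[:, k]
        v = own.var()
        scale[k] = np.sqrt(target / v) if v > 0 else 0.0
    bv = raw * scale
    bv -= bv.mean(axis=0)
    bv[:, scale == 0] = 0.0
    out = pd.DataFrame(bv, columns=trait_spec.breeds)
    out.insert(0, "id", panel.sample_ids)
    return out, {"qtl_index": qtl, "effects": effects * scale}


def simulate_phenotypes(
    true_bv: pd.DataFrame,
    pedigree: Pedigree,
    trait_spec: TraitSpec,
    seed: int = 0,
    phenotyped_ids: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Phenotype records for every (requested) animal of each breed.

    ``phenotyped_ids`` optionally restricts recording per breed (defaults
    to all non-founder animals of the breed; founders of pure breeds are
    treated as unrecorded base animals). Returns (records, true variance
    components): records carry animal, breed, value, raw trait value
    before mode transform, cg key columns (farm, sex, year), covariates
    and record date.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    tab = pedigree.table.set_index("id")
    bv = true_bv.set_index("id")
    sigma2_pe, sigma2_e = {}, {}
    rows = []
    for k, b in enumerate(trait_spec.breeds):
        phen_var = trait_spec.phen_var.get(b, 1.0)
        h2 = trait_spec.heritability[b]
        rep = trait_spec.repeatability.get(b)
        s2_pe = phen_var * (rep - h2) if rep is not None else 0.0
        s2_e = phen_var * (1.0 - (rep if rep is not None else h2))
        sigma2_pe[b] = s2_pe
        sigma2_e[b] = s2_e

        if phenotyped_ids and b in phenotyped_ids:
            ids = list(phenotyped_ids[b])
        else:
            sel = tab[(tab["breed"] == b) & (tab["sire"] != "0")]
            ids = sel.index.tolist()
            if not ids:  # founder-only breed: record the founders
                ids = tab[tab["breed"] == b].index.tolist()
        n = len(ids)
        if n == 0:
            continue
        missing = [a for a in ids if a not in bv.index]
        if missing:
            raise ValueError(f"animals lack breeding values: {missing[:5]}")

        lo, hi = trait_spec.records_per_animal.get(b, (1, 1))
        n_rec = rng.integers(lo, hi + 1, size=n)
        n_cg = trait_spec.n_contemporary_groups.get(b, max(2, n // 60))
        farms = rng.integers(0, max(1, n_cg // 2), size=n)
        sexes = rng.integers(0, 2, size=n)
        cg_eff = rng.normal(0.0, trait_spec.cg_sd, size=n_cg)
        pe = rng.normal(0.0, np.sqrt(s2_pe), size=n) if s2_pe > 0 else np.zeros(n)
        u = bv.loc[ids, b].to_numpy()
        mode = trait_spec.mode.get(b, "log-count")

        for i, a in enumerate(ids):
            for r in range(n_rec[i]):
                age = rng.uniform(300, 700)
                age_c = (age - 500.0) / 200.0
                cg = rng.integers(0, n_cg)
                e = rng.normal(0.0, np.sqrt(s2_e))
                zf = tab.loc[a, "zebu_fraction"]
                zf = 0.0 if pd.isna(zf) else float(zf)
                het = float(tab.loc[a, "het_coef"])
                y = (
                    cg_eff[cg]
                    + trait_spec.beta_zebu * zf
                    + trait_spec.beta_het * het
                    + trait_spec.beta_age * age_c
                    + trait_spec.beta_age2 * age_c**2
                    + u[i]
                    + pe[i]
                    + e
                )
                rows.append(
                    {
                        "animal": a, "breed": b, "raw": y,
                        "farm": f"{b}F{farms[i]}", "sex": int(sexes[i]),
                        "year": 2000 + int(cg) % 3, "cg": f"{b}CG{cg}",
                        "zebu_fraction": zf, "het_coef": het,
                        "age": age, "record": r,
                        "record_date": f"{2003 + r}-06-01",
                    }
                )
    rec = pd.DataFrame(rows)
    # mode transform per breed
    values = np.empty(len(rec))
    for b in trait_spec.breeds:
        sel = (rec["breed"] == b).to_numpy()
        mode = trait_spec.mode.get(b, "log-count")
        raw = rec.loc[sel, "raw"].to_numpy()
        if mode == "log-count":
            values[sel] = raw
        elif mode == "score":
            counts = np.maximum(0, np.round(10.0 ** raw - 1.0)).astype(int)
            values[sel] = bin_tick_score(counts)
        elif mode == "averaged-count":
            values[sel] = raw  # averaged below
        else:
            raise ValueError(f"unknown phenotype mode {mode!r}")
    rec["value"] = values
    # averaged-count breeds collapse to one mean record per animal
    avg_breeds = [b for b in trait_spec.breeds if trait_spec.mode.get(b) == "averaged-count"]
    if avg_breeds:
        keep = ~rec["breed"].isin(avg_breeds)
        collapsed = (
            rec[~keep]
            .groupby(["animal", "breed"], as_index=False)
            .agg({**{c: "first" for c in rec.columns if c not in ("animal", "breed", "value", "raw")},
                  "value": "mean", "raw": "mean"})
        )
        rec = pd.concat([rec[keep], collapsed], ignore_index=True)
    components = {
        "Sigma_u": trait_spec.genetic_covariance(),
        "sigma2_pe": sigma2_pe,
        "sigma2_e": sigma2_e,
    }
    return rec, components


def simulate_study(
    breed_specs: list[BreedSpec],
    trait_spec: TraitSpec,
    n_markers: int = 1000,
    n_qtl: int = 200,
    generations: int = 2,
    seed: int = 0,
    offspring_per_generation: dict | None = None,
    scale_to_founders: bool = False,
    **founder_kwargs,
) -> SimOutput:
    """End-to-end simulation: founders, pedigree/crosses, BVs, phenotypes.

    ``scale_to_founders`` rescales genetic variances against the pedigree
    founders (the evaluation model's base population) instead of each
    breed's recorded cohort.
    """
    ss = np.random.SeedSequence(seed)
    s_founder, s_ped, s_bv, s_phen = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    founders = simulate_founder_haplotypes(n_markers, breed_specs, s_founder, **founder_kwargs)
    ped, panel = simulate_pedigree_and_crosses(
        founders, breed_specs, generations, s_ped, offspring_per_generation
    )
    scale_ids = None
    if scale_to_founders:
        tab = ped.table
        scale_ids = tab.loc[(tab["sire"] == "0") & (tab["dam"] == "0"), "id"].tolist()
    bv, _ = simulate_breeding_values(panel, trait_spec, n_qtl, s_bv, scale_ids=scale_ids)
    phen, comps = simulate_phenotypes(bv, ped, trait_spec, s_phen)
    return SimOutput(panel, ped, phen, bv, comps, seed)
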