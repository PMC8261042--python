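"""Canned study-scale experiments over the simulation and evaluation stack.

These are the desk-scale experiments the analysis scripts and the
acceptance checks run: a founder-x-composite variance-component recovery
study, an LR-method validation study, and the persistence-of-phase
calibration. Problem sizes are chosen so each experiment completes in
minutes on a single core while keeping the statistical structure of the
multi-breed tick-resistance evaluation (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import kinship as km
from . import lrvalidation as lr
from . import popgen, ssgblup, synthdata, varcomp

__all__ = [
    "recovery_breed_specs",
    "recovery_replicate",
    "recovery_experiment",
    "lr_replicate",
    "lr_experiment",
    "phase_persistence_calibration",
]

# truth used by the recovery experiment: two tick-count traits, one on a
# taurine founder breed and one on its 3/8-zebu composite, genetically
# correlated 0.8
RECOVERY_TRUTH = {"h2[A]": 0.3, "h2[B]": 0.4, "r_g[A,B]": 0.8}


def recovery_breed_specs() -> list[synthdata.BreedSpec]:
    """Founder x composite design: taurine A, indicine Z, and composite
    B = 5/8 A : 3/8 Z built through explicit F1 and backcross cohorts."""
    return [
        synthdata.BreedSpec(label="A", role="founder-taurine", divergence=0.1, n_founders=300),
        synthdata.BreedSpec(label="Z", role="founder-indicine", divergence=0.15, n_founders=250),
        synthdata.BreedSpec(label="F1", role="composite", parents={"A": 0.5, "Z": 0.5},
                            n_founders=250, divergence=0.0, n_descendant_generations=0),
        synthdata.BreedSpec(label="D", role="composite", parents={"Z": 0.5, "F1": 0.5},
                            n_founders=350, divergence=0.0, n_descendant_generations=0),
        synthdata.BreedSpec(label="B", role="composite", parents={"A": 0.5, "D": 0.5},
                            n_founders=750, divergence=0.0, n_descendant_generations=1),
    ]


def _recovery_trait_spec() -> synthdata.TraitSpec:
    return synthdata.TraitSpec(
        breeds=["A", "B"],
        heritability={"A": RECOVERY_TRUTH["h2[A]"], "B": RECOVERY_TRUTH["h2[B]"]},
        genetic_correlations=np.array([[1.0, RECOVERY_TRUTH["r_g[A,B]"]],
                                       [RECOVERY_TRUTH["r_g[A,B]"], 1.0]]),
    )


def _genotyped_h_inverse(sim, n_geno_per_breed, seed, breeds=("A", "B")):
    """Random genotyped subset of the phenotyped animals + single-step H^-1."""
    ped = sim.pedigree
    rng = np.random.default_rng(seed)
    phen_ids = sim.phenotypes["animal"].unique()
    geno_ids: list = []
    for b in breeds:
        cand = [a for a in phen_ids if a.startswith(f"{b}_")]
        geno_ids += rng.choice(cand, size=min(n_geno_per_breed, len(cand)), replace=False).tolist()
    order = {a: i for i, a in enumerate(ped.ids)}
    geno_ids = sorted(geno_ids, key=order.get)
    Ainv = km.build_A_inverse(ped.sire_idx, ped.dam_idx, ped.ids)
    A22 = km.build_A(ped.sire_idx, ped.dam_idx, ped.ids, subset=geno_ids)
    gp = sim.panel.subset(sample_ids=geno_ids)
    G = km.build_G(gp.dosages, geno_ids, breed=gp.breed)
    return km.build_H_inverse(Ainv, A22, G)


def recovery_replicate(
    seed: int,
    n_cycles: int = 20_000,
    burn_in: int = 4_000,
    thinning: int = 10,
    n_geno_per_breed: int = 200,
    n_markers: int = 2_000,
) -> pd.DataFrame:
    """One variance-component recovery replicate; returns derived-parameter
    summaries (posterior mean, TS-SE, 90% credible bounds)."""
    sim = synthdata.simulate_study(
        recovery_breed_specs(), _recovery_trait_spec(),
        n_markers=n_markers, n_qtl=200, generations=2, seed=seed,
        offspring_per_generation={"A": 750, "B": 750},
        scale_to_founders=True,
    )
    H_inv = _genotyped_h_inverse(sim, n_geno_per_breed, seed + 5)
    spec = ssgblup.ModelSpec(
        breeds=["A", "B"], cg_column="cg",
        covariates=["zebu_fraction", "het_coef"], age_column="age",
    )
    chain = varcomp.gibbs_sample(
        sim.phenotypes, spec, H_inv,
        n_cycles=n_cycles, burn_in=burn_in, thinning=thinning, seed=seed + 9,
    )
    out = varcomp.derive_parameters(chain)
    out["replicate_seed"] = seed
    return out


def recovery_experiment(seed: int = 0, n_replicates: int = 20, **kwargs) -> pd.DataFrame:
    """Replicated recovery study; one row per (replicate, parameter)."""
    base = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**30)
    rows = [recovery_replicate(base + 17 * r, **kwargs) for r in range(n_replicates)]
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# LR-method validation experiment
# ---------------------------------------------------------------------------

def lr_replicate(seed: int, n_phenotyped: int = 2_000, h2: float = 0.3) -> dict:
    """One old-young LR validation replicate on a single breed.

    Simulates a pedigreed population, fits whole and partial (youngest 1/3
    masked) evaluations with the true variance components, and returns
    rho_w,p, predictive ability, beta_w,p and the truth-based accuracies.
    """
    half = n_phenotyped // 2
    breeds = [synthdata.BreedSpec(label="A", role="founder-taurine",
                                  divergence=0.1, n_founders=max(300, n_phenotyped // 5))]
    ts = synthdata.TraitSpec(
        breeds=["A"], heritability={"A": h2}, genetic_correlations=np.array([[1.0]]),
    )
    sim = synthdata.simulate_study(
        breeds, ts, n_markers=1_000, n_qtl=200, generations=2, seed=seed,
        offspring_per_generation={"A": half}, scale_to_founders=True,
    )
    ped = sim.pedigree
    Ainv = km.build_A_inverse(ped.sire_idx, ped.dam_idx, ped.ids)
    comps = varcomp.CovarianceComponents(
        breeds=["A"], Sigma_u=sim.true_components["Sigma_u"],
        sigma2_e=sim.true_components["sigma2_e"],
    )
    spec = ssgblup.ModelSpec(breeds=["A"], cg_column="cg",
                             covariates=["zebu_fraction", "het_coef"], age_column="age")

    sol_w = ssgblup.solve_mme(ssgblup.assemble_mme(sim.phenotypes, spec, comps, Ainv))
    part = lr.make_partition(sim.phenotypes, ped.table, "old-young", "A")
    sol_p = ssgblup.solve_mme(ssgblup.assemble_mme(part.reference_records, spec, comps, Ainv))

    uw = sol_w.breeding_values()["A"]
    up = sol_p.breeding_values()["A"]
    y_star = lr.adjusted_phenotypes(sim.phenotypes, sol_w, "A")
    stats = lr.lr_statistics(uw, up, y_star, part.validation_ids)
    truth = sim.true_bv.set_index("id")["A"]
    stats["acc_w"] = lr.accuracy_from_truth(uw, truth, part.validation_ids)
    stats["acc_p"] = lr.accuracy_from_truth(up, truth, part.validation_ids)
    stats["seed"] = seed
    return stats


def lr_experiment(seed: int = 0, n_replicates: int = 20, **kwargs) -> pd.DataFrame:
    base = int(np.random.SeedSequence(seed + 1).generate_state(1)[0] % 2**30)
    return pd.DataFrame([lr_replicate(base + 13 * r, **kwargs) for r in range(n_replicates)])


# ---------------------------------------------------------------------------
# persistence-of-phase calibration
# ---------------------------------------------------------------------------

def phase_persistence_calibration(
    seed: int = 0, n_founders: int = 1_000, n_markers: int = 5_000
) -> dict:
    """Same-pool vs independent-pool persistence of phase.

    Two breeds drawn at zero divergence from one ancestral pool share every
    haplotype lineage, so their signed adjacent-marker r vectors should be
    nearly identical (R_A,B -> 1); panels simulated from independent
    ancestral pools share nothing and R should vanish.
    """
    shared = [
        synthdata.BreedSpec(label=l, role="founder-taurine", divergence=0.0,
                            n_founders=n_founders)
        for l in ("S1", "S2")
    ]
    panel = synthdata.simulate_founder_haplotypes(n_markers, shared, seed)

    def ld_of(panel, label):
        sub = panel.subset(
            sample_ids=[s for s, b in zip(panel.sample_ids, panel.breed) if b == label]
        )
        return popgen.adjacent_ld(sub.marker_map, haplotypes=sub.haplotypes)

    same_pool = popgen.phase_persistence(ld_of(panel, "S1"), ld_of(panel, "S2"), "S1", "S2")

    ind1 = [synthdata.BreedSpec(label="I1", role="founder-taurine", divergence=0.0,
                                n_founders=n_founders)]
    ind2 = [synthdata.BreedSpec(label="I2", role="founder-taurine", divergence=0.0,
                                n_founders=n_founders)]
    p1 = synthdata.simulate_founder_haplotypes(n_markers, ind1, seed + 1)
    p2 = synthdata.simulate_founder_haplotypes(n_markers, ind2, seed + 2)
    # marker maps are identical by construction (uniform map), so the two
    # LD tables are comparable marker-for-marker
    ld1 = popgen.adjacent_ld(p1.marker_map, haplotypes=p1.haplotypes)
    ld2 = popgen.adjacent_ld(p2.marker_map, haplotypes=p2.haplotypes)
    independent = popgen.phase_persistence(ld1, ld2, "I1", "I2")
    return {
        "same_pool_R": same_pool.overall,
        "independent_R": independent.overall,
        "n_pairs": same_pool.n_pairs,
    }
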