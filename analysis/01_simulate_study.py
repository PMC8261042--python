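"""Simulate the desk-scale multi-breed tick-resistance study.

Three populations mirror the structure of a multi-country evaluation: a
taurine founder breed (log-count records, repeated measures), an indicine
founder breed (single tick scores), and a 3/8-zebu composite (log-count
records). Writes PLINK genotypes, pedigree, phenotypes and true breeding
values under results/study/.
"""

import sys
from pathlib import Path

import numpy as np

from tickblup import pipeline_io as pio
from tickblup import synthdata as sd

OUT = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240915

# the composite is bred the way 3/8-zebu composites are formed in practice:
# F1 (taurine x zebu), backcross to zebu, then composite x taurine founders
BREEDS = [
    sd.BreedSpec(label="TAU", role="founder-taurine", divergence=0.1, n_founders=250),
    sd.BreedSpec(label="ZEB", role="founder-indicine", divergence=0.15, n_founders=200),
    sd.BreedSpec(label="F1C", role="composite", parents={"TAU": 0.5, "ZEB": 0.5},
                 n_founders=150, divergence=0.0, n_descendant_generations=0),
    sd.BreedSpec(label="BXC", role="composite", parents={"ZEB": 0.5, "F1C": 0.5},
                 n_founders=200, divergence=0.0, n_descendant_generations=0),
    sd.BreedSpec(label="CMP", role="composite", parents={"TAU": 0.5, "BXC": 0.5},
                 n_founders=500, divergence=0.0, n_descendant_generations=1),
]
TRAITS = sd.TraitSpec(
    breeds=["TAU", "ZEB", "CMP"],
    heritability={"TAU": 0.27, "ZEB": 0.39, "CMP": 0.21},
    genetic_correlations=np.array([
        [1.0, 0.17, 0.65],
        [0.17, 1.0, 0.47],
        [0.65, 0.47, 1.0],
    ]),
    repeatability={"TAU": 0.30, "CMP": 0.37},
    records_per_animal={"TAU": (1, 3), "CMP": (1, 3)},
    mode={"ZEB": "score"},
)


def main():
    sim = sd.simulate_study(
        BREEDS, TRAITS, n_markers=2_000, n_qtl=300, generations=2, seed=SEED,
        offspring_per_generation={"TAU": 500, "ZEB": 300, "CMP": 500},
        scale_to_founders=True,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    pio.write_plink(sim.panel, OUT / "genotypes")
    sim.pedigree.table.to_csv(OUT / "pedigree.csv", index=False)
    sim.phenotypes.to_csv(OUT / "phenotypes.csv", index=False)
    sim.true_bv.to_csv(OUT / "true_breeding_values.csv", index=False)

    print(f"seed {SEED}: {len(sim.pedigree)} animals in pedigree, "
          f"{sim.panel.n_markers} markers")
    for b in TRAITS.breeds:
        rec = sim.phenotypes[sim.phenotypes["breed"] == b]
        print(f"  {b}: {len(rec)} records on {rec['animal'].nunique()} animals, "
              f"mean {rec['value'].mean():.2f} +/- {rec['value'].std():.2f}")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
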