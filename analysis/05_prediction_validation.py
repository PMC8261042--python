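"""LR-method validation of genomic predictions for the simulated study.

For each breed: univariate and multi-trait old-young validation (youngest
third masked) and multi-trait other-pops validation (all target-breed
phenotypes masked). Reports predictive ability r(y*, u_p), the dispersion
slope beta_w,p, rho_w,p, and truth-based accuracies. Writes the
validation grid (breeds x statistic x strategy).
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tickblup import lrvalidation as lr
from tickblup import pipeline_io as pio
from tickblup import reporting, ssgblup, varcomp

STUDY = Path("results/study")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20240916

sys.path.insert(0, str(Path(__file__).parent))
vc = __import__("04_variance_components")


def main():
    ped = pio.load_pedigree(STUDY / "pedigree.csv")
    panel = pio.load_genotypes(STUDY / "genotypes")
    phen = pd.read_csv(STUDY / "phenotypes.csv")
    truth = pd.read_csv(STUDY / "true_breeding_values.csv").set_index("id")
    with open(STUDY / "components.json") as fh:
        cj = json.load(fh)
    comps = varcomp.CovarianceComponents(
        breeds=cj["breeds"], Sigma_u=np.array(cj["Sigma_u"]),
        sigma2_pe=cj["sigma2_pe"], sigma2_e=cj["sigma2_e"],
    )
    H_inv = vc.build_h_inverse(ped, panel, phen, SEED)
    spec = ssgblup.ModelSpec(
        breeds=vc.BREEDS, cg_column="cg", covariates=["zebu_fraction", "het_coef"],
        age_column="age", pe_breeds=vc.PE_BREEDS,
    )

    sol_w = ssgblup.solve_mme(ssgblup.assemble_mme(phen, spec, comps, H_inv))
    rows = []
    for breed in vc.BREEDS:
        uw = sol_w.breeding_values()[breed]
        y_star = lr.adjusted_phenotypes(phen, sol_w, breed)
        tasks = [("uni old-young", "old-young", True), ("multi old-young", "old-young", False),
                 ("multi other-pops", "other-pops", False)]
        for label, strategy, univariate in tasks:
            part = lr.make_partition(phen, ped.table, strategy, breed)
            if univariate:
                sol_p = ssgblup.predict_univariate(
                    part.reference_records, spec, comps, H_inv, breed)
                uw_ref = ssgblup.predict_univariate(phen, spec, comps, H_inv, breed)
                uw_used = uw_ref.breeding_values()[breed]
            else:
                sol_p = ssgblup.solve_mme(
                    ssgblup.assemble_mme(part.reference_records, spec, comps, H_inv))
                uw_used = uw
            up = sol_p.breeding_values()[breed]
            stats = lr.lr_statistics(uw_used, up, y_star, part.validation_ids)
            stats.update({"breed": breed, "strategy": label,
                          "acc_w": lr.accuracy_from_truth(uw_used, truth[breed], part.validation_ids),
                          "acc_p": lr.accuracy_from_truth(up, truth[breed], part.validation_ids)})
            rows.append(stats)
            print(f"{breed:4s} {label:17s} r(y*,u_p)={stats['predictive_ability']:+.3f} "
                  f"beta={stats['beta_wp']:+.3f} rho={stats['rho_wp']:+.3f} "
                  f"acc_p={stats['acc_p']:+.3f}")

    grid = pd.DataFrame(rows)
    grid.to_csv(STUDY / "validation_raw.csv", index=False)
    reporting.render_validation_grid(grid).to_csv(STUDY / "validation_grid.csv")
    print("\nvalidation grid written to", STUDY / "validation_grid.csv")


if __name__ == "__main__":
    main()
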