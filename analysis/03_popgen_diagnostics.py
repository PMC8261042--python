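"""Population-genomic diagnostics of the simulated multi-breed panel.

Adjacent-marker LD per breed (EM haplotype frequencies from the unphased
PLINK dosages), persistence of phase and allele-frequency correlations
between breeds, and a PCA of the VanRaden G matrix. Writes the
persistence/frequency matrix (phase above, frequency correlation below
the diagonal), per-breed LD tables and PCA scores.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tickblup import kinship as km
from tickblup import pipeline_io as pio
from tickblup import popgen

STUDY = Path("results/study")


def main():
    panel = pio.load_genotypes(STUDY / "genotypes")
    keep = (STUDY / "keep_samples.txt").read_text().split()
    snps = (STUDY / "extract_snps.txt").read_text().split()
    panel = panel.subset(sample_ids=keep, snp_ids=snps)
    breeds = [b for b in pd.unique(panel.breed) if "." not in str(b)]

    ld = {}
    for b in breeds:
        sub = panel.subset(
            sample_ids=[s for s, br in zip(panel.sample_ids, panel.breed) if br == b]
        )
        ld[b] = popgen.adjacent_ld(sub.marker_map, dosages=sub.dosages)
        ld[b].to_csv(STUDY / f"ld_{b}.csv", index=False)
        mean_r2 = ld[b].loc[ld[b]["defined"], "r2"].mean()
        print(f"{b}: mean adjacent r2 = {mean_r2:.3f}")

    matrix = pd.DataFrame(index=breeds, columns=breeds, dtype=float)
    for i, a in enumerate(breeds):
        for j, b in enumerate(breeds):
            if i < j:
                matrix.loc[a, b] = popgen.phase_persistence(ld[a], ld[b], a, b).overall
            elif i > j:
                matrix.loc[a, b] = popgen.allele_freq_correlation(
                    panel.allele_frequencies(a), panel.allele_frequencies(b)
                )
    matrix.to_csv(STUDY / "phase_persistence_matrix.csv")
    print("\nphase persistence (above) / allele-frequency correlation (below):")
    print(matrix.round(2).to_string())

    dos = panel.dosages.astype(float)
    dos[dos < 0] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    G = km.build_G(dos, panel.sample_ids, breed=panel.breed)
    scores, frac = popgen.grm_pca(G.toarray(), n_components=4)
    pca = pd.DataFrame(scores, columns=[f"PC{k+1}" for k in range(scores.shape[1])])
    pca.insert(0, "id", panel.sample_ids)
    pca.insert(1, "breed", panel.breed)
    pca.to_csv(STUDY / "pca_scores.csv", index=False)
    print("\nPC variance fractions:", np.round(frac, 3))


if __name__ == "__main__":
    main()
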