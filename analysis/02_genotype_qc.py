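"""Genotype quality control on the simulated study panel.

Applies the sample filters (call rate, heterozygosity window, duplicates)
and marker filters (autosome, call rate, MAF, Hardy-Weinberg, redundancy)
and writes PLINK-compatible keep/extract lists plus a per-rule report.
"""

from pathlib import Path

import pandas as pd

from tickblup import genotype_qc as qc
from tickblup import pipeline_io as pio

STUDY = Path("results/study")


def main():
    panel = pio.load_genotypes(STUDY / "genotypes")
    thr = qc.QCThresholds()
    samples, srep = qc.sample_qc(panel.dosages, panel.sample_ids, thr)
    snps, mrep = qc.snp_qc(panel.dosages, panel.marker_map, thr)
    sub = panel.subset(sample_ids=samples, snp_ids=snps)
    snps = qc.dedupe_snps(sub.dosages, sub.marker_map, thr.duplicate_r_max)

    (STUDY / "keep_samples.txt").write_text("\n".join(samples) + "\n")
    (STUDY / "extract_snps.txt").write_text("\n".join(snps) + "\n")
    report = pd.concat([srep.assign(level="sample"), mrep.assign(level="snp")])
    report.to_csv(STUDY / "qc_report.csv", index=False)

    print(f"samples: {len(panel.sample_ids)} -> {len(samples)}")
    print(f"markers: {panel.n_markers} -> {len(snps)}")
    print(report.to_string(index=False))


if __name__ == "__main__":
    main()
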