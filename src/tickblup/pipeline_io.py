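"""File I/O, configuration and end-to-end orchestration.

Genotypes travel as PLINK bed/bim/fam triples (SNP-major 2-bit bed; the
breed is stored in the family-id column, following multi-population PLINK
conventions), pedigrees and phenotypes as UTF-8 CSV, configuration as
YAML. Every pipeline stage writes its outputs plus a manifest (hashed
inputs, parameters, seed) so identical configs reproduce identical runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .containers import GenotypePanel, Pedigree

__all__ = [
    "write_plink",
    "load_genotypes",
    "load_pedigree",
    "pedigree_from_table",
    "load_config",
    "run_pipeline",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of the A1 allele (01 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK bed/bim/fam (breed into the family id)."""
    prefix = Path(prefix)
    mm = panel.marker_map
    n = len(panel.sample_ids)
    dos = panel.dosages
    # dosage+1 -> 2-bit code: -1->01 (missing), 0->11, 1->10, 2->00
    code_of = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
    n_pad = ((n + 3) // 4) * 4
    codes = np.zeros((dos.shape[1], n_pad), dtype=np.uint8)  # trailing slots padded with zero bits
    codes[:, :n] = code_of[dos.T.astype(np.int64) + 1]
    quads = codes.reshape(dos.shape[1], n_pad // 4, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": mm["chrom"],
            "snp": mm["snp"],
            "cm": mm["cm"] if "cm" in mm else 0.0,
            "pos": mm["pos"],
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.breed,
            "iid": panel.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def load_genotypes(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK bed/bim/fam triple into an (unphased) panel.

    The family-id column supplies the breed label. Raises on a wrong bed
    magic number or a payload size inconsistent with bim/fam.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: not a SNP-major PLINK bed file")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != m * n_bytes:
        raise ValueError(
            f"bed payload holds {payload.size} bytes but bim/fam imply {m} x {n_bytes}"
        )
    codes = payload.reshape(m, n_bytes)
    dos = np.empty((n, m), dtype=np.int8)
    for shift in range(4):
        idx = np.arange(shift, n, 4)
        two_bit = (codes[:, idx // 4] >> (2 * shift)) & 0b11
        dos[idx, :] = _CODE_TO_DOSAGE[two_bit].T
    return GenotypePanel(
        marker_map=bim[["snp", "chrom", "pos", "cm"]].copy(),
        sample_ids=fam["iid"].tolist(),
        breed=fam["fid"].to_numpy(),
        haplotypes=None,
        _dosages=dos,
    )


def pedigree_from_table(table: pd.DataFrame) -> Pedigree:
    """Topologically order a raw pedigree table and integer-code parents.

    Unknown parents are '0' or empty; parents referenced but unlisted are
    added as unknown-parent founders. Cycles raise with the offending
    chain.
    """
    tab = table.copy()
    for c in ("sire", "dam"):
        tab[c] = tab[c].fillna("0").astype(str).replace("", "0")
    tab["id"] = tab["id"].astype(str)
    listed = set(tab["id"])
    implicit = sorted(
        {p for c in ("sire", "dam") for p in tab[c] if p != "0" and p not in listed}
    )
    if implicit:
        extra = pd.DataFrame(
            {
                "id": implicit,
                "sire": "0",
                "dam": "0",
                "birthdate": pd.NaT,
                "breed": "unknown",
            }
        )
        for col in tab.columns:
            if col not in extra.columns:
                extra[col] = np.nan
        tab = pd.concat([tab, extra[tab.columns]], ignore_index=True)

    g = nx.DiGraph()
    g.add_nodes_from(tab["id"])
    for _, row in tab.iterrows():
        for p in (row["sire"], row["dam"]):
            if p != "0":
                g.add_edge(p, row["id"])
    try:
        order = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(g)
        chain = " -> ".join(a for a, _ in cycle) + " -> " + cycle[-1][1]
        raise ValueError(f"pedigree contains a cycle: {chain}") from None
    pos = {a: k for k, a in enumerate(order)}
    tab = tab.sort_values("id", key=lambda s: s.map(pos), kind="stable").reset_index(drop=True)
    idx = {a: k for k, a in enumerate(tab["id"])}
    sire_idx = np.array([idx[p] if p != "0" else -1 for p in tab["sire"]])
    dam_idx = np.array([idx[p] if p != "0" else -1 for p in tab["dam"]])
    return Pedigree(table=tab, sire_idx=sire_idx, dam_idx=dam_idx)


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a pedigree CSV (id, sire, dam, birthdate, breed) and order it."""
    tab = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    required = {"id", "sire", "dam"}
    if not required <= set(tab.columns):
        raise ValueError(f"pedigree CSV needs columns {sorted(required)}")
    return pedigree_from_table(tab)


_KNOWN_BLOCKS = {
    "seed", "outdir", "stages", "simulate", "phenotypes", "qc", "popgen",
    "kinship", "model", "mcmc", "validate", "paths",
}


def load_config(path: str | Path) -> dict:
    """Load a YAML run config, rejecting unknown top-level blocks."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path], outputs: list[Path], seed) -> None:
    man = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {p.name: _sha256(p) for p in inputs if p.exists()},
        "outputs": sorted(p.name for p in outputs),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)


def run_pipeline(config: dict, outdir: str | Path | None = None) -> Path:
    """Execute the enabled stages in dependency order on simulated data.

    Stages (config block ``stages``, default all): simulate, qc, popgen,
    kinship, varcomp, blup, validate. Every stage writes CSV outputs and
    a manifest into the run directory; a rerun with the identical config
    and seed reproduces the outputs bit-identically.
    """
    from . import genotype_qc, kinship, lrvalidation, popgen, reporting, ssgblup, synthdata, varcomp

    outdir = Path(outdir or config.get("outdir", "runs/run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages") or ["simulate", "qc", "popgen", "kinship", "varcomp", "blup", "validate"]

    state: dict = {}
    try:
        for stage in stages:
            _STAGE_FNS[stage](config, state, outdir, seed)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return outdir


def _stage_simulate(config, state, outdir, seed):
    from . import synthdata

    sim_cfg = config.get("simulate", {})
    breed_specs = [synthdata.BreedSpec(**b) for b in sim_cfg.get("breeds", [
        {"label": "TAU", "role": "founder-taurine", "divergence": 0.1, "n_founders": 120},
        {"label": "ZEB", "role": "founder-indicine", "divergence": 0.15, "n_founders": 120},
        {"label": "CMP", "role": "composite", "divergence": 0.0, "n_founders": 120,
         "parents": {"TAU": 0.625, "ZEB": 0.375}, "n_descendant_generations": 1},
    ])]
    labels = [b.label for b in breed_specs]
    tcfg = sim_cfg.get("traits", {})
    t = len(labels)
    corr = np.asarray(tcfg.get("genetic_correlations", (0.4 * np.ones((t, t)) + 0.6 * np.eye(t))))
    trait_spec = synthdata.TraitSpec(
        breeds=labels,
        heritability=tcfg.get("heritability", {b: 0.3 for b in labels}),
        genetic_correlations=corr,
        repeatability=tcfg.get("repeatability", {}),
        records_per_animal={k: tuple(v) for k, v in tcfg.get("records_per_animal", {}).items()},
        mode=tcfg.get("mode", {}),
    )
    sim = synthdata.simulate_study(
        breed_specs, trait_spec,
        n_markers=int(sim_cfg.get("n_markers", 600)),
        n_qtl=int(sim_cfg.get("n_qtl", 120)),
        generations=int(sim_cfg.get("generations", 1)),
        seed=seed,
    )
    state["sim"] = sim
    state["trait_spec"] = trait_spec
    write_plink(sim.panel, outdir / "genotypes")
    sim.pedigree.table.to_csv(outdir / "pedigree.csv", index=False)
    sim.phenotypes.to_csv(outdir / "phenotypes.csv", index=False)
    sim.true_bv.to_csv(outdir / "true_breeding_values.csv", index=False)
    _write_manifest(outdir, "simulate", {"n_markers": sim.panel.n_markers, "breeds": labels},
                    [], [outdir / f"genotypes.{s}" for s in ("bed", "bim", "fam")]
                    + [outdir / "pedigree.csv", outdir / "phenotypes.csv"], seed)


def _stage_qc(config, state, outdir, seed):
    from . import genotype_qc

    panel = state["sim"].panel if "sim" in state else load_genotypes(outdir / "genotypes")
    thr = genotype_qc.QCThresholds(**config.get("qc", {}))
    samples, srep = genotype_qc.sample_qc(panel.dosages, panel.sample_ids, thr)
    snps, mrep = genotype_qc.snp_qc(panel.dosages, panel.marker_map, thr)
    snps = genotype_qc.dedupe_snps(
        panel.subset(snp_ids=snps).dosages, panel.subset(snp_ids=snps).marker_map, thr.duplicate_r_max
    )
    state["qc_panel"] = panel.subset(sample_ids=samples, snp_ids=snps)
    (outdir / "keep_samples.txt").write_text("\n".join(samples) + "\n")
    (outdir / "extract_snps.txt").write_text("\n".join(snps) + "\n")
    pd.concat([srep.assign(level="sample"), mrep.assign(level="snp")]).to_csv(
        outdir / "qc_report.csv", index=False
    )
    _write_manifest(outdir, "qc", {"thresholds": vars(thr)},
                    [outdir / "genotypes.bed"],
                    [outdir / "keep_samples.txt", outdir / "extract_snps.txt", outdir / "qc_report.csv"], seed)


def _stage_popgen(config, state, outdir, seed):
    from . import popgen, reporting

    panel = state.get("qc_panel") or state["sim"].panel
    breeds = [b for b in pd.unique(panel.breed) if "." not in str(b) and b != "unknown"]
    ld = {}
    for b in breeds:
        sub = panel.subset(sample_ids=[s for s, br in zip(panel.sample_ids, panel.breed) if br == b])
        ld[b] = popgen.adjacent_ld(sub.marker_map, haplotypes=sub.haplotypes, dosages=None if sub.phased else sub.dosages)
        ld[b].to_csv(outdir / f"ld_{b}.csv", index=False)
    persist = pd.DataFrame(index=breeds, columns=breeds, dtype=float)
    for i, a in enumerate(breeds):
        for j, b in enumerate(breeds):
            if i < j:
                persist.loc[a, b] = popgen.phase_persistence(ld[a], ld[b], a, b).overall
            elif i > j:
                persist.loc[a, b] = popgen.allele_freq_correlation(
                    panel.allele_frequencies(a), panel.allele_frequencies(b)
                )
    persist.to_csv(outdir / "phase_persistence_matrix.csv")
    state["ld"] = ld
    _write_manifest(outdir, "popgen", {"breeds": list(breeds)}, [],
                    [outdir / "phase_persistence_matrix.csv"], seed)


def _stage_kinship(config, state, outdir, seed):
    from . import kinship as km

    sim = state["sim"]
    ped = sim.pedigree
    kcfg = config.get("kinship", {})
    panel = state.get("qc_panel") or sim.panel
    rng = np.random.default_rng(seed)
    n_geno = int(kcfg.get("n_genotyped", min(len(panel.sample_ids), 400)))
    geno_ids = sorted(rng.choice(panel.sample_ids, size=n_geno, replace=False).tolist())
    Ainv = km.build_A_inverse(ped.sire_idx, ped.dam_idx, ped.ids)
    A22 = km.build_A(ped.sire_idx, ped.dam_idx, ped.ids, subset=geno_ids)
    gp = panel.subset(sample_ids=geno_ids)
    G = km.build_G(gp.dosages, geno_ids, breed=gp.breed)
    blend = tuple(kcfg.get("blend", (0.95, 0.05)))
    Hinv = km.build_H_inverse(Ainv, A22, G, blend)
    state["H_inv"] = Hinv
    coo = Hinv.values.tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
        outdir / "h_inverse_triplets.csv", index=False
    )
    pd.Series(Hinv.ids).to_csv(outdir / "h_inverse_ids.csv", index=False, header=False)
    _write_manifest(outdir, "kinship", {"blend": list(blend), "n_genotyped": n_geno},
                    [outdir / "pedigree.csv"], [outdir / "h_inverse_triplets.csv"], seed)


def _model_spec(state, config):
    from . import ssgblup

    sim = state["sim"]
    tspec = state["trait_spec"]
    mcfg = config.get("model", {})
    return ssgblup.ModelSpec(
        breeds=list(tspec.breeds),
        cg_column=mcfg.get("cg_column", "cg"),
        covariates=mcfg.get("covariates", ["zebu_fraction", "het_coef"]),
        age_column=mcfg.get("age_column", "age"),
        pe_breeds=tuple(tspec.repeatability.keys()),
    )


def _stage_varcomp(config, state, outdir, seed):
    from . import reporting, varcomp

    mcmc = config.get("mcmc", {})
    spec = _model_spec(state, config)
    chain = varcomp.gibbs_sample(
        state["sim"].phenotypes, spec, state["H_inv"],
        n_cycles=int(mcmc.get("cycles", 6000)),
        burn_in=int(mcmc.get("burn_in", 1500)),
        thinning=int(mcmc.get("thinning", 5)),
        seed=seed,
    )
    state["chain"] = chain
    state["components"] = chain.posterior_mean_components()
    chain.draws.to_csv(outdir / "gibbs_draws.csv", index=False)
    params = varcomp.derive_parameters(chain)
    params.to_csv(outdir / "genetic_parameters.csv", index=False)
    reporting.render_parameter_matrix(params, chain.breeds).to_csv(outdir / "parameter_matrix.csv")
    _write_manifest(outdir, "varcomp",
                    {"cycles": chain.n_cycles, "burn_in": chain.burn_in, "thinning": chain.thinning},
                    [outdir / "phenotypes.csv"], [outdir / "gibbs_draws.csv"], seed)


def _stage_blup(config, state, outdir, seed):
    from . import ssgblup

    spec = _model_spec(state, config)
    system = ssgblup.assemble_mme(
        state["sim"].phenotypes, spec, state["components"], state["H_inv"]
    )
    sol = ssgblup.solve_mme(system)
    state["solutions"] = sol
    sol.table.to_csv(outdir / "solutions.csv", index=False)
    _write_manifest(outdir, "blup", {"n_equations": len(system.rhs)},
                    [outdir / "phenotypes.csv"], [outdir / "solutions.csv"], seed)


def _stage_validate(config, state, outdir, seed):
    from . import lrvalidation as lr
    from . import reporting, ssgblup

    sim = state["sim"]
    spec = _model_spec(state, config)
    comps = state["components"]
    sol_w = state["solutions"]
    reports = []
    strategies = config.get("validate", {}).get("strategies", ["old-young", "other-pops"])
    for breed in spec.breeds:
        uw = sol_w.breeding_values()[breed]
        y_star = lr.adjusted_phenotypes(sim.phenotypes, sol_w, breed)
        for strategy in strategies:
            part = lr.make_partition(sim.phenotypes, sim.pedigree.table, strategy, breed)
            system = ssgblup.assemble_mme(part.reference_records, spec, comps, state["H_inv"])
            up = ssgblup.solve_mme(system).table
            up = up[(up["effect"] == "animal") & (up["trait"] == breed)].set_index("level")["estimate"]
            stats = lr.lr_statistics(uw, up, y_star, part.validation_ids)
            stats.update({"breed": breed, "strategy": f"multi {strategy}"})
            truth = sim.true_bv.set_index("id")[breed]
            stats["acc_p"] = lr.accuracy_from_truth(up, truth, part.validation_ids)
            stats["acc_w"] = lr.accuracy_from_truth(uw, truth, part.validation_ids)
            reports.append(stats)
    grid = pd.DataFrame(reports)
    grid.to_csv(outdir / "validation_raw.csv", index=False)
    reporting.render_validation_grid(grid).to_csv(outdir / "validation_grid.csv")
    _write_manifest(outdir, "validate", {"strategies": strategies},
                    [outdir / "phenotypes.csv"], [outdir / "validation_grid.csv"], seed)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "popgen": _stage_popgen,
    "kinship": _stage_kinship,
    "varcomp": _stage_varcomp,
    "blup": _stage_blup,
    "validate": _stage_validate,
}
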