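"""Multi-breed simulation: drift calibration, crossing, breeding values, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from tickblup import synthdata as sd


def hudson_fst(p1, p2, n1, n2):
    """Hudson's two-population Fst estimator (ratio of averages) — the
    independent oracle for the drift calibration."""
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


def _founder_specs(div, n=300):
    return [
        sd.BreedSpec(label="P", role="founder-taurine", divergence=div, n_founders=n),
        sd.BreedSpec(label="Q", role="founder-indicine", divergence=div, n_founders=n),
    ]


class TestFounderHaplotypes:
    def test_seeded_determinism(self):
        a = sd.simulate_founder_haplotypes(300, _founder_specs(0.1, 100), seed=5)
        b = sd.simulate_founder_haplotypes(300, _founder_specs(0.1, 100), seed=5)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.sample_ids == b.sample_ids

    def test_zero_divergence_frequencies_converge(self):
        panel = sd.simulate_founder_haplotypes(2_000, _founder_specs(0.0, 1_000), seed=2)
        fp = panel.allele_frequencies("P")
        fq = panel.allele_frequencies("Q")
        assert np.abs(fp - fq).mean() < 0.02
        assert np.corrcoef(fp, fq)[0, 1] > 0.99

    def test_realized_fst_matches_divergence(self):
        panel = sd.simulate_founder_haplotypes(5_000, _founder_specs(0.2, 500), seed=3)
        fst = hudson_fst(
            panel.allele_frequencies("P"), panel.allele_frequencies("Q"), 1_000, 1_000
        )
        assert fst == pytest.approx(0.2, abs=0.05)

    def test_frequencies_strictly_polymorphic_parameters_validated(self):
        with pytest.raises(ValueError):
            sd.BreedSpec(label="X", divergence=1.0)
        with pytest.raises(ValueError, match="n_markers"):
            sd.simulate_founder_haplotypes(1, _founder_specs(0.1, 10), seed=0)
        with pytest.raises(ValueError, match="founder"):
            sd.simulate_founder_haplotypes(
                10, [sd.BreedSpec(label="C", role="composite", parents={"A": 1.0})], seed=0
            )


class TestPedigreeAndCrosses:
    @pytest.fixture
    def crossed(self):
        specs = _founder_specs(0.1, 80) + [
            sd.BreedSpec(label="C", role="composite", parents={"P": 0.625, "Q": 0.375},
                         n_founders=60, divergence=0.0, n_descendant_generations=1),
        ]
        founders = sd.simulate_founder_haplotypes(200, specs, seed=7)
        ped, panel = sd.simulate_pedigree_and_crosses(founders, specs, generations=1, seed=8)
        return specs, ped, panel

    def test_f1_heterosis_coefficient_is_one(self):
        specs = _founder_specs(0.1, 40) + [
            sd.BreedSpec(label="F1", role="composite", parents={"P": 0.5, "Q": 0.5},
                         n_founders=30, divergence=0.0, n_descendant_generations=0),
        ]
        founders = sd.simulate_founder_haplotypes(100, specs, seed=1)
        ped, _ = sd.simulate_pedigree_and_crosses(founders, specs, generations=0, seed=2)
        f1 = ped.table[ped.table["breed"] == "F1"]
        assert np.allclose(f1["het_coef"], 1.0)

    def test_composite_zebu_fraction_exact(self, crossed):
        _, ped, _ = crossed
        comp = ped.table[ped.table["breed"] == "C"]
        assert len(comp) > 0
        assert np.abs(comp["zebu_fraction"] - 0.375).max() < 1e-12

    def test_topological_order_and_acyclicity(self, crossed):
        _, ped, _ = crossed
        n = len(ped)
        idx = np.arange(n)
        assert np.all(ped.sire_idx < idx) and np.all(ped.dam_idx < idx)
        # no animal is its own ancestor: walk ancestor sets
        for i in range(n - 20, n):
            stack, seen = [i], set()
            while stack:
                j = stack.pop()
                for p in (ped.sire_idx[j], ped.dam_idx[j]):
                    if p >= 0 and p not in seen:
                        assert p != i
                        seen.add(p)
                        stack.append(p)

    def test_undefined_composite_parent_rejected(self):
        specs = [sd.BreedSpec(label="P", role="founder-taurine", n_founders=20),
                 sd.BreedSpec(label="C", role="composite", parents={"X": 1.0}, n_founders=5)]
        founders = sd.simulate_founder_haplotypes(50, specs, seed=0)
        with pytest.raises(ValueError, match="undefined"):
            sd.simulate_pedigree_and_crosses(founders, specs, generations=0, seed=0)

    def test_non_dyadic_fractions_rejected(self):
        specs = _founder_specs(0.1, 20) + [
            sd.BreedSpec(label="C", role="composite", parents={"P": 2 / 3, "Q": 1 / 3},
                         n_founders=5, divergence=0.0)
        ]
        founders = sd.simulate_founder_haplotypes(50, specs, seed=0)
        with pytest.raises(ValueError, match="dyadic"):
            sd.simulate_pedigree_and_crosses(founders, specs, generations=0, seed=0)


def _two_trait_spec(h2a=0.3, h2b=0.4, rg=0.8, **kw):
    return sd.TraitSpec(
        breeds=["P", "Q"], heritability={"P": h2a, "Q": h2b},
        genetic_correlations=np.array([[1.0, rg], [rg, 1.0]]), **kw
    )


class TestBreedingValues:
    @pytest.fixture
    def panel(self):
        return sd.simulate_founder_haplotypes(400, _founder_specs(0.1, 250), seed=13)

    def test_zero_variance_trait_gives_zero_bv(self, panel):
        ts = _two_trait_spec(h2a=0.0)
        bv, _ = sd.simulate_breeding_values(panel, ts, n_qtl=100, seed=3)
        assert np.all(bv["P"].to_numpy() == 0.0)

    def test_effect_correlation_matches_target(self, panel):
        ts = _two_trait_spec(rg=0.8)
        big = sd.simulate_founder_haplotypes(1_200, _founder_specs(0.1, 100), seed=14)
        _, info = sd.simulate_breeding_values(big, ts, n_qtl=1_000, seed=4)
        r = np.corrcoef(info["effects"][:, 0], info["effects"][:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_realized_within_breed_variance_matches_spec(self, panel):
        ts = _two_trait_spec()
        bv, _ = sd.simulate_breeding_values(panel, ts, n_qtl=150, seed=5)
        for b, h2 in (("P", 0.3), ("Q", 0.4)):
            own = bv.set_index("id").loc[
                [i for i, br in zip(panel.sample_ids, panel.breed) if br == b], b
            ]
            assert own.var(ddof=0) == pytest.approx(h2, rel=1e-9)

    def test_clones_get_identical_breeding_values(self, panel):
        from tickblup.containers import GenotypePanel

        hap = np.vstack([panel.haplotypes, panel.haplotypes[:2]])
        clone = GenotypePanel(
            marker_map=panel.marker_map,
            sample_ids=panel.sample_ids + ["clone"],
            breed=np.append(panel.breed, panel.breed[0]),
            haplotypes=hap,
        )
        bv, _ = sd.simulate_breeding_values(clone, _two_trait_spec(), n_qtl=100, seed=6)
        bv = bv.set_index("id")
        assert np.allclose(bv.loc["clone"], bv.loc[panel.sample_ids[0]])

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            sd.TraitSpec(breeds=["P", "Q"], heritability={"P": 0.3, "Q": 0.3},
                         genetic_correlations=np.array([[1.0, 1.2], [1.2, 1.0]]))


class TestPhenotypes:
    def _sim(self, ts, seed=21, n=400):
        specs = _founder_specs(0.1, n)
        return sd.simulate_study(specs, ts, n_markers=150, n_qtl=50, generations=1,
                                 seed=seed)

    def test_zero_noise_phenotype_equals_breeding_value(self):
        ts = _two_trait_spec(h2a=1.0, h2b=1.0, cg_sd=0.0)
        ts.beta_zebu = ts.beta_het = ts.beta_age = ts.beta_age2 = 0.0
        sim = self._sim(ts, n=60)
        bv = sim.true_bv.set_index("id")
        for _, row in sim.phenotypes.iterrows():
            assert row["value"] == pytest.approx(bv.loc[row["animal"], row["breed"]], abs=1e-10)

    def test_seeded_phenotype_determinism(self):
        ts = _two_trait_spec(repeatability={"P": 0.5}, records_per_animal={"P": (1, 3)})
        a = self._sim(ts, n=80)
        b = self._sim(ts, n=80)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_variance_components_recovered_by_moments(self):
        # repeated-record breed: between/within animal decomposition
        ts = sd.TraitSpec(
            breeds=["P"], heritability={"P": 0.3}, repeatability={"P": 0.5},
            genetic_correlations=np.array([[1.0]]),
            records_per_animal={"P": (2, 2)}, cg_sd=0.0,
        )
        ts.beta_zebu = ts.beta_het = ts.beta_age = ts.beta_age2 = 0.0
        specs = [sd.BreedSpec(label="P", role="founder-taurine", divergence=0.1,
                              n_founders=2_000)]
        sim = sd.simulate_study(specs, ts, n_markers=200, n_qtl=60, generations=1,
                                seed=33, offspring_per_generation={"P": 10_000})
        rec = sim.phenotypes
        wide = rec.pivot_table(index="animal", columns="record", values="value")
        within = 0.5 * (wide[0] - wide[1]).var()  # estimates sigma2_e
        between = wide.mean(axis=1).var() - within / 2  # estimates sigma2_u + sigma2_pe
        assert within == pytest.approx(0.5, rel=0.1)
        assert between == pytest.approx(0.5, rel=0.1)

    def test_heritability_by_parent_offspring_regression(self):
        ts = sd.TraitSpec(breeds=["P"], heritability={"P": 0.4},
                          genetic_correlations=np.array([[1.0]]), cg_sd=0.0)
        ts.beta_zebu = ts.beta_het = ts.beta_age = ts.beta_age2 = 0.0
        specs = [sd.BreedSpec(label="P", role="founder-taurine", divergence=0.1,
                              n_founders=1_500)]
        sim = sd.simulate_study(specs, ts, n_markers=300, n_qtl=100, generations=1,
                                seed=44, offspring_per_generation={"P": 6_000})
        ped = sim.pedigree.table.set_index("id")
        # phenotype founders too (single records, pure u + e)
        all_ids = ped.index.tolist()
        phen, _ = sd.simulate_phenotypes(
            sim.true_bv, sim.pedigree, ts, seed=45, phenotyped_ids={"P": all_ids}
        )
        y = phen.set_index("animal")["value"]
        kids = ped[ped["sire"] != "0"]
        slope = np.polyfit(y.loc[kids["sire"]].to_numpy(), y.loc[kids.index].to_numpy(), 1)[0]
        # offspring-on-one-parent regression estimates h2 / 2
        assert 2 * slope == pytest.approx(0.4, abs=0.05)

    def test_missing_breeding_value_rejected(self):
        ts = _two_trait_spec()
        sim = self._sim(ts, n=50)
        bad_bv = sim.true_bv.iloc[:-5]
        with pytest.raises(ValueError, match="lack breeding values"):
            sd.simulate_phenotypes(bad_bv, sim.pedigree, ts, seed=1)
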