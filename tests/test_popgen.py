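"""LD, persistence of phase, allele-frequency correlation, PCA of G."""

import numpy as np
import pandas as pd
import pytest

from tickblup import popgen, synthdata


def _map(m, chrom=None):
    return pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else np.ones(m, dtype=int),
            "pos": np.arange(1, m + 1),
        }
    )


def _haps_from_counts(counts):
    """Haplotype matrix with the given AB/Ab/aB/ab counts at two markers."""
    rows = (
        [[1, 1]] * counts[0] + [[1, 0]] * counts[1] + [[0, 1]] * counts[2] + [[0, 0]] * counts[3]
    )
    return np.array(rows, dtype=np.uint8)


class TestAdjacentLD:
    def test_complete_coupling(self):
        ld = popgen.adjacent_ld(_map(2), haplotypes=_haps_from_counts((50, 0, 0, 50)))
        assert ld["r"].iloc[0] == pytest.approx(1.0)
        assert ld["r2"].iloc[0] == pytest.approx(1.0)

    def test_linkage_equilibrium(self):
        # haplotype frequencies equal to the product of allele frequencies
        ld = popgen.adjacent_ld(_map(2), haplotypes=_haps_from_counts((25, 25, 25, 25)))
        assert ld["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_r2(self):
        # p_AB=0.4, p_Ab=0.1, p_aB=0.1, p_ab=0.4 with p_A=p_B=0.5 -> r2 = 0.36
        ld = popgen.adjacent_ld(_map(2), haplotypes=_haps_from_counts((40, 10, 10, 40)))
        assert ld["r2"].iloc[0] == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_pair_flagged_undefined(self):
        h = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.uint8)
        ld = popgen.adjacent_ld(_map(2), haplotypes=h)
        assert not ld["defined"].iloc[0]

    def test_chromosome_boundary_pairs_skipped(self, rng):
        h = rng.integers(0, 2, size=(40, 6)).astype(np.uint8)
        ld = popgen.adjacent_ld(_map(6, chrom=[1, 1, 1, 2, 2, 2]), haplotypes=h)
        assert len(ld) == 4
        assert set(ld["chrom"]) == {1, 2}

    def test_phased_equals_bruteforce_pearson(self, rng):
        h = rng.integers(0, 2, size=(80, 30)).astype(np.uint8)
        ld = popgen.adjacent_ld(_map(30), haplotypes=h)
        for _, row in ld[ld["defined"]].iterrows():
            brute = np.corrcoef(h[:, int(row.i)], h[:, int(row.j)])[0, 1]
            assert row.r == pytest.approx(brute, abs=1e-12)

    def test_em_converges_to_phased_r(self):
        spec = [synthdata.BreedSpec(label="X", role="founder-taurine", divergence=0.1,
                                    n_founders=2_000)]
        panel = synthdata.simulate_founder_haplotypes(300, spec, seed=4)
        ld_phased = popgen.adjacent_ld(panel.marker_map, haplotypes=panel.haplotypes)
        ld_em = popgen.adjacent_ld(panel.marker_map, dosages=panel.dosages)
        ok = (ld_phased["defined"] & ld_em["defined"]).to_numpy()
        diff = np.abs(ld_phased["r"].to_numpy()[ok] - ld_em["r"].to_numpy()[ok])
        assert np.quantile(diff, 0.95) < 0.02
        assert diff.mean() < 0.005

    def test_allele_flip_flips_signs_locally(self, rng):
        h = rng.integers(0, 2, size=(60, 10)).astype(np.uint8)
        ld = popgen.adjacent_ld(_map(10), haplotypes=h)
        flipped = h.copy()
        flipped[:, 4] = 1 - flipped[:, 4]
        ld_f = popgen.adjacent_ld(_map(10), haplotypes=flipped)
        ok = (ld["defined"] & ld_f["defined"]).to_numpy()
        assert np.allclose(ld_f["r2"].to_numpy()[ok], ld["r2"].to_numpy()[ok], atol=1e-12)
        involves_4 = ((ld["i"] == 4) | (ld["j"] == 4)).to_numpy()
        sign = np.where(involves_4, -1.0, 1.0)
        assert np.allclose(ld_f["r"].to_numpy()[ok], (sign * ld["r"])[ok], atol=1e-12)


class TestPhasePersistence:
    def test_identical_vectors_give_one(self, rng):
        h = rng.integers(0, 2, size=(50, 20)).astype(np.uint8)
        ld = popgen.adjacent_ld(_map(20), haplotypes=h)
        res = popgen.phase_persistence(ld, ld.copy())
        assert res.overall == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, rng):
        h = rng.integers(0, 2, size=(50, 20)).astype(np.uint8)
        ld = popgen.adjacent_ld(_map(20), haplotypes=h)
        ld_neg = ld.copy()
        ld_neg["r"] = -ld_neg["r"]
        assert popgen.phase_persistence(ld, ld_neg).overall == pytest.approx(-1.0)

    def test_textbook_pearson_example(self):
        ra = np.array([0.1, 0.5, -0.2, 0.3])
        rb = np.array([0.2, 0.4, 0.0, 0.1])
        # explicit-sum Pearson computation as the oracle
        ca, cb = ra - ra.mean(), rb - rb.mean()
        expected = (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())
        tmpl = pd.DataFrame(
            {"chrom": 1, "i": range(4), "j": range(1, 5),
             "snp_i": [f"s{j}" for j in range(4)], "snp_j": [f"s{j}" for j in range(1, 5)],
             "r": ra, "r2": ra**2, "defined": True}
        )
        other = tmpl.copy()
        other["r"] = rb
        res = popgen.phase_persistence(tmpl, other)
        assert res.overall == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        tmpl = pd.DataFrame(
            {"chrom": 1, "i": range(3), "j": range(1, 4),
             "snp_i": list("abc"), "snp_j": list("bcd"),
             "r": [0.2, 0.2, 0.2], "r2": [0.04] * 3, "defined": True}
        )
        other = tmpl.copy()
        other["r"] = [0.1, 0.3, 0.2]
        assert np.isnan(popgen.phase_persistence(tmpl, other).overall)


class TestAlleleFreqCorrelation:
    def test_identical_and_flipped(self, rng):
        f = rng.uniform(0.05, 0.95, 200)
        assert popgen.allele_freq_correlation(f, f) == pytest.approx(1.0)
        assert popgen.allele_freq_correlation(f, 1 - f) == pytest.approx(-1.0)

    def test_matches_reference_routine_on_drifted_breeds(self):
        specs = [
            synthdata.BreedSpec(label=l, role="founder-taurine", divergence=0.2, n_founders=150)
            for l in ("P", "Q")
        ]
        panel = synthdata.simulate_founder_haplotypes(800, specs, seed=9)
        fa = panel.allele_frequencies("P")
        fb = panel.allele_frequencies("Q")
        assert popgen.allele_freq_correlation(fa, fb) == pytest.approx(
            float(np.corrcoef(fa, fb)[0, 1]), abs=1e-12
        )

    def test_degenerate_undefined(self):
        assert np.isnan(popgen.allele_freq_correlation([0.5], [0.5]))
        assert np.isnan(popgen.allele_freq_correlation([0.5, 0.5], [0.1, 0.9]))


class TestGrmPca:
    def test_identity_equal_fractions(self):
        scores, frac = popgen.grm_pca(np.eye(6), n_components=6)
        assert np.allclose(frac, 1 / 6)

    def test_rank_one_explains_everything(self, rng):
        v = rng.normal(0, 1, 8)
        scores, frac = popgen.grm_pca(np.outer(v, v))
        assert frac[0] == pytest.approx(1.0)

    def test_two_group_structure_separates_groups(self):
        # two unrelated groups after centering: within +0.5, between -0.5
        s = np.r_[np.ones(4), -np.ones(4)]
        G = 0.5 * np.outer(s, s) + 0.5 * np.eye(8)
        scores, _ = popgen.grm_pca(G, n_components=2)
        lead = scores[:, 0]
        assert np.all(np.sign(lead[:4]) == -np.sign(lead[4:]))

    def test_asymmetric_rejected(self):
        M = np.eye(3)
        M[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            popgen.grm_pca(M)
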