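import numpy as np
import pandas as pd
import pytest

from pedherit import (
    CohortSpec,
    CorrelationStructure,
    TraitGenSpec,
    compute_kinship,
    generate_ogtt,
    generate_pedigree,
    generate_phenotypes,
    matsuda_isi,
    relative_pairs,
    simulate_cohort,
)


class TestGeneratePedigree:
    def test_single_family_two_children(self):
        spec = CohortSpec(n_nuclear_families=1, children_probs={2: 1.0}, seed=1)
        ped = generate_pedigree(spec)
        assert len(ped) == 4
        kin = compute_kinship(ped)
        c1, c2 = ped.leaves()
        assert kin.phi(c1, c2) == 0.25

    def test_no_linking_keeps_families_disjoint(self):
        spec = CohortSpec(n_nuclear_families=30, extended_linking=0.0, seed=2)
        ped = generate_pedigree(spec)
        kin = compute_kinship(ped)
        fams = {i.family_id for i in ped.individuals}
        assert len(fams) == 30
        # all related pairs are within nuclear families: phi in {0.25}
        long = kin.to_long()
        assert set(np.round(long["phi"], 4)) <= {0.25}

    def test_linking_creates_avuncular_and_cousin_pairs(self):
        spec = CohortSpec(n_nuclear_families=200, extended_linking=0.5, seed=3)
        ped = generate_pedigree(spec)
        kin = compute_kinship(ped)
        table = relative_pairs(ped, kin, ids=ped.leaves())
        counts = table.set_index("pair_class")["count"]
        assert counts["phi=0.125 (half sibs / avuncular / grandparental)"] > 0
        assert counts["phi=0.0625 (first cousins)"] > 0

    def test_default_scale_matches_study_design(self):
        ped = generate_pedigree(CohortSpec(seed=7))
        children = ped.leaves()
        # ~670 phenotyped children from 401 nuclear families
        assert 600 <= len(children) <= 740
        kin = compute_kinship(ped)
        total = relative_pairs(ped, kin, ids=children).set_index(
            "pair_class"
        )["count"]["total related"]
        # related-pair count is only calibrated in order of magnitude
        assert 150 <= total <= 36_640

    def test_deterministic_under_seed(self):
        p1 = generate_pedigree(CohortSpec(n_nuclear_families=40, seed=11))
        p2 = generate_pedigree(CohortSpec(n_nuclear_families=40, seed=11))
        assert p1.ids == p2.ids
        assert [i.father_id for i in p1.individuals] == [
            i.father_id for i in p2.individuals
        ]


class TestGeneratePhenotypes:
    def test_degenerate_full_heritability_identical_latents(self):
        spec = CohortSpec(n_nuclear_families=40, seed=5)
        ped = generate_pedigree(spec)
        traits = [
            TraitGenSpec("a", 0.0, 1.0, 1.0),
            TraitGenSpec("b", 0.0, 1.0, 1.0),
        ]
        corr = CorrelationStructure.from_pairs(
            ["a", "b"], {("a", "b"): 1.0}, {}
        )
        df = generate_phenotypes(ped, traits, corr, rng=5, spec=spec)
        assert np.corrcoef(df["a"], df["b"])[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_zero_heritability_kills_sib_correlation(self):
        sib1, sib2 = [], []
        for seed in range(5):
            spec = CohortSpec(
                n_nuclear_families=1000, children_probs={2: 1.0},
                extended_linking=0.0, seed=600 + seed,
            )
            ped = generate_pedigree(spec)
            df = generate_phenotypes(
                ped, [TraitGenSpec("t", 0.0, 1.0, 0.0)], rng=600 + seed,
                spec=spec,
            )
            vals = df.set_index("id")["t"]
            sib1.append(vals.iloc[0::2].to_numpy())
            sib2.append(vals.iloc[1::2].to_numpy())
        r = np.corrcoef(np.concatenate(sib1), np.concatenate(sib2))[0, 1]
        assert abs(r) < 0.03

    def test_phenotypic_correlation_matches_decomposition(self):
        """Pooled cohorts reproduce the decomposition-implied correlation."""
        h2 = (0.58, 0.64)
        rho_g, rho_e = 0.62, -0.19
        implied = np.sqrt(h2[0] * h2[1]) * rho_g + np.sqrt(
            (1 - h2[0]) * (1 - h2[1])
        ) * rho_e
        traits = [
            TraitGenSpec("t1", 0.0, 1.0, h2[0]),
            TraitGenSpec("t2", 0.0, 1.0, h2[1]),
        ]
        corr = CorrelationStructure.from_pairs(
            ["t1", "t2"], {("t1", "t2"): rho_g}, {("t1", "t2"): rho_e}
        )
        xs, ys = [], []
        for seed in range(15):
            spec = CohortSpec(n_nuclear_families=1000, seed=900 + seed)
            ped = generate_pedigree(spec)
            df = generate_phenotypes(ped, traits, corr, rng=900 + seed, spec=spec)
            xs.append(df["t1"].to_numpy())
            ys.append(df["t2"].to_numpy())
        r = np.corrcoef(np.concatenate(xs), np.concatenate(ys))[0, 1]
        assert r == pytest.approx(implied, abs=0.02)

    def test_lognormal_transform_matches_target_moments(self):
        spec = CohortSpec(n_nuclear_families=1500, children_probs={2: 1.0},
                          extended_linking=0.0, seed=8)
        ped = generate_pedigree(spec)
        df = generate_phenotypes(
            ped, [TraitGenSpec("lyc", 0.41, 0.58, 0.5, transform="exp")],
            rng=8, spec=spec,
        )
        assert df["lyc"].min() > 0
        assert df["lyc"].mean() == pytest.approx(0.41, rel=0.05)
        # the SD of a cv~1.4 log-normal has ~10% sampling error at this n
        assert df["lyc"].std() == pytest.approx(0.58, rel=0.25)

    def test_nonpsd_structure_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            CorrelationStructure.from_pairs(
                ["a", "b", "c"],
                {("a", "b"): 0.9, ("b", "c"): 0.9, ("a", "c"): -0.9},
            )


class TestGenerateOgtt:
    def test_fasting_glucose_calibration(self):
        rng = np.random.default_rng(10)
        ogtt = generate_ogtt(rng.standard_normal(10_000), rng)
        assert ogtt["glucose_0"].mean() == pytest.approx(89.5, abs=0.5)
        assert ogtt["glucose_0"].std() == pytest.approx(7.5, abs=1.0)

    def test_zero_noise_isi_strictly_decreasing_in_latent(self):
        lat = np.linspace(-2.5, 2.5, 60)
        ogtt = generate_ogtt(lat, rng=1, noise=0.0)
        g = ogtt[[c for c in ogtt.columns if c.startswith("glucose")]].to_numpy()
        i = ogtt[[c for c in ogtt.columns if c.startswith("insulin")]].to_numpy()
        isi = matsuda_isi(g, i)
        assert (np.diff(isi) < 0).all()

    def test_bit_identical_under_fixed_seed(self):
        lat = np.random.default_rng(3).standard_normal(100)
        a = generate_ogtt(pd.Series(lat), rng=123)
        b = generate_ogtt(pd.Series(lat), rng=123)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateCohort:
    def test_full_cohort_reproducible_and_complete(self):
        traits = [TraitGenSpec("lyc", 0.41, 0.58, 0.98, transform="exp")]
        c1 = simulate_cohort(CohortSpec(n_nuclear_families=50), traits, seed=42,
                             ogtt=True)
        c2 = simulate_cohort(CohortSpec(n_nuclear_families=50), traits, seed=42,
                             ogtt=True)
        pd.testing.assert_frame_equal(c1.phenotypes, c2.phenotypes)
        assert {"lyc", "glucose_0", "insulin_120"} <= set(c1.phenotypes.columns)
        assert len(c1.phenotypes) == len(c1.pedigree.leaves())

    def test_carotenoid_effect_raises_isi_at_high_levels(self):
        traits = [
            TraitGenSpec("car", 0.5, 0.3, 0.8, transform="exp"),
            TraitGenSpec("ins", 13.6, 9.4, 0.55, transform="exp"),
        ]
        coh = simulate_cohort(
            CohortSpec(n_nuclear_families=600), traits, seed=9, ogtt=True,
            ir_source="ins", carotenoid_effects={"car": 0.8},
        )
        df = coh.phenotypes
        g = df[[c for c in df.columns if c.startswith("glucose")]].to_numpy()
        i = df[[c for c in df.columns if c.startswith("insulin")]].to_numpy()
        isi = matsuda_isi(g, i)
        hi = df["car"] > df["car"].median()
        assert np.log(isi[hi.to_numpy()]).mean() > np.log(isi[~hi.to_numpy()]).mean()
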