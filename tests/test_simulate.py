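import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tfcrosstalk.diffbind import nb_wald
from tfcrosstalk.simulate import (
    AHR_MOTIF,
    HIF_MOTIF,
    OccupancyModel,
    default_model,
    make_gene_table,
    simulate_chip,
    simulate_cohort,
    simulate_genome,
    simulate_occupancy,
    simulate_region_counts,
    simulate_rna,
)

from conftest import make_site_table


class TestOccupancy:
    def test_single_active_factor_closed_form(self, single_site_model):
        # f_AHR = 1/(1+1) = 1/2; occ = 10 * 1/2
        occ = simulate_occupancy(single_site_model, "ahr_only")
        assert occ["AHR"].iloc[0] == pytest.approx(5.0)

    def test_trans_antagonism_closed_form(self, single_site_model):
        # activating HIF1 dilutes the shared pool: 10/(1+1+1) = 3.333
        occ = simulate_occupancy(single_site_model, "ahr_plus_hif")
        assert occ["AHR"].iloc[0] == pytest.approx(10.0 / 3.0)

    def test_cis_mitigation_closed_form(self):
        sites = make_site_table([("s1", 100, 500, "AHR&HIF1", 10.0, {"AHR": 280, "HIF1": 320})])
        m = OccupancyModel(
            activities={"both": {"AHR": 1.0, "HIF1": 1.0, "HIF2": 0.0}},
            K=1.0,
            gamma=1.0,
            sites=sites,
        )
        occ = simulate_occupancy(m, "both")
        assert occ["AHR"].iloc[0] == pytest.approx(10.0 / 3.0 * (1 + 1.0 / 3.0))

    def test_unknown_condition_raises(self, single_site_model):
        with pytest.raises(KeyError):
            simulate_occupancy(single_site_model, "no_such_condition")

    def test_zero_activity_gives_zero_occupancy(self):
        sites = make_site_table([("s1", 100, 500, "AHR", 1.0, {"AHR": 300})])
        m = OccupancyModel(
            activities={"off": {"AHR": 0.0, "HIF1": 0.0, "HIF2": 0.0}}, sites=sites
        )
        occ = simulate_occupancy(m, "off")
        assert occ[["AHR", "HIF1", "HIF2", "ARNT"]].to_numpy().sum() == 0.0

    @given(a_hif=st.floats(0.01, 5.0), a_hif_more=st.floats(0.01, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_antagonism(self, a_hif, a_hif_more):
        """AHR occupancy strictly decreases as competing HIF activity rises."""
        lo, hi = sorted({a_hif, a_hif + a_hif_more})
        sites = make_site_table([("s1", 100, 500, "AHR", 1.0, {"AHR": 300})])
        m = OccupancyModel(
            activities={
                "low": {"AHR": 1.0, "HIF1": lo, "HIF2": 0.0},
                "high": {"AHR": 1.0, "HIF1": hi, "HIF2": 0.0},
            },
            sites=sites,
        )
        occ_lo = simulate_occupancy(m, "low")["AHR"].iloc[0]
        occ_hi = simulate_occupancy(m, "high")["AHR"].iloc[0]
        assert occ_hi < occ_lo

    def test_dimer_fractions_sum_below_one(self):
        m = OccupancyModel(activities={"c": {"AHR": 5.0, "HIF1": 9.0, "HIF2": 3.0}}, K=0.5)
        f = m.dimer_fractions("c")
        assert all(0 <= v <= 1 for v in f.values())
        assert sum(f.values()) < 1

    @pytest.mark.parametrize("gamma", [0.0, 0.5, 1.0])
    def test_cis_mitigation_ratio_property(self, gamma):
        """The hypoxia/normoxia occupancy ratio at shared AHR-HIF1 sites
        exceeds the same ratio at AHR-only sites iff gamma > 0."""
        sites = make_site_table(
            [
                ("indiv", 1000, 1400, "AHR", 1.0, {"AHR": 1200}),
                ("shared", 3000, 3400, "AHR&HIF1", 1.0, {"AHR": 3180, "HIF1": 3220}),
            ]
        )
        m = OccupancyModel(
            activities={
                "normoxia_ITE": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0},
                "hypoxia_ITE": {"AHR": 1.0, "HIF1": 1.0, "HIF2": 0.0},
            },
            gamma=gamma,
            sites=sites,
        )
        occ_n = simulate_occupancy(m, "normoxia_ITE")["AHR"]
        occ_h = simulate_occupancy(m, "hypoxia_ITE")["AHR"]
        ratio_indiv = occ_h["indiv"] / occ_n["indiv"]
        ratio_shared = occ_h["shared"] / occ_n["shared"]
        if gamma > 0:
            assert ratio_shared > ratio_indiv
        else:
            assert ratio_shared == pytest.approx(ratio_indiv)


class TestChipNoise:
    def test_poisson_limit_variance(self, rng):
        counts = simulate_region_counts(
            OccupancyModel(
                activities={"c": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0}},
                sites=make_site_table(
                    [(f"s{i}", 1000 * i + 100, 1000 * i + 500, "AHR", 0.09, {"AHR": 1000 * i + 300})
                     for i in range(1, 11)]
                ),
            ),
            "c", "AHR", n_replicates=1000, rng=rng, scale=1000.0, background=5.0, dispersion=0.0,
        )
        # lambda = 5 + 1000 * 0.09 * 0.5 = 50; alpha = 0 is Poisson
        row = counts.iloc[0].to_numpy()
        assert row.var(ddof=1) == pytest.approx(50.0, rel=0.10)
        assert row.mean() == pytest.approx(50.0, rel=0.05)

    def test_nb_moments(self, rng):
        lam, alpha = 80.0, 0.2
        sites = make_site_table([("s1", 100, 500, "AHR", (lam - 5.0) / 1000 / 0.5, {"AHR": 300})])
        m = OccupancyModel(activities={"c": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0}}, sites=sites)
        counts = simulate_region_counts(
            m, "c", "AHR", n_replicates=20_000, rng=rng, scale=1000.0, background=5.0,
            dispersion=alpha,
        ).iloc[0].to_numpy()
        assert counts.mean() == pytest.approx(lam, rel=0.02)
        assert counts.var(ddof=1) == pytest.approx(lam + alpha * lam**2, rel=0.08)

    def test_zero_occupancy_counts_match_background(self, rng):
        sites = make_site_table([(f"s{i}", 2000 * i, 2000 * i + 400, "AHR", 1.0, {"AHR": 2000 * i + 200})
                                 for i in range(1, 30)])
        m = OccupancyModel(activities={"off": {"AHR": 0.0, "HIF1": 0.0, "HIF2": 0.0}}, sites=sites)
        counts = simulate_region_counts(m, "off", "AHR", n_replicates=50, rng=rng, background=5.0)
        assert counts.to_numpy().mean() == pytest.approx(5.0, rel=0.05)

    def test_seed_determinism(self, single_site_model):
        t1, c1 = simulate_chip(single_site_model, "ahr_only", "AHR", 10_000, seed=42)
        t2, c2 = simulate_chip(single_site_model, "ahr_only", "AHR", 10_000, seed=42)
        np.testing.assert_array_equal(t1[0].data["chrS"], t2[0].data["chrS"])
        pd.testing.assert_frame_equal(c1, c2)

    def test_replicate_count_validation(self, single_site_model):
        with pytest.raises(ValueError):
            simulate_chip(single_site_model, "ahr_only", "AHR", 10_000, n_replicates=0)


class TestGenome:
    def test_planted_motifs_present(self, rng):
        model = default_model(rng, genome_length=200_000,
                              class_counts={"AHR": 5, "HIF1": 5, "AHR&HIF1": 5})
        genome = simulate_genome(model, 200_000, seed=3)
        seq = genome["chrS"]
        comp = str.maketrans("ACGT", "TGCA")
        for _, row in model.sites.iterrows():
            for fac, motif in (("AHR", AHR_MOTIF), ("HIF1", HIF_MOTIF)):
                pos = row[f"motif_{fac}"]
                if pos < 0:
                    continue
                expected = motif if row["strand"] == "+" else motif.translate(comp)[::-1]
                start = int(pos) - len(motif) // 2
                assert seq[start : start + 5] == expected

    def test_shared_sites_have_offset_motifs(self, rng):
        model = default_model(rng, genome_length=100_000, class_counts={"AHR&HIF1": 8},
                              motif_offset=40)
        shared = model.sites
        assert ((shared["motif_HIF1"] - shared["motif_AHR"]).abs() == 40).all()


class TestRna:
    def test_null_genes_give_uniform_p(self):
        """With beta = 0 the two-group NB Wald p-values are uniform."""
        sites = make_site_table([("s1", 1000, 1400, "AHR", 1.0, {"AHR": 1200})])
        m = OccupancyModel(
            activities={
                "c1": {"AHR": 0.0, "HIF1": 0.0, "HIF2": 0.0},
                "c2": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0},
            },
            sites=sites,
        )
        genes = pd.DataFrame(
            {
                "chrom": "chrS",
                "tss": np.arange(2000),
                "strand": "+",
                "linked_site": "",
                "beta": 0.0,
                "base_mean": 200.0,
            },
            index=[f"g{i}" for i in range(2000)],
        )
        counts = simulate_rna(genes, m, ["c1", "c2"], n_replicates=6, dispersion=0.05, seed=11)
        g1 = counts[[c for c in counts if c.startswith("c1")]]
        g2 = counts[[c for c in counts if c.startswith("c2")]]
        res = nb_wald(g1, g2, alpha=0.05)
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_known_effect_recovery(self):
        """beta = 1 with occupancy going 0 -> max yields log2FC ~ 1."""
        sites = make_site_table([("s1", 1000, 1400, "AHR", 1.0, {"AHR": 1200})])
        m = OccupancyModel(
            activities={
                "off": {"AHR": 0.0, "HIF1": 0.0, "HIF2": 0.0},
                "on": {"AHR": 1.0, "HIF1": 0.0, "HIF2": 0.0},
            },
            sites=sites,
        )
        genes = pd.DataFrame(
            {
                "chrom": "chrS",
                "tss": 1200,
                "strand": "+",
                "linked_site": "s1",
                "beta": 1.0,
                "base_mean": 300.0,
            },
            index=[f"g{i}" for i in range(200)],
        )
        counts = simulate_rna(genes, m, ["off", "on"], n_replicates=6, dispersion=0.05, seed=5)
        g1 = counts[[c for c in counts if c.startswith("off")]]
        g2 = counts[[c for c in counts if c.startswith("on")]]
        res = nb_wald(g1, g2, alpha=0.05, epsilon=0.5)
        assert res["log2fc"].mean() == pytest.approx(1.0, abs=0.1)

    def test_seed_reproducibility(self, single_site_model):
        genes = make_gene_table(single_site_model, np.random.default_rng(0), n_null_genes=5,
                                genome_length=10_000)
        c1 = simulate_rna(genes, single_site_model, ["ahr_only"], seed=9)
        c2 = simulate_rna(genes, single_site_model, ["ahr_only"], seed=9)
        pd.testing.assert_frame_equal(c1, c2)


class TestCohort:
    def test_single_pair_metadata(self):
        expr, meta = simulate_cohort(1, {"HIF": ["g1"], "AHR": ["g2"]}, seed=0)
        assert len(meta) == 2
        assert meta["patient"].nunique() == 1
        assert set(meta["tissue"]) == {"normal", "tumour"}
        assert expr.shape[1] == 2

    def test_determinism(self):
        sig = {"HIF": [f"h{i}" for i in range(10)], "AHR": [f"a{i}" for i in range(10)]}
        e1, m1 = simulate_cohort(10, sig, seed=3)
        e2, m2 = simulate_cohort(10, sig, seed=3)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_tumour_shift_direction(self):
        sig = {"HIF": [f"h{i}" for i in range(30)], "AHR": [f"a{i}" for i in range(30)]}
        expr, meta = simulate_cohort(40, sig, delta_hif=0.8, delta_ahr=-0.8, sigma=0.5, seed=1)
        logx = np.log2(expr + 1)
        tum = meta.index[meta["tissue"] == "tumour"]
        nor = meta.index[meta["tissue"] == "normal"]
        hif_diff = logx.loc[sig["HIF"], tum].mean().mean() - logx.loc[sig["HIF"], nor].mean().mean()
        ahr_diff = logx.loc[sig["AHR"], tum].mean().mean() - logx.loc[sig["AHR"], nor].mean().mean()
        assert hif_diff > 0.3
        assert ahr_diff < -0.3
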