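"""Simulator, spatial sampling, sequencing and cohort generation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from spatialevo.simdata import (
    SimulationConfig,
    generate_cell_fractions,
    generate_clinical,
    generate_cohort,
    sample_regions,
    sequence_patient,
    sequence_region,
    simulate_tumor,
)
from spatialevo.simdata.cohort import CELL_TYPES, HOT_MEAN, COLD_MEAN


class TestSimulateTumor:
    def test_zero_mutation_rate_yields_no_somatic_mutations(self, fast_cfg):
        cfg = fast_cfg.with_updates(mutation_rate=0.0, n_founder_mutations=0)
        seed = 0
        while True:
            seed += 1
            st = simulate_tumor(cfg, seed=seed)
            if st.outcome == "target":
                break
        assert st.n_mutations == 0

    def test_extinction_is_reported_not_raised(self, fast_cfg):
        # crank death far above birth: certain extinction
        cfg = fast_cfg.with_updates(death_rate=0.9, birth_rate=0.1)
        st = simulate_tumor(cfg, seed=1)
        assert st.outcome == "extinct" and st.extinct
        assert st.n_cells == 0

    def test_invalid_config_rejected(self, fast_cfg):
        with pytest.raises(ValueError):
            simulate_tumor(fast_cfg.with_updates(upward_bias=1.5), seed=1)
        with pytest.raises(ValueError):
            simulate_tumor(fast_cfg.with_updates(deme_capacity=0), seed=1)

    def test_capacity_invariant(self, fast_state):
        cfg = fast_state.config
        deme = fast_state.rows * cfg.lattice_circumference + fast_state.cols
        occ = np.bincount(deme)
        assert occ.max() <= cfg.deme_capacity

    def test_determinism_bit_identical(self, fast_cfg):
        a = simulate_tumor(fast_cfg, seed=42)
        b = simulate_tumor(fast_cfg, seed=42)
        assert a.digest() == b.digest()

    def test_ancestry_monotonicity(self, fast_state):
        # child genotype subtree counts never exceed the parent's
        counts = fast_state.genotype_cell_counts()
        sub = fast_state.subtree_counts(counts)
        parent = fast_state.parent
        child_ids = np.arange(1, fast_state.n_genotypes)
        assert (sub[child_ids] <= sub[parent[child_ids]]).all()

    def test_neoantigen_fraction_matches_rate(self, fast_cfg):
        cfg = fast_cfg.with_updates(neoantigen_prob=0.2, n_founder_mutations=0)
        seed = 0
        while True:
            seed += 1
            st = simulate_tumor(cfg, seed=seed)
            if st.outcome == "target":
                break
        passengers = ~st.mut_is_driver
        n = int(passengers.sum())
        frac = st.mut_is_neo[passengers].mean()
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(frac - 0.2) < 3 * sd

    def test_symmetric_displacement_without_bias(self, fast_cfg):
        disps = []
        seed = 0
        while len(disps) < 25 and seed < 400:
            seed += 1
            st = simulate_tumor(fast_cfg, seed=seed)
            if st.outcome == "target":
                disps.append(st.centroid_displacement())
        assert len(disps) >= 20
        assert abs(np.mean(disps)) < 2.0

    def test_upward_bias_shifts_centroid(self, fast_cfg):
        cfg_b = fast_cfg.with_updates(upward_bias=0.6)
        d0, db = [], []
        seed = 0
        while (len(d0) < 15 or len(db) < 15) and seed < 600:
            seed += 1
            if len(d0) < 15:
                st = simulate_tumor(fast_cfg, seed=seed)
                if st.outcome == "target":
                    d0.append(st.centroid_displacement())
            if len(db) < 15:
                st = simulate_tumor(cfg_b, seed=seed + 1000)
                if st.outcome == "target":
                    db.append(st.centroid_displacement())
        # upward = decreasing row index: biased displacements more negative
        assert np.mean(db) < np.mean(d0)
        p = mannwhitneyu(db, d0, alternative="less").pvalue
        assert p < 0.01

    def test_immune_pressure_reduces_establishment(self, fast_cfg):
        # elimination phase: under a uniform hot field, incipient tumors
        # carrying clonal neoantigens are far less likely to establish
        from spatialevo.spatial import fisher_2x2
        base = fast_cfg.with_updates(neoantigen_prob=0.1)
        hot = base.with_updates(immune_kill=1.0, immune_field=0.001)
        n = 250
        s0 = sum(simulate_tumor(base, seed=s).outcome == "target"
                 for s in range(1, n + 1))
        s1 = sum(simulate_tumor(hot, seed=s).outcome == "target"
                 for s in range(10_001, 10_001 + n))
        assert s1 < s0
        _, p, _ = fisher_2x2([[s1, n - s1], [s0, n - s0]])
        assert p < 0.01


class TestSampling:
    def test_fixed_mutation_ccf_one_everywhere(self, fast_state):
        tt = sample_regions(fast_state)
        founder_ids = [i for i in range(fast_state.config.n_founder_mutations)
                       if i in tt.ccf.index]
        assert founder_ids
        assert np.allclose(tt.ccf.loc[founder_ids].to_numpy(), 1.0)

    def test_degenerate_single_deme(self, fast_cfg):
        # without migration the tumor never leaves the founder deme
        cfg = fast_cfg.with_updates(target_cells=15, deme_capacity=20,
                                    migration_rate=0.0)
        seed = 0
        while True:
            seed += 1
            st = simulate_tumor(cfg, seed=seed)
            if st.outcome == "target":
                break
        assert len(set(zip(st.rows, st.cols))) == 1
        tt = sample_regions(st, disk_radius=0)
        assert len(set(tt.anchors.values())) == 1
        vals = tt.ccf.to_numpy()
        assert np.allclose(vals, vals[:, [0]])

    def test_spatially_confined_mutation(self, fast_state):
        # a mutation present only in the upper half must have zero CCF in T3
        # when the upper and lower disks are disjoint
        tt = sample_regions(fast_state, disk_radius=1)
        if not {"T1", "T3"} <= set(tt.ccf.columns):
            pytest.skip("tumor too small for distinct T1/T3 disks")
        upper_only = tt.ccf[(tt.ccf["T1"] > 0)]
        rows = fast_state.rows
        mid = rows.mean()
        # use truth origin: mutations that arose in the upper quarter late
        cand = upper_only.index[
            np.asarray(fast_state.mut_origin_row[upper_only.index] < mid - 2)
        ]
        if len(cand) == 0:
            pytest.skip("no upper-confined mutations in this realization")
        assert (tt.ccf.loc[cand, "T3"] < tt.ccf.loc[cand, "T1"]).mean() > 0.5

    def test_extinct_tumor_rejected(self, fast_cfg):
        cfg = fast_cfg.with_updates(death_rate=0.9, birth_rate=0.1)
        st = simulate_tumor(cfg, seed=1)
        with pytest.raises(ValueError):
            sample_regions(st)


class TestSequencing:
    def test_clonal_pure_expected_vaf_half(self, rng):
        ccf = pd.Series(np.ones(4000))
        calls = sequence_region(ccf, depth=300, purity=1.0, seed=5)
        vaf = calls["alt_reads"] / calls["total_reads"]
        assert vaf.mean() == pytest.approx(0.5, abs=0.01)

    def test_zero_ccf_zero_alt(self):
        calls = sequence_region(pd.Series(np.zeros(100)), depth=300, purity=1.0, seed=5)
        assert (calls["alt_reads"] == 0).all()

    def test_binomial_mean_oracle(self):
        # CCF 0.8, purity 0.5 -> expected VAF 0.20
        ccf = pd.Series(np.full(2000, 0.8))
        calls = sequence_region(ccf, depth=300, purity=0.5, seed=5)
        vaf = calls["alt_reads"] / calls["total_reads"]
        assert vaf.mean() == pytest.approx(0.20, abs=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sequence_region(pd.Series([0.5]), depth=0, purity=1.0, seed=1)
        with pytest.raises(ValueError):
            sequence_region(pd.Series([0.5]), depth=300, purity=0.0, seed=1)
        with pytest.raises(ValueError):
            sequence_region(pd.Series([1.5]), depth=300, purity=1.0, seed=1)

    def test_bulk_matches_region_schema(self, rng):
        ccf = pd.DataFrame({"T1": [0.5, 0.2], "T5": [1.0, 0.0]})
        bulk = sequence_patient(ccf, 300, {"T1": 0.8, "T5": 0.7}, seed=3)
        single = sequence_region(ccf["T1"], 300, 0.8, seed=3, region="T1")
        assert list(bulk.columns) == list(single.columns)
        assert set(bulk["region"]) == {"T1", "T5"}


class TestCellFractions:
    def test_simplex_constraint(self, rng):
        df = generate_cell_fractions(["hot"] * 10 + ["cold"] * 10, 150, rng)
        sums = df.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (df.to_numpy() >= 0).all()

    def test_infinite_concentration_returns_means(self):
        df = generate_cell_fractions(["hot", "cold"], np.inf, 0)
        assert np.allclose(df.iloc[0].to_numpy(), HOT_MEAN, atol=1e-6)
        assert np.allclose(df.iloc[1].to_numpy(), COLD_MEAN, atol=1e-6)

    def test_hot_has_higher_cd8(self, rng):
        hot = generate_cell_fractions(["hot"] * 100, 200, rng)
        cold = generate_cell_fractions(["cold"] * 100, 200, rng)
        assert hot["CD8_T"].mean() > cold["CD8_T"].mean()

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            generate_cell_fractions(["hot"], concentration=-1.0)
        with pytest.raises(ValueError):
            generate_cell_fractions(["lukewarm"], 100)


class TestClinical:
    def test_no_drinkers_when_marginal_zero(self):
        df = generate_clinical(50, seed=1, marginals={"drinking": 0.0})
        assert not df["drinking"].any()

    def test_coupling_raises_drinker_beta(self):
        df = generate_clinical(200, seed=2, couple=True)
        d = df[df["drinking"]]["beta"].mean()
        nd = df[~df["drinking"]]["beta"].mean()
        assert d > nd

    def test_determinism(self):
        a = generate_clinical(30, seed=9)
        b = generate_clinical(30, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_age_range(self):
        df = generate_clinical(300, seed=3)
        assert df["age"].between(40, 80).all()


class TestCohort:
    @pytest.fixture(scope="class")
    def tiny_cohort_cfg(self):
        return SimulationConfig(
            lattice_circumference=20, lattice_length=30, deme_capacity=25,
            target_cells=500, mutation_rate=4.0, n_founder_mutations=30,
        )

    def test_determinism_identical_digests(self, tiny_cohort_cfg):
        a = generate_cohort(4, template=tiny_cohort_cfg, seed=7)
        b = generate_cohort(4, template=tiny_cohort_cfg, seed=7)
        assert a.digest() == b.digest()

    def test_region_counts_within_bounds(self, tiny_cohort_cfg):
        co = generate_cohort(6, template=tiny_cohort_cfg, seed=3)
        for pat, sub in co.calls.groupby("patient"):
            primary = [r for r in sub["region"].unique() if not r.startswith("LN")]
            assert 2 <= len(primary) <= 5
            assert "T5" in primary

    def test_truth_and_observed_share_ids(self, tiny_cohort_cfg):
        co = generate_cohort(3, template=tiny_cohort_cfg, seed=5)
        for pat, pt in co.truth.items():
            obs_ids = set(co.calls[co.calls["patient"] == pat]["mut_id"])
            truth_ids = set(pt.truth.ccf.index)
            assert obs_ids == truth_ids

    def test_extinction_resampling_reported(self, tiny_cohort_cfg):
        co = generate_cohort(4, template=tiny_cohort_cfg, seed=11)
        assert co.n_extinct_resampled >= 0
        assert all(pt.outcome != "extinct" for pt in co.truth.values())

    def test_cell_fractions_align_with_primary_regions(self, tiny_cohort_cfg):
        co = generate_cohort(4, template=tiny_cohort_cfg, seed=13)
        for pat, sub in co.cell_fractions.groupby("patient"):
            regs = set(sub["region"])
            call_regs = {r for r in co.calls[co.calls["patient"] == pat]["region"]
                         if not r.startswith("LN")}
            assert regs == call_regs
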