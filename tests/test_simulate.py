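"""Generators: determinism, degenerate configs, and distributional oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mthotspot as mh
from mthotspot.simulate import SimConfigError, expected_substitution_spectrum


class TestCohortGenerator:
    def test_seeded_runs_are_identical(self, toy_ref):
        cfg = mh.CohortSimConfig(n_tumors=200, seed=9)
        a, _ = mh.simulate_cohort(toy_ref, cfg)
        b, _ = mh.simulate_cohort(toy_ref, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_config_every_tumor_carries_spike(self, toy_ref):
        spike = mh.SpikedHotspot(pos=300, alt="T" if toy_ref.base(300) != "T" else "G",
                                 prob=1.0)
        cfg = mh.CohortSimConfig(
            n_tumors=50, mean_mutations_per_tumor=0.0, spiked_hotspots=(spike,), seed=1
        )
        calls, truth = mh.simulate_cohort(toy_ref, cfg)
        assert len(calls) == 50
        assert (calls["pos"] == 300).all()
        assert (calls["alt"] == spike.alt).all()
        assert truth["pos"].tolist() == [300]

    def test_total_snv_count_within_poisson_bounds(self, rcrs_ref):
        cfg = mh.CohortSimConfig(n_tumors=5000, mean_mutations_per_tumor=1.4, seed=21)
        calls, _ = mh.simulate_cohort(rcrs_ref, cfg)
        expected = 5000 * 1.4
        # within-tumor dedup removes a handful of position collisions at most
        assert abs(len(calls) - expected) < 3 * np.sqrt(expected) + 10

    def test_spike_in_blacklist_rejected(self, rcrs_ref):
        spike = mh.SpikedHotspot(pos=514, alt="A", prob=0.5)
        with pytest.raises(SimConfigError):
            mh.simulate_cohort(
                rcrs_ref, mh.CohortSimConfig(n_tumors=10, spiked_hotspots=(spike,))
            )

    def test_spike_alt_equal_to_reference_rejected(self, toy_ref):
        spike = mh.SpikedHotspot(pos=300, alt=toy_ref.base(300), prob=0.5)
        with pytest.raises(SimConfigError):
            mh.simulate_cohort(
                toy_ref, mh.CohortSimConfig(n_tumors=10, spiked_hotspots=(spike,))
            )

    def test_emitted_records_respect_contract(self, toy_ref):
        calls, _ = mh.simulate_cohort(toy_ref, mh.CohortSimConfig(n_tumors=500, seed=2))
        assert calls["tumor_vaf"].between(0.05, 1.0).all()
        assert calls["normal_vaf"].between(0.0, 0.01, inclusive="left").all()
        assert ((calls["alt_fwd"] + calls["alt_rev"]) >= 1).all()
        assert (calls["ref"] != calls["alt"]).all()
        # one row per (tumor, position)
        assert not calls.duplicated(subset=["sample_id", "pos"]).any()

    def test_spectrum_converges_to_configured_signature(self, rcrs_ref):
        cfg = mh.CohortSimConfig(n_tumors=20000, seed=4)
        calls, _ = mh.simulate_cohort(rcrs_ref, cfg)
        region = np.where(
            rcrs_ref._control_mask[calls["pos"].to_numpy() - 1],
            "control",
            "noncontrol",
        )
        sub = calls["ref"].str.cat(calls["alt"], sep=">")
        observed = pd.Series(1, index=[region, sub]).groupby(level=[0, 1]).sum()
        expected = expected_substitution_spectrum(rcrs_ref)
        expected = expected[expected > 0]
        obs = observed.reindex(expected.index, fill_value=0)
        chi2 = stats.chisquare(obs, expected * obs.sum())
        assert chi2.pvalue > 0.001

    def test_strand_asymmetry_reverses_in_control_region(self, rcrs_ref):
        calls, _ = mh.simulate_cohort(
            rcrs_ref, mh.CohortSimConfig(n_tumors=10000, seed=6)
        )
        in_ctrl = rcrs_ref._control_mask[calls["pos"].to_numpy() - 1]
        sub = calls["ref"].str.cat(calls["alt"], sep=">")
        pyr = sub.isin(["C>T", "T>C"])
        # pyrimidine-strand substitutions dominate outside, purine inside
        assert pyr[~in_ctrl].mean() > 0.6
        assert pyr[in_ctrl].mean() < 0.4


class TestGermlineGenerator:
    def test_only_constrained_positions_when_no_polymorphic(self, toy_ref):
        table = mh.simulate_germline_table(toy_ref, n_constrained=50, n_polymorphic=0,
                                           seed=3)
        assert all(table.is_constrained(p) for p in table.carriers)

    def test_polymorphic_positions_have_at_least_two_carriers(self, toy_ref):
        table = mh.simulate_germline_table(toy_ref, 20, 30, seed=3)
        counts = sorted(table.carriers.values())
        assert sum(c >= 2 for c in counts) == 30

    def test_absent_position_reads_zero(self, toy_ref):
        table = mh.simulate_germline_table(toy_ref, 5, 5, seed=3)
        absent = next(p for p in range(1, toy_ref.length) if p not in table.carriers)
        assert table.count(absent) == 0

    def test_seeded_reproducibility(self, toy_ref):
        a = mh.simulate_germline_table(toy_ref, 10, 10, seed=8)
        b = mh.simulate_germline_table(toy_ref, 10, 10, seed=8)
        assert a.carriers == b.carriers

    def test_requesting_too_many_positions_raises(self, toy_ref):
        with pytest.raises(SimConfigError):
            mh.simulate_germline_table(toy_ref, 1500, 1500, seed=0)


class TestAnnotationGenerator:
    def test_covers_every_rrna_position_once(self, rcrs_ref):
        ann = mh.simulate_annotations(rcrs_ref, seed=2)
        expected = sum(
            len(rcrs_ref.gene_positions(g)) for g in ("MT-RNR1", "MT-RNR2")
        )
        assert len(ann) == expected
        assert not ann["pos"].duplicated().any()
        assert set(ann["structure_class"]) <= {"WC", "non-WC", "loop-or-other"}

    def test_class_proportions_follow_config(self, rcrs_ref):
        ann = mh.simulate_annotations(rcrs_ref, seed=2, class_probs=(1.0, 0.0, 0.0))
        assert (ann["structure_class"] == "WC").all()

    def test_elevated_positions_shift_conservation(self, rcrs_ref):
        hot = rcrs_ref.gene_positions("MT-RNR1")[:40]
        ann = mh.simulate_annotations(rcrs_ref, seed=2, elevated_positions=hot)
        hi = ann.loc[ann["pos"].isin(hot), "conservation"]
        lo = ann.loc[~ann["pos"].isin(hot), "conservation"]
        _, p = mh.conservation_comparison(hi, lo)
        assert p < 0.01
        assert hi.mean() > lo.mean()


class TestSingleCellGenerator:
    def test_seeded_runs_identical(self):
        cfg = mh.SingleCellSimConfig(n_cells=300, n_genes=20, seed=5)
        ac_a, ad_a, tr_a = mh.simulate_singlecell(cfg)
        ac_b, ad_b, tr_b = mh.simulate_singlecell(cfg)
        pd.testing.assert_frame_equal(ac_a, ac_b)
        assert (ad_a.X != ad_b.X).nnz == 0
        np.testing.assert_array_equal(tr_a["heteroplasmy"], tr_b["heteroplasmy"])

    def test_zero_effect_correlations_center_on_zero(self):
        cfg = mh.SingleCellSimConfig(n_cells=1500, n_genes=30, seed=6,
                                     qc_violation_rate=0.0)
        ac, adata, _ = mh.simulate_singlecell(cfg)
        cells = mh.qc_filter_cells(adata.obs, ac, "m.1227")
        het = mh.cell_heteroplasmy(ac, "m.1227", cells)
        res = mh.correlate_all_genes(adata, het)
        assert abs(res["rho"].mean()) < 0.02
        within = (res["rho"].abs() <= 3 / np.sqrt(res["n_cells_used"])).mean()
        assert within >= 0.9

    def test_zero_inflated_mass_matches_mixture_cdf(self):
        cfg = mh.SingleCellSimConfig(n_cells=8000, zero_weight=0.3, n_genes=5, seed=7)
        _, _, truth = mh.simulate_singlecell(cfg)
        h = truth["heteroplasmy"]
        expected = mh.heteroplasmy_mixture_cdf(cfg, 0.10)
        se = np.sqrt(expected * (1 - expected) / len(h))
        assert abs((h < 0.10).mean() - expected) < 4 * se

    def test_observed_heteroplasmy_is_unbiased_binomial_sample(self):
        cfg = mh.SingleCellSimConfig(n_cells=4000, n_genes=5, seed=8,
                                     qc_violation_rate=0.0)
        ac, adata, truth = mh.simulate_singlecell(cfg)
        lt = ac[ac["locus"] == "m.1227"].reset_index(drop=True)
        cov = (lt["alt"] + lt["ref"]).to_numpy()
        ok = cov > 0
        obs = lt.loc[ok, "alt"].to_numpy() / cov[ok]
        resid = obs - truth["heteroplasmy"][ok]
        se = np.sqrt(np.mean(truth["heteroplasmy"] * (1 - truth["heteroplasmy"]))
                     / np.mean(cov)) / np.sqrt(ok.sum())
        assert abs(resid.mean()) < 4 * se

    def test_effect_gene_names_and_truth_roundtrip(self):
        eff = (mh.EffectGene("MT-CO1", 0.25, -2.0, "compensatory"),)
        cfg = mh.SingleCellSimConfig(n_cells=100, n_genes=10, effect_genes=eff, seed=9)
        _, adata, truth = mh.simulate_singlecell(cfg)
        assert "MT-CO1" in adata.var_names
        assert truth["effect_genes"]["MT-CO1"]["theta"] == 0.25

    def test_dosage_links(self):
        h = np.array([0.0, 0.2, 0.25, 0.6, 1.0])
        step = mh.dosage_multiplier(h, 0.25, -1.0, "step")
        np.testing.assert_allclose(step, [1, 1, 1, 0.5, 0.5])
        hinge = mh.dosage_multiplier(h, 0.25, -1.0, "hinge")
        assert hinge[0] == hinge[2] == 1.0 and hinge[4] == 0.5
        comp = mh.dosage_multiplier(h, 0.25, -1.0, "compensatory", comp_lfc=1.0)
        assert comp[2] == pytest.approx(2.0)  # compensatory peak at theta
        assert comp[4] == pytest.approx(1.0)  # rise cancelled by full decline
        with pytest.raises(ValueError):
            mh.dosage_multiplier(h, 0.25, -1.0, "nope")

    def test_invalid_configs_raise(self):
        with pytest.raises(SimConfigError):
            mh.simulate_singlecell(mh.SingleCellSimConfig(zero_weight=1.5))
        eff = tuple(mh.EffectGene(f"E{i}", 0.2, -1.0) for i in range(5))
        with pytest.raises(SimConfigError):
            mh.simulate_singlecell(
                mh.SingleCellSimConfig(n_genes=3, effect_genes=eff)
            )
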