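"""Promoter methylation: probe windows, beta aggregation, silencing calls."""

import numpy as np
import pandas as pd
import pytest

import brcaness.methylation as m
from brcaness.methylation import PromoterProfile
from brcaness.panel import GenePanel


@pytest.fixture
def toy_panel():
    return GenePanel(pd.DataFrame({
        "symbol": ["G1", "G2", "REFA", "REFB"],
        "is_reference": [False, False, True, True],
        "tss_chrom": ["chr1", "chr1", "chr2", "chr3"],
        "tss_pos": [100_000, 108_000, 50_000, 50_000],
    }))


def manifest_of(entries):
    return pd.DataFrame(entries, columns=["probe", "chrom", "pos"]).set_index("probe")


class TestProbeAssignment:
    def test_probe_at_tss_assigned(self, toy_panel):
        pm = m.assign_promoter_probes(manifest_of([("p1", "chr1", 100_000)]), toy_panel)
        assert ("p1", "G1") in set(zip(pm["probe"], pm["gene"]))

    def test_window_boundary_inclusive(self, toy_panel):
        pm = m.assign_promoter_probes(
            manifest_of([("in", "chr2", 60_000), ("out", "chr2", 60_001)]), toy_panel)
        hits = set(zip(pm["probe"], pm["gene"]))
        assert ("in", "REFA") in hits and ("out", "REFA") not in hits

    def test_probe_between_two_tss_maps_to_both(self, toy_panel):
        # G1 and G2 TSSs are 8 kb apart; a probe in between is in both windows
        pm = m.assign_promoter_probes(manifest_of([("mid", "chr1", 104_000)]), toy_panel)
        assert set(pm.loc[pm["probe"] == "mid", "gene"]) == {"G1", "G2"}

    def test_chromosome_naming_normalized(self, toy_panel):
        pm = m.assign_promoter_probes(manifest_of([("p1", "1", 100_000)]), toy_panel)
        assert ("p1", "G1") in set(zip(pm["probe"], pm["gene"]))

    def test_wrong_chromosome_not_assigned(self, toy_panel):
        pm = m.assign_promoter_probes(manifest_of([("p1", "chr9", 100_000)]), toy_panel)
        assert len(pm) == 0

    @pytest.mark.parametrize("wide,narrow", [(10_000, 5_000), (10_000, 1_000)])
    def test_shrinking_window_monotone(self, toy_panel, wide, narrow):
        rng = np.random.default_rng(0)
        entries = [(f"p{i}", "chr1", int(100_000 + rng.integers(-15_000, 15_000)))
                   for i in range(60)]
        big = m.assign_promoter_probes(manifest_of(entries), toy_panel, window=wide)
        small = m.assign_promoter_probes(manifest_of(entries), toy_panel, window=narrow)
        assert set(zip(small["probe"], small["gene"])) <= set(zip(big["probe"], big["gene"]))


class TestPromoterMeans:
    def _profile(self, toy_panel, betas, positions):
        manifest = manifest_of([(f"p{i}", "chr1", pos) for i, pos in enumerate(positions)])
        meth = pd.DataFrame({"S1": betas}, index=manifest.index).rename_axis("probe")
        pm = m.assign_promoter_probes(manifest, toy_panel)
        return m.promoter_means(meth, pm, pd.Series({"S1": "LUAD"}))

    def test_mean_at_cutoff_not_hypermethylated(self, toy_panel):
        prof = self._profile(toy_panel, [0.2, 0.4], [100_000, 100_100])
        assert prof.mean_beta.loc["G1", "LUAD"] == pytest.approx(0.3)
        assert not prof.hypermethylated.loc["G1", "LUAD"]

    def test_just_above_cutoff_hypermethylated(self, toy_panel):
        prof = self._profile(toy_panel, [0.31, 0.31], [100_000, 100_100])
        assert prof.hypermethylated.loc["G1", "LUAD"]

    def test_probe_outside_window_ignored(self, toy_panel):
        # 0.2 in window, 0.9 at TSS+25 kb: the mean is 0.2
        prof = self._profile(toy_panel, [0.2, 0.9], [100_000, 125_000])
        assert prof.mean_beta.loc["G1", "LUAD"] == pytest.approx(0.2)

    def test_gene_without_probes_missing(self, toy_panel):
        prof = self._profile(toy_panel, [0.2], [100_000])
        assert "REFA" not in prof.mean_beta.index  # missing, never 0

    def test_probe_order_permutation_invariant(self, small_cohort):
        bundle, _ = small_cohort
        pm = m.assign_promoter_probes(bundle.manifest, bundle.panel)
        prof1 = m.promoter_means(bundle.methylation, pm, bundle.samples)
        shuffled = bundle.methylation.sample(frac=1, random_state=3)
        prof2 = m.promoter_means(shuffled, pm.sample(frac=1, random_state=4),
                                 bundle.samples)
        pd.testing.assert_frame_equal(
            prof1.mean_beta.sort_index(), prof2.mean_beta.sort_index())

    def test_matches_brute_force(self, small_cohort):
        bundle, _ = small_cohort
        pm = m.assign_promoter_probes(bundle.manifest, bundle.panel)
        prof = m.promoter_means(bundle.methylation, pm, bundle.samples)
        gene, ctype = "ATM", "HIGH1"
        probes = pm.loc[pm["gene"] == gene, "probe"]
        ids = bundle.samples.index[bundle.samples == ctype]
        cols = [s for s in ids if s in bundle.methylation.columns]
        expect = bundle.methylation.loc[probes, cols].to_numpy().mean()
        assert prof.mean_beta.loc[gene, ctype] == pytest.approx(expect)


class TestLoad:
    def test_forty_genes_at_half(self, panel):
        mean_beta = pd.DataFrame(0.5, index=panel.symbols, columns=["LUAD"])
        prof = PromoterProfile(mean_beta=mean_beta,
                               probe_counts=pd.Series(4, index=panel.symbols),
                               hypermethylated=mean_beta > 0.3, cutoff=0.3)
        load = m.methylation_load(prof, panel)
        assert load.loc["LUAD", "load"] == pytest.approx(20.0)
        assert load.loc["LUAD", "n_genes"] == 40
        assert load.loc["LUAD", "BRCA1_mean_beta"] == pytest.approx(0.5)

    def test_missing_gene_excluded_from_sum(self, panel):
        mean_beta = pd.DataFrame(0.5, index=panel.symbols, columns=["LUAD"])
        mean_beta.loc["ATM", "LUAD"] = np.nan
        prof = PromoterProfile(mean_beta=mean_beta,
                               probe_counts=pd.Series(4, index=panel.symbols),
                               hypermethylated=mean_beta > 0.3, cutoff=0.3)
        load = m.methylation_load(prof, panel)
        assert load.loc["LUAD", "load"] == pytest.approx(19.5)
        assert load.loc["LUAD", "n_genes"] == 39


class TestAssociation:
    def test_constructed_anticorrelation_is_silencing(self, toy_panel):
        rng = np.random.default_rng(1)
        betas = 0.2 + 0.6 * rng.random(30)
        manifest = manifest_of([("p1", "chr1", 100_000)])
        meth = pd.DataFrame([betas], index=pd.Index(["p1"], name="probe"),
                            columns=[f"S{i}" for i in range(30)])
        expr = pd.DataFrame([-betas], index=pd.Index(["G1"], name="gene"),
                            columns=meth.columns)
        pm = m.assign_promoter_probes(manifest, toy_panel)
        out = m.methylation_expression_association(
            meth, pm, expr, pd.Series("LUAD", index=meth.columns))
        row = out.loc[(out["gene"] == "G1") & (out["cancer_type"] == "LUAD")]
        assert row["r"].item() == pytest.approx(-1.0)
        assert row["call"].item() == "silencing"

    def test_weak_correlation_no_call(self, toy_panel):
        rng = np.random.default_rng(2)
        betas = 0.2 + 0.6 * rng.random(40)
        expr_vals = rng.normal(size=40)  # independent of beta
        manifest = manifest_of([("p1", "chr1", 100_000)])
        cols = [f"S{i}" for i in range(40)]
        meth = pd.DataFrame([betas], index=pd.Index(["p1"], name="probe"), columns=cols)
        expr = pd.DataFrame([expr_vals], index=pd.Index(["G1"], name="gene"), columns=cols)
        pm = m.assign_promoter_probes(manifest, toy_panel)
        out = m.methylation_expression_association(
            meth, pm, expr, pd.Series("LUAD", index=cols))
        assert out["call"].item() == "none"

    def test_planted_silenced_gene_called(self, small_cohort):
        bundle, truth = small_cohort
        pm = m.assign_promoter_probes(bundle.manifest, bundle.panel)
        out = m.methylation_expression_association(
            bundle.methylation, pm, bundle.expression, bundle.samples)
        calls = {(g, c) for g, c in
                 zip(out.loc[out["call"] == "silencing", "gene"],
                     out.loc[out["call"] == "silencing", "cancer_type"])}
        planted = set(truth.silenced_pairs)
        # at least 80% of planted silenced pairs are recovered
        assert len(calls & planted) >= 0.8 * len(planted)

    def test_too_few_samples_undefined(self, toy_panel):
        manifest = manifest_of([("p1", "chr1", 100_000)])
        cols = ["S0", "S1"]
        meth = pd.DataFrame([[0.2, 0.4]], index=pd.Index(["p1"], name="probe"), columns=cols)
        expr = pd.DataFrame([[1.0, 2.0]], index=pd.Index(["G1"], name="gene"), columns=cols)
        pm = m.assign_promoter_probes(manifest, toy_panel)
        out = m.methylation_expression_association(
            meth, pm, expr, pd.Series("LUAD", index=cols))
        assert out["undefined"].all()


def test_hypermethylation_classification_vs_cutoff_gene(small_cohort):
    bundle, _ = small_cohort
    pm = m.assign_promoter_probes(bundle.manifest, bundle.panel)
    prof = m.promoter_means(bundle.methylation, pm, bundle.samples)
    out = m.classify_hypermethylated_genes(prof, bundle.panel, cutoff_gene="BRCA2")
    pan = prof.mean_beta.mean(axis=1)
    expect = pan.loc[out.index] > pan.loc["BRCA2"]
    assert (out["hypermethylated_vs_cutoff"] == expect).all()
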