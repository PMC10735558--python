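"""Curation, structure/kinship, LD decay, GWAS models and QTL assembly."""

import numpy as np
import pandas as pd
import pytest

from durumwp import assoc, simdata


def tiny_panel(dosage_cols, positions=None, chrom="chr1"):
    markers = list(dosage_cols)
    n = len(dosage_cols[markers[0]])
    dosage = pd.DataFrame(dosage_cols, index=[f"g{i}" for i in range(n)])
    mm = pd.DataFrame({"marker_id": markers, "chromosome": chrom,
                       "position": positions or list(range(1, len(markers) + 1)),
                       "alleles": "A/B"})
    return assoc.MarkerPanel(dosage, mm)


class TestCuration:
    def test_low_maf_and_monomorphic_removed(self):
        n = 100
        good = np.r_[np.zeros(50), np.full(50, 2.0)]
        low_maf = np.r_[np.full(96, 0.0), np.full(4, 2.0)]   # MAF 0.04
        mono = np.zeros(n)
        panel = tiny_panel({"good": good, "lowmaf": low_maf, "mono": mono})
        out, report = assoc.curate_markers(panel)
        assert list(out.dosage.columns) == ["good"]
        assert report["n_removed_maf"] == 2

    def test_high_het_and_missing_removed(self):
        n = 100
        good = np.r_[np.zeros(50), np.full(50, 2.0)]
        het = good.copy(); het[:10] = 1.0
        miss = good.astype(float).copy(); miss[:5] = np.nan
        panel = tiny_panel({"good": good, "het": het, "miss": miss})
        out, _ = assoc.curate_markers(panel)
        assert list(out.dosage.columns) == ["good"]

    def test_planted_violators_removed_exactly(self):
        cfg = simdata.SimConfig(n_genotypes=120, n_markers=200, n_violating_markers=10,
                                seed=2)
        dosage, mm, _ = simdata.simulate_genotypes(cfg)
        panel = assoc.MarkerPanel(dosage, mm)
        out, report = assoc.curate_markers(panel)
        assert report["n_input"] - report["n_kept"] == 10
        assert not out.dosage.columns.str.startswith("VIO-").any()

    def test_empty_panel_raises(self):
        panel = tiny_panel({"mono": np.zeros(20)})
        with pytest.raises(ValueError):
            assoc.curate_markers(panel)


class TestStructureKinship:
    def test_duplicated_genotypes_have_identical_kinship_rows(self, random_panel):
        dosage = random_panel.dosage.copy()
        dosage.iloc[1] = dosage.iloc[0]
        panel = assoc.MarkerPanel(dosage, random_panel.marker_map)
        Q, K = assoc.structure_and_kinship(panel)
        a, b = dosage.index[0], dosage.index[1]
        assert np.allclose(K.loc[a], K.loc[b])
        assert K.loc[a, a] == pytest.approx(K.loc[a, b])

    def test_kinship_psd(self, random_panel):
        _, K = assoc.structure_and_kinship(random_panel)
        ev = np.linalg.eigvalsh(K.to_numpy())
        assert ev.min() >= -1e-8

    def test_pc1_separates_drifted_subpopulations(self):
        cfg = simdata.SimConfig(n_genotypes=100, n_markers=300, subpop_drift=0.3,
                                seed=8, n_qtl=0)
        dosage, mm, subpop = simdata.simulate_genotypes(cfg)
        Q, _ = assoc.structure_and_kinship(assoc.MarkerPanel(dosage, mm))
        pc1 = Q["PC1"]
        means = pc1.groupby(subpop).mean()
        pooled_sd = pc1.groupby(subpop).std().mean()
        assert abs(means.diff().iloc[-1]) > 2 * pooled_sd


class TestLdDecay:
    def test_identical_markers_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.choice([0.0, 2.0], 100)
        panel = tiny_panel({"a": col, "b": col.copy()}, positions=[1, 1000])
        ld = assoc.ld_decay(panel, critical_r2=0.05, n_bins=2)
        assert ld.curve["mean_r2"].max() == pytest.approx(1.0)

    def test_independent_markers_background_r2(self, random_panel):
        ld = assoc.ld_decay(random_panel, critical_r2=0.05, n_bins=20)
        n = random_panel.n_genotypes
        far = ld.curve[ld.curve["distance"] > ld.curve["distance"].median()]
        assert far["mean_r2"].mean() == pytest.approx(1.0 / n, abs=2.0 / n)

    def test_block_scale_recovered_within_factor_two(self):
        L = 30e6
        hits = 0
        for seed in (0, 1, 2):
            cfg = simdata.SimConfig(n_genotypes=150, n_markers=400, n_chromosomes=2,
                                    chromosome_length=300_000_000, ld_block_length=L,
                                    seed=seed, n_qtl=0)
            dosage, mm, _ = simdata.simulate_genotypes(cfg)
            ld = assoc.ld_decay(assoc.MarkerPanel(dosage, mm), critical_r2=0.05)
            if L / 2 <= ld.ld_distance <= L * 2:
                hits += 1
        assert hits == 3

    def test_no_pairs_raises(self):
        panel = tiny_panel({"a": np.r_[np.zeros(10), np.full(10, 2.0)]})
        with pytest.raises(ValueError):
            assoc.ld_decay(panel, max_distance=0.0)


class TestGwas:
    def test_noiseless_marker_fully_explains_phenotype(self, random_panel):
        y = pd.Series(2.0 * random_panel.dosage["m0010"], index=random_panel.dosage.index)
        scan = assoc.gwas(random_panel, y, model="GLM_Q")
        row = scan.set_index("marker_id").loc["m0010"]
        assert row["effect"] == pytest.approx(2.0)
        assert row["r2_marker"] == pytest.approx(1.0)
        assert row["p_value"] <= 1e-250

    def test_identity_kinship_equals_glm(self, random_panel):
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(0, 1, random_panel.n_genotypes),
                      index=random_panel.dosage.index)
        K = pd.DataFrame(np.eye(random_panel.n_genotypes),
                         index=random_panel.dosage.index, columns=random_panel.dosage.index)
        glm = assoc.gwas(random_panel, y, model="GLM_Q")
        mlm = assoc.gwas(random_panel, y, K=K, model="MLM_QK")
        assert np.abs(glm["p_value"].to_numpy() - mlm["p_value"].to_numpy()).max() < 1e-6

    def test_collinear_covariates_rejected(self, random_panel):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(0, 1, random_panel.n_genotypes),
                      index=random_panel.dosage.index)
        cov = pd.DataFrame({"DTH": 1.0, "DTH2": 2.0}, index=random_panel.dosage.index)
        with pytest.raises(ValueError, match="singular"):
            assoc.gwas(random_panel, y, covariates=cov, model="GLM_Q")

    def test_mlm_shrinks_inflation_under_structure(self):
        # strong structure, no QTL: MLM λ should be nearer 1 than GLM λ
        closer = 0
        for seed in range(5):
            cfg = simdata.SimConfig(n_genotypes=150, n_markers=400, n_subpopulations=2,
                                    subpop_drift=0.3, seed=seed, n_qtl=0)
            dosage, mm, subpop = simdata.simulate_genotypes(cfg)
            panel = assoc.MarkerPanel(dosage, mm)
            rng = np.random.default_rng(seed + 100)
            y = pd.Series(subpop.to_numpy() * 3.0 + rng.normal(0, 1, len(subpop)),
                          index=dosage.index)
            _, K = assoc.structure_and_kinship(panel)
            glm = assoc.gwas(panel, y, model="GLM_Q")
            mlm = assoc.gwas(panel, y, K=K, model="MLM_QK")
            lam_g = assoc.genomic_inflation(glm["p_value"].to_numpy())
            lam_m = assoc.genomic_inflation(mlm["p_value"].to_numpy())
            if abs(lam_m - 1) <= abs(lam_g - 1):
                closer += 1
        assert closer >= 4

    def test_auto_prefers_better_calibrated_model(self, random_panel):
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(0, 1, random_panel.n_genotypes),
                      index=random_panel.dosage.index)
        K = pd.DataFrame(np.eye(random_panel.n_genotypes),
                         index=random_panel.dosage.index, columns=random_panel.dosage.index)
        out = assoc.gwas(random_panel, y, K=K, model="auto")
        assert out["model_used"].iloc[0] in ("GLM_Q", "MLM_QK")


def mta(marker, pos, context="combined_stress", lod=5.0, r2=0.1, chrom="chr1",
        trait="GY", effect=1.0):
    return dict(marker_id=marker, chromosome=chrom, position=pos, context=context,
                lod=lod, r2_marker=r2, trait=trait, effect=effect, p_value=10 ** -lod,
                model_used="GLM_Q")


class TestAssembleQtl:
    MERGE = 102.6e6

    def test_merge_rule_distances(self):
        close = pd.DataFrame([mta("a", int(10e6)), mta("b", int(50e6))])
        out = assoc.assemble_qtl(close, self.MERGE)
        assert len(out) == 1
        far = pd.DataFrame([mta("a", int(10e6)), mta("b", int(150e6))])
        assert len(assoc.assemble_qtl(far, self.MERGE)) == 2

    def test_single_linkage_transitivity(self):
        chain = pd.DataFrame([mta("a", int(10e6)), mta("b", int(100e6)),
                              mta("c", int(190e6))])
        out = assoc.assemble_qtl(chain, self.MERGE)
        assert len(out) == 1
        assert out.iloc[0]["end"] - out.iloc[0]["start"] == pytest.approx(180e6)

    def test_consistency_rule(self):
        combined = {"combined_stress"}
        good = pd.DataFrame([mta("a", 1, "combined_stress"), mta("a", 1, "E1"),
                             mta("a", 1, "E2")])
        assert assoc.assemble_qtl(good, self.MERGE, combined).iloc[0]["consistent"]
        one_env = pd.DataFrame([mta("a", 1, "combined_stress"), mta("a", 1, "E1")])
        assert not assoc.assemble_qtl(one_env, self.MERGE, combined).iloc[0]["consistent"]
        no_combined = pd.DataFrame([mta("a", 1, "E1"), mta("a", 1, "E2")])
        assert not assoc.assemble_qtl(no_combined, self.MERGE, combined).iloc[0]["consistent"]

    def test_representative_marker_tiebreak(self):
        mtas = pd.DataFrame([
            mta("hi_lod", int(10e6), lod=6.0, r2=0.05),
            mta("hi_r2", int(20e6), lod=5.0, r2=0.20),
            mta("tie_low_pos", int(5e6), lod=5.0, r2=0.20),
        ])
        out = assoc.assemble_qtl(mtas, self.MERGE)
        assert out.iloc[0]["representative_marker"] == "hi_lod"
        out2 = assoc.assemble_qtl(mtas[mtas["marker_id"] != "hi_lod"], self.MERGE)
        assert out2.iloc[0]["representative_marker"] == "tie_low_pos"

    def test_input_order_invariance(self):
        mtas = pd.DataFrame([mta("a", int(10e6)), mta("b", int(50e6)),
                             mta("c", int(300e6), chrom="chr2")])
        a = assoc.assemble_qtl(mtas, self.MERGE)
        b = assoc.assemble_qtl(mtas.iloc[::-1].reset_index(drop=True), self.MERGE)
        pd.testing.assert_frame_equal(a, b)

    def test_true_positive_flag_on_overlap(self):
        mtas = pd.DataFrame([mta("a", int(10e6))])
        other = pd.DataFrame([{"chromosome": "chr1", "start": int(5e6), "end": int(15e6)}])
        assert assoc.assemble_qtl(mtas, self.MERGE, other_panel_qtl=other).iloc[0]["true_positive"]
        far = pd.DataFrame([{"chromosome": "chr1", "start": int(500e6), "end": int(510e6)}])
        assert not assoc.assemble_qtl(mtas, self.MERGE, other_panel_qtl=far).iloc[0]["true_positive"]

    def test_both_gates_must_pass(self):
        thr = assoc.SignificanceThresholds(lod_cutoff=2.69, r2_cutoff=0.024)
        scan = pd.DataFrame([mta("a", 1, lod=5.0, r2=0.01),
                             mta("b", 2, lod=1.0, r2=0.5),
                             mta("c", 3, lod=5.0, r2=0.5)])
        out = assoc.significant_mtas(scan, thr)
        assert list(out["marker_id"]) == ["c"]
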