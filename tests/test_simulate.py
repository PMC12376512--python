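"""Generators: determinism, planted-structure guarantees, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lipsmr import (
    AssayParams,
    LipSimConfig,
    SmrSimConfig,
    ar1_ld,
    generate_assay_traces,
    generate_lipms_dataset,
    generate_smr_dataset,
    interval_gap,
)


class TestLipGenerator:
    def test_same_seed_identical_output(self):
        cfg = LipSimConfig(n_proteins=15, n_targets=2, n_far_decoys=2, seed=9)
        db1, t1, tr1 = generate_lipms_dataset(cfg)
        db2, t2, tr2 = generate_lipms_dataset(cfg)
        assert [(r.protein_id, r.sequence) for r in db1] == [
            (r.protein_id, r.sequence) for r in db2
        ]
        pd.testing.assert_frame_equal(t1.df, t2.df)
        pd.testing.assert_frame_equal(tr1.peptides, tr2.peptides)

    def test_adding_proteins_does_not_reshuffle_existing(self):
        small = LipSimConfig(n_proteins=10, n_targets=2, n_far_decoys=2, seed=3)
        big = LipSimConfig(n_proteins=14, n_targets=2, n_far_decoys=2, seed=3)
        db_s, t_s, _ = generate_lipms_dataset(small)
        db_b, t_b, _ = generate_lipms_dataset(big)
        for a, b in zip(db_s, db_b):
            assert (a.protein_id, a.sequence) == (b.protein_id, b.sequence)
        pd.testing.assert_frame_equal(t_s.df, t_b.df.iloc[: len(t_s.df)].reset_index(drop=True))

    def test_no_planting_when_no_targets(self):
        cfg = LipSimConfig(n_proteins=10, n_targets=0, n_far_decoys=0, seed=1)
        _, _, truth = generate_lipms_dataset(cfg)
        assert (truth.peptides["planted"] == "none").all()
        assert (truth.proteins["cls"] == "null").all()

    def test_truth_table_class_counts_and_structure(self):
        cfg = LipSimConfig(
            n_proteins=20, n_targets=5, n_far_decoys=3, n_same_direction_decoys=2, seed=2
        )
        _, _, truth = generate_lipms_dataset(cfg)
        counts = truth.proteins["cls"].value_counts()
        assert counts["target"] == 5
        assert counts["far_decoy"] == 3
        assert counts["same_direction_decoy"] == 2
        peps = truth.peptides
        for rec in truth.proteins.itertuples():
            planted = peps[(peps["protein_id"] == rec.protein_id) & (peps["planted"] != "none")]
            ups = planted[planted["planted"] == "up"]
            downs = planted[planted["planted"] == "down"]
            if rec.cls == "target":
                gaps = [
                    interval_gap(u.start, u.end, d.start, d.end)
                    for u in ups.itertuples()
                    for d in downs.itertuples()
                ]
                assert len(ups) >= 1 and len(downs) >= 1 and min(gaps) <= cfg.adjacency_gap
            elif rec.cls == "far_decoy":
                gaps = [
                    interval_gap(u.start, u.end, d.start, d.end)
                    for u in ups.itertuples()
                    for d in downs.itertuples()
                ]
                assert min(gaps) > cfg.adjacency_gap

    def test_generated_peptides_match_their_coordinates(self, small_lip_dataset):
        db, _, truth = small_lip_dataset
        for rec in truth.peptides.itertuples():
            seq = db[rec.protein_id].sequence
            assert seq[rec.start - 1 : rec.end] == rec.sequence

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(ValueError):
            generate_lipms_dataset(LipSimConfig(n_proteins=5, n_targets=4, n_far_decoys=4))
        with pytest.raises(ValueError):
            generate_lipms_dataset(LipSimConfig(effect_delta=0.0))
        with pytest.raises(ValueError):
            generate_lipms_dataset(LipSimConfig(n_replicates=1))

    def test_null_two_sigma_exceedance_matches_normal_tail(self):
        """With no planted effects the fraction of peptides whose mean
        log2 difference exceeds 2*noise_sd matches the normal tail."""
        cfg = LipSimConfig(
            n_proteins=150, n_targets=0, n_far_decoys=0, missing_rate=0.0, seed=14
        )
        _, table, _ = generate_lipms_dataset(cfg)
        log = np.log2(table.intensity_matrix())
        n = cfg.n_replicates
        diff = log[:, n:].mean(axis=1) - log[:, :n].mean(axis=1)
        # diff ~ N(0, 2*sd^2/n)
        sd_diff = cfg.noise_sd * np.sqrt(2 / n)
        expected = 2 * sps.norm.sf(2 * cfg.noise_sd / sd_diff)
        observed = (np.abs(diff) > 2 * cfg.noise_sd).mean()
        se = np.sqrt(expected * (1 - expected) / len(diff))
        assert abs(observed - expected) < 4 * se + 1e-3


class TestSmrGenerator:
    def test_determinism_and_truth_fields(self):
        cfg = SmrSimConfig(n_genes=5, seed=6)
        a = generate_smr_dataset(cfg)
        b = generate_smr_dataset(cfg)
        for (la, lda, ta), (lb, ldb, tb) in zip(a, b):
            pd.testing.assert_frame_equal(la, lb)
            assert np.array_equal(lda, ldb)
            assert ta == tb

    def test_zero_rho_gives_diagonal_ld(self):
        ld = ar1_ld(8, 0.0)
        assert np.allclose(ld, np.eye(8))
        cfg = SmrSimConfig(n_genes=1, ld_rho=0.0, seed=1)
        _, ld, _ = generate_smr_dataset(cfg)[0]
        assert np.allclose(ld - np.diag(np.diag(ld)), 0.0)

    def test_null_top_snp_ratio_centred_at_zero(self):
        cfg = SmrSimConfig(n_genes=400, beta_xy=0.0, seed=21)
        ratios = []
        for locus, _, _ in generate_smr_dataset(cfg):
            z2 = (locus["b_eqtl"] / locus["se_eqtl"]) ** 2
            top = z2.idxmax()
            ratios.append(locus["b_gwas"][top] / locus["b_eqtl"][top])
        assert abs(np.mean(ratios)) < 3 * np.std(ratios) / np.sqrt(len(ratios)) + 1e-3

    def test_causal_top_snp_ratio_near_beta(self):
        cfg = SmrSimConfig(n_genes=400, beta_xy=-0.1, seed=22)
        ratios = []
        for locus, _, _ in generate_smr_dataset(cfg):
            z2 = (locus["b_eqtl"] / locus["se_eqtl"]) ** 2
            top = z2.idxmax()
            ratios.append(locus["b_gwas"][top] / locus["b_eqtl"][top])
        assert abs(np.median(ratios) - (-0.1)) < 0.01

    def test_ld_matrices_positive_semidefinite(self):
        for rho in (-0.9, -0.3, 0.0, 0.5, 0.95):
            assert np.linalg.eigvalsh(ar1_ld(25, rho)).min() > -1e-8

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            generate_smr_dataset(SmrSimConfig(ld_rho=1.0))
        with pytest.raises(ValueError):
            generate_smr_dataset(SmrSimConfig(m_snps=3))


class TestAssayTraces:
    def test_constant_gtt_trace(self):
        params = AssayParams(baseline=10.0, peak=10.0, noise_sd=0.0)
        trace = generate_assay_traces("gtt", params, seed=0)
        assert np.allclose(trace["value"], 10.0)

    def test_ocr_phase_means_recovered_without_noise(self):
        params = AssayParams(noise_sd=0.0)
        trace = generate_assay_traces("ocr", params, seed=0)
        for phase, mean in params.phase_means.items():
            assert np.allclose(trace.loc[trace["phase"] == phase, "value"], mean)
        # injection order preserved
        assert list(dict.fromkeys(trace["phase"])) == [
            "baseline", "oligomycin", "fccp", "rot_aa",
        ]

    def test_same_seed_identical_trace(self):
        params = AssayParams(noise_sd=1.0)
        a = generate_assay_traces("ocr", params, seed=5)
        b = generate_assay_traces("ocr", params, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            generate_assay_traces("elisa", AssayParams(), seed=0)
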