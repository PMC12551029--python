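import numpy as np
import pandas as pd
import pytest

from dualrisk.io import WeightTable
from dualrisk.scores import ScoreConfig, compute_ats, score_cohort
from dualrisk.simulate import (
    SCORE_VARS,
    CohortTruth,
    GeneratorConfig,
    GeneratorError,
    default_target_corr,
    embed_betas,
    generate_cohort,
    nearest_psd_correlation,
    summarize_cohort,
    to_person_wide,
)


class TestTargetCorr:
    def test_default_is_psd_and_keeps_printed_entries(self):
        r = default_target_corr()
        assert np.linalg.eigvalsh(r)[0] >= 0
        idx = {v: k for k, v in enumerate(SCORE_VARS)}
        assert r[idx["ats5"], idx["ats6"]] == pytest.approx(0.846, abs=1e-6)
        assert r[idx["eis5"], idx["cri5"]] == pytest.approx(-0.580, abs=1e-6)
        assert r[idx["ats5"], idx["eis5"]] == pytest.approx(0.403, abs=1e-6)

    def test_nearest_psd_projection(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(bad)
        assert np.linalg.eigvalsh(fixed)[0] >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0, atol=1e-12)

    def test_non_psd_target_rejected_with_eigenvalue(self):
        bad = np.eye(6)
        bad[0, 1] = bad[1, 0] = 0.9
        bad[0, 2] = bad[2, 0] = -0.9
        bad[1, 2] = bad[2, 1] = 0.9
        with pytest.raises(GeneratorError, match="eigenvalue"):
            GeneratorConfig(target_corr=bad)


class TestGenerateCohort:
    def test_same_seed_reproduces_exactly(self):
        cfg = GeneratorConfig(n_couples=30)
        a = generate_cohort(cfg, seed=11)
        b = generate_cohort(cfg, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2].complete, b[2].complete)

    def test_no_missingness_yields_all_person_waves(self, complete_cohort):
        sheet, obs, truth = complete_cohort
        assert truth.n_person_waves == 2 * truth.n_individuals
        assert len(obs) == 2 * truth.n_individuals

    def test_correlations_converge_to_target(self):
        # icc = 0, 10000 individuals: empirical corr within +-0.02 of target
        cfg = GeneratorConfig(n_couples=5000, couple_icc=0.0, missingness=(1, 0, 0))
        _, _, truth = generate_cohort(cfg, seed=2)
        emp = truth.complete[list(SCORE_VARS)].corr().to_numpy()
        np.testing.assert_allclose(emp, cfg.target_corr, atol=0.02)

    def test_partners_independent_when_icc_zero(self):
        cfg = GeneratorConfig(n_couples=5000, couple_icc=0.0, missingness=(1, 0, 0))
        _, _, truth = generate_cohort(cfg, seed=3)
        a = truth.complete.iloc[0::2].reset_index(drop=True)
        b = truth.complete.iloc[1::2].reset_index(drop=True)
        for v in SCORE_VARS:
            assert abs(np.corrcoef(a[v], b[v])[0, 1]) < 0.03

    def test_partner_correlation_scales_with_icc(self):
        cfg = GeneratorConfig(n_couples=5000, couple_icc=0.4, missingness=(1, 0, 0))
        _, _, truth = generate_cohort(cfg, seed=4)
        a = truth.complete.iloc[0::2].reset_index(drop=True)
        b = truth.complete.iloc[1::2].reset_index(drop=True)
        assert np.corrcoef(a["ats5"], b["ats5"])[0, 1] == pytest.approx(0.4, abs=0.05)

    def test_missingness_frequencies_match_binomial(self):
        cfg = GeneratorConfig(n_couples=2000)
        _, _, truth = generate_cohort(cfg, seed=5)
        n = 2 * cfg.n_couples
        both = (truth.mask["w5"] & truth.mask["w6"]).sum()
        for count, p in ((both, cfg.missingness[0]),):
            se = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 4 * se

    def test_pattern_counts_sum_to_individuals(self, default_cohort):
        sheet, obs, truth = default_cohort
        rep = summarize_cohort(sheet, obs)
        assert sum(rep["pattern_counts"].values()) == rep["n_individuals"]
        assert rep["n_person_waves"] == truth.n_person_waves

    def test_mar_dropout_depends_on_ats(self):
        cfg = GeneratorConfig(n_couples=3000, mar_logistic_coef=1.5)
        _, _, truth = generate_cohort(cfg, seed=6)
        merged = truth.complete.merge(truth.mask, on="person_id")
        w5 = merged[merged["w5"]]
        dropped = w5.loc[~w5["w6"], "ats5"]
        retained = w5.loc[w5["w6"], "ats5"]
        assert dropped.mean() > retained.mean() + 0.2

    def test_truth_parameters_roundtrip_config(self):
        cfg = GeneratorConfig(n_couples=12, couple_icc=0.3, seed=42)
        _, _, truth = generate_cohort(cfg)
        d = truth.to_dict()["config"]
        assert d["n_couples"] == 12 and d["couple_icc"] == 0.3 and d["seed"] == 42
        np.testing.assert_allclose(d["target_corr"], cfg.target_corr)


class TestSummaries:
    def test_complete_data_fiml_equals_pairwise(self, complete_cohort):
        sheet, obs, _ = complete_cohort
        rep = summarize_cohort(sheet, obs)
        np.testing.assert_allclose(
            rep["fiml_corr"].to_numpy(), rep["pairwise_corr"].to_numpy(), atol=1e-6
        )

    def test_elevated_share_matches_manual_count(self, default_cohort):
        sheet, obs, truth = default_cohort
        rep = summarize_cohort(sheet, obs)
        w5 = obs[obs["wave"] == 5]
        assert rep["pct_elevated"]["w5"] == pytest.approx((w5["ats"] > 2.35).mean())


class TestEmbedBetas:
    @pytest.fixture
    def small(self, rng):
        cfg = GeneratorConfig(n_couples=40)
        sheet, obs, truth = generate_cohort(cfg, seed=8)
        wt = WeightTable(
            {f"cgsyn{j:06d}": c for j, c in enumerate(rng.normal(0, 0.3, 15))}
        )
        return sheet, obs, truth, wt

    def test_cri_recovered_exactly(self, small):
        sheet, obs, truth, wt = small
        bm = embed_betas(obs, wt, seed=1)
        panel = score_cohort(bm, wt, sheet.drop(columns=["ats1", "ats2", "ats3", "ats4"]),
                             ScoreConfig())
        np.testing.assert_allclose(panel["cri"], obs["cri"], atol=1e-10)

    def test_eis_z_correlates_one_with_target(self, small):
        sheet, obs, truth, wt = small
        bm = embed_betas(obs, wt, seed=1)
        panel = score_cohort(bm, wt, sheet, ScoreConfig())
        r = np.corrcoef(panel["eis_z"], obs["eis"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_fixed_reference_ats_exact(self, small):
        sheet, obs, truth, wt = small
        ats = compute_ats(
            sheet[["ats1", "ats2", "ats3", "ats4"]].to_numpy(),
            reference=truth.ats_reference,
        )
        np.testing.assert_allclose(ats, obs["ats"], atol=1e-10)

    def test_noiseless_single_probe_is_inverse_logit(self):
        scores = pd.DataFrame(
            {"person_id": ["p1", "p2"], "wave": [5, 5], "eis": [1.0, -1.0],
             "cri": [0.5, 0.5], "ats": [0.0, 0.1]}
        )
        wt = WeightTable({"cgsyn000000": 1.0})
        bm = embed_betas(scores, wt, noise_sd=0.0, cri_noise_sd=0.0, seed=0)
        expect = 1.0 / (1.0 + 2.0 ** (-scores["eis"].to_numpy()))
        np.testing.assert_allclose(bm.values[0], expect, atol=1e-12)

    def test_zero_weights_rejected(self):
        scores = pd.DataFrame(
            {"person_id": ["p1"], "wave": [5], "eis": [0.0], "cri": [0.5], "ats": [0.0]}
        )
        with pytest.raises(GeneratorError, match="all-zero"):
            embed_betas(scores, WeightTable({"cgA": 0.0}), seed=0)


def test_to_person_wide_shapes(default_cohort):
    sheet, obs, truth = default_cohort
    wide = to_person_wide(obs, sheet)
    assert len(wide) == truth.n_individuals
    assert {"ats5", "eis6", "cri5", "age", "sex", "binge"} <= set(wide.columns)
    # wave-5-only people have NaN wave-6 scores
    only5 = truth.mask[truth.mask["w5"] & ~truth.mask["w6"]]["person_id"]
    assert wide.set_index("person_id").loc[only5, "cri6"].isna().all()
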