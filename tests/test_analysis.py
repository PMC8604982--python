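"""Eigenvariate extraction, baseline contrasts, mixed model, post hocs."""

import numpy as np
import pandas as pd
import pytest

from semadapt.analysis import (
    CONTRAST_DC,
    CONTRAST_SC,
    adaptation_contrasts,
    detect_roi_interactions,
    extract_eigenvariate,
    fit_adaptation_lmm,
    flag_adaptation,
    pairwise_comparisons,
    posthoc_categories,
)
from semadapt.simulate import gen_lmm_contrasts


# ---------------------------------------------------------------------------
# Eigenvariate
# ---------------------------------------------------------------------------

def _corr(a, b):
    return float(np.corrcoef(a, b)[0, 1])


def test_single_voxel_returns_its_series():
    y = np.array([[1.0, 3.0, 2.0, 5.0]])
    e = extract_eigenvariate(y, scaling_mode="none")
    assert _corr(e, y[0]) > 0.999999
    assert np.allclose(e, y[0])


def test_identical_voxels_return_common_series():
    base = np.array([2.0, 4.0, 3.0, 6.0])
    y = np.tile(base, (7, 1))
    for mode in ("none", "grand_mean"):
        assert np.allclose(extract_eigenvariate(y, scaling_mode=mode), base)


def test_rank_one_recovery_against_svd_oracle():
    rng = np.random.default_rng(0)
    n_vox, n_obs = 40, 60
    u = rng.uniform(0.5, 1.5, n_vox)
    v = rng.normal(0, 1, n_obs)
    signal = np.outer(u, v)
    noise = rng.normal(0, signal.std() / 10, signal.shape)  # SNR 10
    y = signal + noise
    e = extract_eigenvariate(y, scaling_mode="none")
    assert abs(_corr(e, v)) > 0.99
    # direct SVD oracle
    _, s, vt = np.linalg.svd(y)
    assert abs(_corr(e, vt[0])) > 0.999999


def test_eigenvariate_voxel_order_invariance():
    rng = np.random.default_rng(1)
    y = rng.normal(10, 2, (12, 30))
    e = extract_eigenvariate(y)
    perm = rng.permutation(12)
    assert np.allclose(extract_eigenvariate(y[perm]), e, atol=1e-8)


def test_eigenvariate_scale_equivariance_without_scaling():
    rng = np.random.default_rng(2)
    y = rng.normal(5, 1, (8, 20))
    e = extract_eigenvariate(y, scaling_mode="none")
    assert np.allclose(extract_eigenvariate(3.0 * y, scaling_mode="none"), 3.0 * e)


def test_eigenvariate_errors():
    with pytest.raises(ValueError):
        extract_eigenvariate(np.zeros((3, 5)))
    with pytest.raises(ValueError):
        extract_eigenvariate(np.ones((3, 1)))
    with pytest.raises(ValueError):
        extract_eigenvariate(np.ones((2, 4)), scaling_mode="zscore")
    with pytest.raises(ValueError):
        extract_eigenvariate(np.array([[1.0, np.nan]]))


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _beta_table(cells):
    return pd.DataFrame(
        cells, columns=["subject", "roi", "condition", "domain", "category", "value"]
    )


def test_contrast_zero_when_condition_equals_baseline():
    betas = _beta_table(
        [
            ("s1", "r1", "SameWord", "ABS", "", 10.0),
            ("s1", "r1", "SameCategory", "ABS", "EM", 10.0),
        ]
    )
    out = adaptation_contrasts(betas)
    assert (out["value"] == 0.0).all()


def test_contrast_simple_arithmetic():
    betas = _beta_table(
        [
            ("s1", "r1", "SameWord", "ABS", "", 10.0),
            ("s1", "r1", "SameCategory", "ABS", "EM", 5.0),
            ("s1", "r1", "DifferentCategory", "ABS", "", 12.0),
        ]
    )
    out = adaptation_contrasts(betas).set_index(["contrast", "granularity"])["value"]
    assert out.loc[(CONTRAST_SC, "category")] == -5.0
    assert out.loc[(CONTRAST_DC, "category")] == 2.0


def test_contrasts_match_loop_oracle():
    rng = np.random.default_rng(4)
    rows = []
    for s in ("s1", "s2", "s3"):
        for r in ("r1", "r2"):
            for d in ("ABS", "CNC"):
                rows.append((s, r, "SameWord", d, "", rng.normal(10, 2)))
                for cat in ("x", "y"):
                    rows.append((s, r, "SameCategory", d, cat, rng.normal(10, 2)))
                rows.append((s, r, "DifferentCategory", d, "", rng.normal(10, 2)))
    betas = _beta_table(rows)
    out = adaptation_contrasts(betas)
    cat = out[out["granularity"] == "category"]
    # independent loop-based subtraction
    base = {
        (r.subject, r.roi, r.domain): r.value
        for r in betas.itertuples()
        if r.condition == "SameWord"
    }
    for r in betas.itertuples():
        if r.condition == "SameWord":
            continue
        contrast = CONTRAST_SC if r.condition == "SameCategory" else CONTRAST_DC
        got = cat[
            (cat["subject"] == r.subject)
            & (cat["roi"] == r.roi)
            & (cat["domain"] == r.domain)
            & (cat["category"] == r.category)
            & (cat["contrast"] == contrast)
        ]["value"].iloc[0]
        assert got == pytest.approx(r.value - base[(r.subject, r.roi, r.domain)])
    # cell conservation: one contrast row per non-baseline beta row
    assert len(cat) == (betas["condition"] != "SameWord").sum()


def test_missing_baseline_named():
    betas = _beta_table([("s1", "r1", "SameCategory", "ABS", "EM", 5.0)])
    with pytest.raises(ValueError, match="r1"):
        adaptation_contrasts(betas)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

def _moment_icc(df):
    """Closed-form balanced one-way variance decomposition (oracle)."""
    wide = df.pivot_table(index="subject", columns=["roi", "condition", "domain", "category"],
                          values="value")
    k = wide.shape[1]
    subj_means = wide.mean(axis=1)
    grand = wide.to_numpy().mean()
    ms_between = k * ((subj_means - grand) ** 2).sum() / (len(wide) - 1)
    ms_within = ((wide.sub(subj_means, axis=0)) ** 2).to_numpy().sum() / (len(wide) * (k - 1))
    var_u = max(0.0, (ms_between - ms_within) / k)
    return var_u / (var_u + ms_within)


def test_lmm_icc_agrees_with_moment_oracle():
    df = gen_lmm_contrasts(n_subjects=14, rois=4, icc=0.3, total_sd=2.0, seed=8)
    res = fit_adaptation_lmm(df)
    assert res.icc == pytest.approx(_moment_icc(df), abs=0.02)
    assert 0.0 <= res.icc <= 1.0
    assert np.isfinite(res.wald_z_subject)
    assert set(res.term_tests["term"]) == {
        "condition", "domain", "roi", "condition:domain", "condition:roi",
        "domain:roi", "condition:domain:roi",
    }


def test_lmm_null_subject_variance_estimated_near_zero():
    low = 0
    for seed in range(20):
        df = gen_lmm_contrasts(n_subjects=12, rois=4, icc=0.0, total_sd=1.0, seed=seed)
        low += fit_adaptation_lmm(df).icc < 0.05
    assert low >= 19  # >= 95% of simulations


def test_lmm_detects_planted_interaction_at_strong_effect():
    """Omnibus three-way Wald test under a 1.5x residual-SD single-ROI deficit."""
    sig = 0
    for seed in range(15):
        df = gen_lmm_contrasts(
            n_subjects=20, rois=8, icc=0.0, total_sd=1.0,
            cell_effects={("SameCategory-SameWord", "ABS", "roi01"): -1.5},
            seed=100 + seed,
        )
        res = fit_adaptation_lmm(df)
        p = res.term_tests.set_index("term").loc["condition:domain:roi", "p_value"]
        sig += p < 0.05
    assert sig >= 0.9 * 15


def test_lmm_rejects_empty_cells():
    df = gen_lmm_contrasts(n_subjects=6, rois=2, seed=0)
    broken = df[~((df["roi"] == "roi01") & (df["condition"] == "SameCategory-SameWord"))]
    with pytest.raises(ValueError, match="empty cells"):
        fit_adaptation_lmm(broken)


def test_roi_interaction_probe_localizes_planted_effect():
    df = gen_lmm_contrasts(
        n_subjects=24, rois=6, icc=0.0, total_sd=1.0,
        cell_effects={("SameCategory-SameWord", "ABS", "roi03"): -1.0},
        seed=5,
    )
    probe = detect_roi_interactions(df)
    assert probe["family_size"].iloc[0] == 12
    hit = probe[(probe["roi"] == "roi03") & (probe["condition"] == "SameCategory-SameWord")]
    assert bool(hit["significant"].iloc[0])
    others = probe[~((probe["roi"] == "roi03") & (probe["condition"] == "SameCategory-SameWord"))]
    assert others["significant"].sum() == 0


# ---------------------------------------------------------------------------
# Post-hoc category analyses
# ---------------------------------------------------------------------------

def _contrast_frame(values, roi="r1", domain="ABS"):
    rows = []
    for cat, vals in values.items():
        for i, v in enumerate(vals):
            rows.append((f"s{i}", roi, domain, cat, CONTRAST_SC, "category", v))
    return pd.DataFrame(
        rows,
        columns=["subject", "roi", "domain", "category", "contrast", "granularity", "value"],
    )


def test_posthoc_identical_categories_give_zero_t_and_d():
    vals = [1.0, 2.0, 3.0, 4.0]
    con = _contrast_frame({"a": vals, "b": vals})
    out = posthoc_categories(con, "r1", "ABS")
    assert out["omnibus"]["test"] == "paired_t"
    assert out["omnibus"]["statistic"] == 0.0
    row = out["pairwise"].iloc[0]
    assert row["t"] == 0.0 and row["cohen_d"] == 0.0


def test_posthoc_anova_f_matches_hand_decomposition():
    # 4 categories x 5 subjects fixture; textbook sums-of-squares oracle.
    rng = np.random.default_rng(9)
    data = {c: rng.normal(i, 1.0, 5) for i, c in enumerate("abcd")}
    con = _contrast_frame(data)
    out = posthoc_categories(con, "r1", "ABS")
    groups = list(data.values())
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = 3, 16
    f_oracle = (ss_between / df_b) / (ss_within / df_w)
    assert out["omnibus"]["test"] == "anova"
    assert out["omnibus"]["statistic"] == pytest.approx(f_oracle)
    assert out["omnibus"]["df"] == (df_b, df_w)


def test_posthoc_detects_two_pooled_sd_shift():
    """A category shifted by 2 pooled SDs survives Bonferroni at n = 36."""
    hits = 0
    n_sims = 20
    for seed in range(n_sims):
        rng = np.random.default_rng(300 + seed)
        data = {c: rng.normal(0, 1.0, 36) for c in ("a", "b", "c")}
        data["d"] = rng.normal(2.0, 1.0, 36)
        out = posthoc_categories(_contrast_frame(data), "r1", "ABS")
        pw = out["pairwise"]
        with_d = pw[(pw["level_a"] == "d") | (pw["level_b"] == "d")]
        hits += bool((with_d["p_bonferroni"] < 0.05).all())
    assert hits >= 0.9 * n_sims


def test_posthoc_requires_replication():
    con = _contrast_frame({"a": [1.0], "b": [2.0]})
    with pytest.raises(ValueError, match="fewer than 2"):
        posthoc_categories(con, "r1", "ABS")
    with pytest.raises(ValueError, match=">= 2 categories"):
        posthoc_categories(_contrast_frame({"a": [1.0, 2.0]}), "r1", "ABS")


def test_bonferroni_never_below_raw_p():
    rng = np.random.default_rng(10)
    con = _contrast_frame({c: rng.normal(0, 1, 8) for c in "abcd"})
    pw = pairwise_comparisons(con, "category")
    assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-12).all()
    assert (pw["family_size"] == 6).all()


# ---------------------------------------------------------------------------
# Adaptation flag
# ---------------------------------------------------------------------------

def test_flag_planted_negative_contrast_adapted():
    rng = np.random.default_rng(12)
    con = _contrast_frame(
        {"em": rng.normal(-5, 0.5, 20), "cog": rng.normal(1, 0.5, 20)}
    )
    assert flag_adaptation(con, "r1", "em") == "adapted"


def test_flag_planted_positive_contrast_not_adapted():
    rng = np.random.default_rng(13)
    con = _contrast_frame(
        {"em": rng.normal(5, 0.5, 20), "cog": rng.normal(0, 0.5, 20)}
    )
    assert flag_adaptation(con, "r1", "em") == "not_adapted"


def test_flag_false_positive_rate_calibrated_under_null():
    alpha, n_sims = 0.05, 500
    fps = 0
    for seed in range(n_sims):
        rng = np.random.default_rng(1000 + seed)
        con = _contrast_frame({c: rng.normal(0, 1, 12) for c in ("a", "b")})
        fps += flag_adaptation(con, "r1", "a", alpha=alpha) == "adapted"
    mc_err = np.sqrt(alpha * (1 - alpha) / n_sims)
    assert fps / n_sims <= alpha + 2 * mc_err
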