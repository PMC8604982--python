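"""Synthetic-data generators: exact mixes, determinism, planted structure."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from semadapt.analysis import CONTRAST_SC, adaptation_contrasts, fit_adaptation_lmm
from semadapt.brainmap import control_type_mean
from semadapt.literature import AtlasVolume, records_to_table
from semadapt.simulate import (
    PARADIGM_CODE_DIST,
    BoldSimConfig,
    CorpusConfig,
    LexiconConfig,
    design_cells,
    expected_control_type_mean,
    gen_atlas,
    gen_bold,
    gen_bold_voxels,
    gen_brainmap_profiles,
    gen_lexicon,
    gen_literature_corpus,
    gen_lmm_contrasts,
    parcel_centers,
)


# ---------------------------------------------------------------------------
# Literature corpus
# ---------------------------------------------------------------------------

def test_default_corpus_reproduces_reference_accounting():
    records = gen_literature_corpus()
    assert len(records) == 195
    counts = Counter(r.correction for r in records)
    assert counts["uncorrected"] == 56
    assert counts["unknown"] == 17
    assert counts["voxel"] + counts["cluster"] == 122


def test_corpus_deterministic_under_seed():
    a = records_to_table(gen_literature_corpus(CorpusConfig(seed=5)))
    b = records_to_table(gen_literature_corpus(CorpusConfig(seed=5)))
    assert a.to_csv() == b.to_csv()
    c = records_to_table(gen_literature_corpus(CorpusConfig(seed=6)))
    assert a.to_csv() != c.to_csv()


def test_corpus_proportions_pass_goodness_of_fit_at_large_n():
    cfg = CorpusConfig(n_contrasts=10000, seed=2)
    records = gen_literature_corpus(cfg)
    counts = Counter(r.contrast_class for r in records)
    observed = [counts[k] for k in sorted(cfg.class_mix)]
    expected = [cfg.class_mix[k] * cfg.n_contrasts for k in sorted(cfg.class_mix)]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = stats.chi2.sf(chi2, df=len(observed) - 1)
    assert p > 0.01


def test_corpus_talairach_fraction_exact():
    cfg = CorpusConfig(n_contrasts=100, talairach_fraction=0.25, seed=1)
    records = gen_literature_corpus(cfg)
    assert sum(r.space == "Talairach" for r in records) == 25


def test_corpus_rejects_invalid_proportions():
    with pytest.raises(ValueError, match="sum"):
        CorpusConfig(correction_mix={"voxel": 0.5, "cluster": 0.5, "uncorrected": 0.5, "unknown": 0.0})
    with pytest.raises(ValueError):
        CorpusConfig(n_contrasts=0)
    with pytest.raises(ValueError):
        CorpusConfig(focus_noise_sd=-1.0)


# ---------------------------------------------------------------------------
# Database profiles
# ---------------------------------------------------------------------------

def test_expected_control_type_means_separate_planted_classes():
    # oracle: expectation computed from the configured code distribution
    for klass, dist in PARADIGM_CODE_DIST.items():
        assert expected_control_type_mean(klass) == pytest.approx(
            sum(c * p for c, p in dist.items())
        )
    assert expected_control_type_mean("semantic") > 0.6
    assert expected_control_type_mean("control") < -0.6
    assert abs(expected_control_type_mean("ambiguous")) < 0.6


def test_profiles_p_in_unit_interval_and_determinism():
    profiles, paradigms = gen_brainmap_profiles(["a", "b"], "semantic", seed=3)
    assert profiles["P"].between(0, 1).all()
    p2, q2 = gen_brainmap_profiles(["a", "b"], "semantic", seed=3)
    pd.testing.assert_frame_equal(profiles, p2)
    pd.testing.assert_frame_equal(paradigms, q2)


def test_profiles_reject_empty_or_unknown():
    with pytest.raises(ValueError, match="empty"):
        gen_brainmap_profiles([], "semantic")
    with pytest.raises(ValueError, match="unknown planted"):
        gen_brainmap_profiles(["a"], "middling")


def test_planted_class_sign_recovered_across_seeds():
    """Computed control-type mean matches the planted class in >= 95% of
    regions over 100 seeds."""
    hits = total = 0
    for seed in range(100):
        regions = [f"r{i}" for i in range(6)]
        planted = ["semantic"] * 3 + ["control"] * 3
        _, paradigms = gen_brainmap_profiles(regions, planted, seed=seed)
        for region, klass in zip(regions, planted):
            ctm = control_type_mean(
                paradigms.loc[paradigms["region_label"] == region, "code"]
            )
            total += 1
            hits += (ctm > 0) if klass == "semantic" else (ctm < 0)
    assert hits / total >= 0.95


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def test_atlas_parcel_count_and_round_trip():
    img = gen_atlas(grid_shape=(2, 2, 2), parcel_size_mm=10.0, voxel_size_mm=2.0)
    atlas = AtlasVolume(img)
    assert len(atlas.labels) == 8
    for label, center in parcel_centers(img).items():
        got, reason = atlas.label_at(center)
        assert got == label and reason == "direct"


def test_atlas_background_and_bounds():
    img = gen_atlas(grid_shape=(2, 2, 2), parcel_size_mm=10.0, voxel_size_mm=2.0)
    atlas = AtlasVolume(img)
    corner = atlas.affine @ np.array([0, 0, 0, 1.0])
    assert atlas.label_at(corner[:3]) == (None, "background")
    assert atlas.label_at((999.0, 0.0, 0.0)) == (None, "outside_volume")
    # a background voxel adjacent to the grid resolves with a search radius
    lab, reason = atlas.label_at(corner[:3] + 8.0, search_radius_mm=6.0)
    assert lab is not None and reason == "nearest_nonzero"


def test_atlas_rejects_bad_geometry():
    with pytest.raises(ValueError):
        gen_atlas(grid_shape=(0, 2, 2))
    with pytest.raises(ValueError):
        gen_atlas(parcel_size_mm=-1.0)
    with pytest.raises(ValueError):
        gen_atlas(parcel_size_mm=5.0, voxel_size_mm=2.0)


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------

def test_lexicon_default_counts(lexicon):
    main = lexicon.main_words()
    counts = main.groupby("category").size()
    for cat in ("EM", "COG", "ATT", "ACT"):
        assert counts[cat] == 24
    for cat in ("BIOL", "ART"):
        assert counts[cat] == 48
    base = lexicon.words[lexicon.words["is_baseline"]]
    assert base.groupby("domain").size().to_dict() == {"ABS": 6, "CNC": 6}


def test_relatedness_symmetric_unit_diagonal(lexicon):
    rel = lexicon.relatedness
    assert np.allclose(rel.to_numpy(), rel.to_numpy().T)
    assert np.allclose(np.diag(rel.to_numpy()), 1.0)
    assert rel.to_numpy().min() >= 0.0 and rel.to_numpy().max() <= 1.0


def test_relatedness_centers(lexicon):
    words = lexicon.main_words()
    em = words.loc[words["category"] == "EM", "word"].tolist()
    cog = words.loc[words["category"] == "COG", "word"].tolist()
    within = lexicon.relatedness.loc[em, em].to_numpy()
    between = lexicon.relatedness.loc[em, cog].to_numpy()
    iu = np.triu_indices_from(within, k=1)
    assert abs(within[iu].mean() - 0.7) < 0.05
    assert abs(between.mean() - 0.3) < 0.05


def test_lexicon_rejects_tiny_categories():
    with pytest.raises(ValueError, match="at least 2"):
        LexiconConfig(n_words_per_category={"EM": 1, "COG": 24, "ATT": 24, "ACT": 24,
                                            "BIOL": 48, "ART": 48})


def test_lexicon_deterministic():
    a = gen_lexicon(LexiconConfig(seed=9))
    b = gen_lexicon(LexiconConfig(seed=9))
    pd.testing.assert_frame_equal(a.words, b.words)
    pd.testing.assert_frame_equal(a.relatedness, b.relatedness)


# ---------------------------------------------------------------------------
# BOLD betas
# ---------------------------------------------------------------------------

def test_design_cells_enumerates_ten_conditions(trials):
    cells = design_cells(trials)
    assert len(cells) == 10  # 6 Same-Category categories + 2 DC + 2 SW cells
    assert (cells[cells["condition"] != "SameCategory"]["category"] == "").all()


def test_subject_intercept_cancels_in_contrasts(trials):
    """The subject intercept is removed by baseline subtraction: the fitted
    ICC on contrasts stays small and does not grow with the planted subject
    SD. (A small positive floor remains because every contrast of a
    (subject, roi, domain) block shares the same Same-Word baseline draw.)"""
    iccs = {}
    for subject_sd in (0.0, 5000.0):
        cfg = BoldSimConfig(n_subjects=12, rois=("r1", "r2", "r3"), adaptation_map={},
                            subject_sd=subject_sd, seed=0)
        con = adaptation_contrasts(gen_bold(cfg, trials))
        cat = con[con["granularity"] == "category"].rename(columns={"contrast": "condition"})
        iccs[subject_sd] = fit_adaptation_lmm(cat).icc
    assert iccs[0.0] < 0.15
    assert abs(iccs[5000.0] - iccs[0.0]) < 0.02


def test_bold_null_adaptation_gives_zero_mean_contrast(trials):
    cfg = BoldSimConfig(n_subjects=30, rois=("r1", "r2"), adaptation_map={},
                        sc_shift=0.0, dc_shift=0.0, seed=1)
    con = adaptation_contrasts(gen_bold(cfg, trials))
    cells = con.groupby(["roi", "contrast"])["value"]
    se = cells.sem()
    assert (cells.mean().abs() < 4 * se).all()


def test_bold_recovers_planted_effect_within_two_se(trials):
    """Monte-Carlo recovery of a -3000 unit planted adaptation at n = 36."""
    reps = 100
    means = []
    for seed in range(reps):
        cfg = BoldSimConfig(
            n_subjects=36, rois=("L-MTG",), adaptation_map={("L-MTG", "EM"): -3000.0},
            sc_shift=0.0, dc_shift=0.0, subject_sd=0.0, seed=seed,
        )
        con = adaptation_contrasts(gen_bold(cfg, trials))
        cell = con[
            (con["granularity"] == "category")
            & (con["contrast"] == CONTRAST_SC)
            & (con["category"] == "EM")
        ]
        means.append(cell["value"].mean())
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(reps)
    assert abs(means.mean() - (-3000.0)) < 2 * se


def test_bold_validates_adaptation_map_and_conditions(trials):
    with pytest.raises(ValueError, match="not in config.rois"):
        gen_bold(BoldSimConfig(rois=("r1",), adaptation_map={("r9", "EM"): -1.0}), trials)
    with pytest.raises(ValueError, match="not in the design"):
        gen_bold(BoldSimConfig(rois=("r1",), adaptation_map={("r1", "XX"): -1.0}), trials)
    broken = trials[trials["condition"] != "SameWord"]
    with pytest.raises(ValueError, match="SameWord"):
        gen_bold(BoldSimConfig(rois=("r1",), adaptation_map={}), broken)


def test_bold_voxel_matrices_share_rank_one_structure(trials):
    cfg = BoldSimConfig(n_subjects=2, rois=("r1",), adaptation_map={},
                        n_voxels_per_roi=25, voxel_noise_sd=100.0, seed=4)
    mats, cells = gen_bold_voxels(cfg, trials)
    assert set(mats) == {("sub00", "r1"), ("sub01", "r1")}
    mat = mats[("sub00", "r1")]
    assert mat.shape == (25, len(cells))
    s = np.linalg.svd(mat, compute_uv=False)
    assert s[0] / s[1] > 10  # dominant shared component


def test_gen_lmm_contrasts_plants_requested_icc():
    df = gen_lmm_contrasts(n_subjects=200, rois=4, icc=0.3, total_sd=1.0, seed=0)
    wide = df.pivot_table(index="subject",
                          columns=["roi", "condition", "domain", "category"],
                          values="value")
    k = wide.shape[1]
    ms_b = k * ((wide.mean(axis=1) - wide.to_numpy().mean()) ** 2).sum() / (len(wide) - 1)
    ms_w = ((wide.sub(wide.mean(axis=1), axis=0)) ** 2).to_numpy().sum() / (len(wide) * (k - 1))
    var_u = max(0.0, (ms_b - ms_w) / k)
    icc_hat = var_u / (var_u + ms_w)
    assert icc_hat == pytest.approx(0.3, abs=0.05)


def test_gen_lmm_contrasts_validates_inputs():
    with pytest.raises(ValueError):
        gen_lmm_contrasts(icc=1.0)
    with pytest.raises(ValueError):
        gen_lmm_contrasts(total_sd=0.0)
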