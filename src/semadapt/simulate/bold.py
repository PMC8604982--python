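"""Synthetic region-level BOLD beta estimates with planted adaptation effects.

``gen_bold`` draws one beta per subject x ROI x condition cell following the
additive model

    beta = grand_mean + subject_intercept + condition_shift
           + planted_adaptation + residual_noise

where the planted adaptation, keyed by (ROI, category), moves the Same
Category cell toward the Same Word baseline (a negative value = adaptation).
The subject intercept is shared by every cell of a subject, so it cancels
exactly in the baseline-subtracted contrasts the downstream mixed model
analyses — mirroring a study in which between-subject variability contributes
next to nothing to the contrast variance.

``gen_lmm_contrasts`` is the direct generative counterpart of that contrast
mixed model: it draws contrast values with a subject random intercept whose
variance fraction (the intraclass correlation) is specified explicitly, plus
optional fixed cell effects. It is the tool for parameter-recovery studies of
the ICC estimator and for power simulations of the factorial interaction
tests.

``gen_bold_voxels`` expands cell betas into a rank-1 voxel pattern (random
positive voxel loadings) plus independent voxel noise so that eigenvariate
extraction has a ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoldSimConfig",
    "DEFAULT_ADAPTATION_MAP",
    "design_cells",
    "gen_bold",
    "gen_bold_voxels",
    "gen_lmm_contrasts",
]

#: Default planted Same-Category adaptation (BOLD units), emulating selective
#: adaptation of an anterior middle temporal region by the emotion/attitude
#: abstract categories and of an anterior fusiform region by the concrete
#: categories.
DEFAULT_ADAPTATION_MAP = {
    ("L-MTG", "EM"): -2800.0,
    ("L-MTG", "ATT"): -2750.0,
    ("L-FG", "BIOL"): -3400.0,
    ("L-FG", "ART"): -2900.0,
}

_DEF_ROIS = ("L-MTG", "L-FG") + tuple(f"roi{i:02d}" for i in range(3, 27))


@dataclass(frozen=True)
class BoldSimConfig:
    """Configuration of the beta-table generator.

    Magnitudes are arbitrary BOLD units on the scale of first-level beta
    estimates (grand mean ~10^4, effects and noise ~10^3).
    """

    n_subjects: int = 36
    rois: Sequence[str] = _DEF_ROIS
    adaptation_map: Mapping[tuple, float] = field(
        default_factory=lambda: dict(DEFAULT_ADAPTATION_MAP)
    )
    grand_mean: float = 12000.0
    sc_shift: float = 1500.0
    dc_shift: float = 1800.0
    subject_sd: float = 100.0
    residual_sd: float = 1000.0
    n_voxels_per_roi: int = 30
    voxel_noise_sd: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if len(self.rois) < 1:
            raise ValueError("at least one ROI is required")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be non-negative")
        if self.n_voxels_per_roi < 1:
            raise ValueError("n_voxels_per_roi must be positive")

    @property
    def n_rois(self) -> int:
        return len(self.rois)


def design_cells(design: pd.DataFrame) -> pd.DataFrame:
    """Distinct (condition, domain, category) cells of a trial table.

    Same Category cells are category specific; Different Category and Same
    Word cells are pooled at domain level (category empty), matching a
    first-level model with one regressor per Same-Category category and one
    per domain for the mixed-category and baseline conditions.
    """
    needed = {"condition", "domain", "prime_category"}
    if not needed <= set(design.columns):
        raise ValueError(f"trial table is missing columns: {sorted(needed - set(design.columns))}")
    cells = []
    for (cond, dom), grp in design.groupby(["condition", "domain"], sort=True):
        if cond == "SameCategory":
            for cat in sorted(grp["prime_category"].unique()):
                cells.append({"condition": cond, "domain": dom, "category": cat})
        else:
            cells.append({"condition": cond, "domain": dom, "category": ""})
    return pd.DataFrame(cells)


def _check_design(cells: pd.DataFrame) -> None:
    conds = set(cells["condition"])
    missing = {"SameCategory", "DifferentCategory", "SameWord"} - conds
    if missing:
        raise ValueError(f"design is missing conditions: {sorted(missing)}")


def gen_bold(config: BoldSimConfig, design: pd.DataFrame) -> pd.DataFrame:
    """Generate a beta table (subject, roi, condition, domain, category, value).

    ``design`` is a trial table from :func:`semadapt.design.build_runs`; its
    distinct condition cells define the beta cells. Every key of
    ``adaptation_map`` must name an (ROI, category) pair present in the
    design. Fixed seed implies bit-identical output.
    """
    cells = design_cells(design)
    _check_design(cells)
    rois = [str(r) for r in config.rois]
    sc_cats = set(cells.loc[cells["condition"] == "SameCategory", "category"])
    for roi, cat in config.adaptation_map:
        if str(roi) not in rois:
            raise ValueError(f"adaptation_map ROI {roi!r} not in config.rois")
        if cat not in sc_cats:
            raise ValueError(f"adaptation_map category {cat!r} not in the design")

    rng = np.random.default_rng(config.seed)
    shift = {"SameWord": 0.0, "SameCategory": config.sc_shift, "DifferentCategory": config.dc_shift}
    rows = []
    for s in range(config.n_subjects):
        subj = f"sub{s:02d}"
        intercept = rng.normal(0.0, config.subject_sd)
        for roi in rois:
            for _, cell in cells.iterrows():
                eff = shift[cell["condition"]]
                if cell["condition"] == "SameCategory":
                    eff += config.adaptation_map.get((roi, cell["category"]), 0.0)
                rows.append(
                    {
                        "subject": subj,
                        "roi": roi,
                        "condition": cell["condition"],
                        "domain": cell["domain"],
                        "category": cell["category"],
                        "value": config.grand_mean
                        + intercept
                        + eff
                        + rng.normal(0.0, config.residual_sd),
                    }
                )
    return pd.DataFrame(rows)


def gen_bold_voxels(
    config: BoldSimConfig, design: pd.DataFrame
) -> tuple[dict, pd.DataFrame]:
    """Voxel-level variant: per (subject, roi), a voxels x cells matrix.

    Each matrix is ``u beta^T + noise`` with positive voxel loadings ``u``
    drawn once per ROI (rank-1 shared component), so the first right singular
    vector recovers the cell beta profile. Returns ``(matrices, cells)`` where
    ``matrices`` maps (subject, roi) to an array and ``cells`` indexes the
    columns.
    """
    betas = gen_bold(config, design)
    cells = design_cells(design)
    rng = np.random.default_rng(config.seed + 1)
    loadings = {
        str(roi): rng.uniform(0.5, 1.5, size=config.n_voxels_per_roi)
        for roi in config.rois
    }
    matrices = {}
    key_cols = ["condition", "domain", "category"]
    cell_index = pd.MultiIndex.from_frame(cells[key_cols])
    for (subj, roi), grp in betas.groupby(["subject", "roi"], sort=True):
        beta_vec = (
            grp.set_index(key_cols)["value"].reindex(cell_index).to_numpy(dtype=float)
        )
        u = loadings[str(roi)]
        mat = np.outer(u, beta_vec) + rng.normal(
            0.0, config.voxel_noise_sd, size=(len(u), len(beta_vec))
        )
        matrices[(subj, str(roi))] = mat
    return matrices, cells


def gen_lmm_contrasts(
    n_subjects: int = 36,
    rois: Sequence[str] | int = 26,
    icc: float = 0.0,
    total_sd: float = 1000.0,
    categories: Mapping[str, Sequence[str]] | None = None,
    cell_effects: Mapping[tuple, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw contrast values directly from the mixed model.

    Each subject contributes one value per (roi, contrast condition, domain,
    category) cell:

        value = cell_effect + subject_intercept + residual

    with subject-intercept variance ``icc * total_sd**2`` and residual
    variance ``(1 - icc) * total_sd**2``, so ``icc`` is the intraclass
    correlation of the generated table. ``cell_effects`` maps
    (condition, domain, roi) — or (condition, domain, roi, category) — to a
    fixed shift. Default categories: four abstract, two concrete.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    if total_sd <= 0:
        raise ValueError("total_sd must be positive")
    if isinstance(rois, int):
        rois = [f"roi{i:02d}" for i in range(1, rois + 1)]
    rois = [str(r) for r in rois]
    if categories is None:
        categories = {"ABS": ("EM", "COG", "ATT", "ACT"), "CNC": ("BIOL", "ART")}
    cell_effects = dict(cell_effects or {})

    subject_sd = float(np.sqrt(icc) * total_sd)
    residual_sd = float(np.sqrt(1.0 - icc) * total_sd)
    rng = np.random.default_rng(seed)
    conditions = ("SameCategory-SameWord", "DifferentCategory-SameWord")

    rows = []
    for s in range(n_subjects):
        subj = f"sub{s:02d}"
        intercept = rng.normal(0.0, subject_sd) if subject_sd > 0 else 0.0
        for roi in rois:
            for cond in conditions:
                for dom, cats in categories.items():
                    for cat in cats:
                        eff = cell_effects.get(
                            (cond, dom, roi), 0.0
                        ) + cell_effects.get((cond, dom, roi, cat), 0.0)
                        rows.append(
                            {
                                "subject": subj,
                                "roi": roi,
                                "condition": cond,
                                "domain": dom,
                                "category": cat,
                                "value": eff + intercept + rng.normal(0.0, residual_sd),
                            }
                        )
    return pd.DataFrame(rows)
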