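"""Adaptation analysis of region-level BOLD estimates.

The analysis chain mirrors a repetition-suppression ROI study:

1. ``extract_eigenvariate`` summarizes a voxels x observations beta matrix by
   the first right singular vector of its (optionally grand-mean scaled)
   SVD, sign-aligned with the across-voxel mean series and rescaled to the
   amplitude of an average voxel.
2. ``adaptation_contrasts`` subtracts the Same Word baseline (identical-word
   repetition, isolating word-form effects) per subject, region and domain
   from the Same Category and Different Category estimates. A *smaller*
   Same Category - Same Word value indicates a *larger* adaptation effect.
3. ``fit_adaptation_lmm`` fits a linear mixed model with
   CONDITION x DOMAIN x ROI fixed effects and a participant random
   intercept (REML), reporting joint Wald tests for every factorial term,
   the Wald Z of the random-intercept variance and the intraclass
   correlation ICC = sigma^2_subject / (sigma^2_subject + sigma^2_residual).
4. ``posthoc_categories`` compares categories within a region and domain
   (one-way ANOVA for more than two categories, a paired t-test for two)
   with Bonferroni-adjusted pairwise paired t-tests and Cohen's d.
5. ``flag_adaptation`` applies a decision rule for the presence of
   adaptation in a (region, category) cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONTRAST_SC",
    "CONTRAST_DC",
    "AdaptationLmmResult",
    "extract_eigenvariate",
    "adaptation_contrasts",
    "fit_adaptation_lmm",
    "detect_roi_interactions",
    "pairwise_comparisons",
    "posthoc_categories",
    "flag_adaptation",
]

CONTRAST_SC = "SameCategory-SameWord"
CONTRAST_DC = "DifferentCategory-SameWord"

_BETA_COLUMNS = ("subject", "roi", "condition", "domain", "category", "value")


# ---------------------------------------------------------------------------
# Eigenvariate extraction
# ---------------------------------------------------------------------------

def extract_eigenvariate(voxel_matrix, scaling_mode: str = "grand_mean") -> np.ndarray:
    """First-singular-component summary of a voxels x observations matrix.

    With ``scaling_mode="grand_mean"`` the matrix is divided by its grand
    mean before the SVD and the output is rescaled back to input units. The
    returned series is ``s1 * v1 / sqrt(n_voxels)`` — the first right
    singular vector scaled to the amplitude of an average voxel, so an ROI of
    identical voxels returns exactly their common series — with its sign
    chosen so the correlation with the across-voxel mean series is
    non-negative.
    """
    y = np.asarray(voxel_matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 2:
        raise ValueError("voxel matrix must be 2-D with >= 1 voxel and >= 2 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("voxel matrix contains non-finite values")
    if np.all(y == 0):
        raise ValueError("voxel matrix is identically zero")
    if scaling_mode not in ("none", "grand_mean"):
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")

    scale = 1.0
    if scaling_mode == "grand_mean":
        gm = y.mean()
        if gm == 0:
            raise ValueError("grand mean is zero; cannot grand-mean scale")
        y = y / gm
        scale = gm

    _, s, vt = np.linalg.svd(y, full_matrices=False)
    if s[0] <= 0 or not np.isfinite(s[0]):
        raise ValueError("voxel matrix has rank 0 after scaling")
    e = s[0] * vt[0] / np.sqrt(y.shape[0])

    mean_series = y.mean(axis=0)
    em, mm = e - e.mean(), mean_series - mean_series.mean()
    align = float(em @ mm)
    if align == 0.0:
        align = float(e @ mean_series)
    if align < 0:
        e = -e
    return scale * e


# ---------------------------------------------------------------------------
# Contrasts against the Same Word baseline
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {missing}")


def adaptation_contrasts(betas: pd.DataFrame) -> pd.DataFrame:
    """Per-subject Same Word baseline subtraction at category and domain
    granularity.

    ``betas`` is a long table (subject, roi, condition, domain, category,
    value) holding the Same Word cell per (subject, roi, domain) plus Same /
    Different Category cells (category may be empty for domain-level cells,
    e.g. Different Category estimates pooled over target categories).

    Returns a long table with columns (subject, roi, domain, category,
    contrast, granularity, value): category-level rows subtract the domain's
    Same Word baseline from each category cell; domain-level rows average the
    category-level contrasts within (subject, roi, domain, contrast).
    """
    _require_columns(betas, _BETA_COLUMNS, "beta table")
    if not np.all(np.isfinite(betas["value"].to_numpy(dtype=float))):
        raise ValueError("beta table contains non-finite values")

    sw = betas[betas["condition"] == "SameWord"]
    baseline = sw.set_index(["subject", "roi", "domain"])["value"]
    if baseline.index.duplicated().any():
        dup = baseline.index[baseline.index.duplicated()][0]
        raise ValueError(f"duplicate Same Word baseline cell {dup}")

    rows = []
    for _, row in betas[betas["condition"] != "SameWord"].iterrows():
        key = (row["subject"], row["roi"], row["domain"])
        if key not in baseline.index:
            raise ValueError(
                f"missing Same Word baseline for subject={key[0]!r} roi={key[1]!r} "
                f"domain={key[2]!r}"
            )
        contrast = (
            CONTRAST_SC if row["condition"] == "SameCategory" else CONTRAST_DC
        )
        rows.append(
            {
                "subject": row["subject"],
                "roi": row["roi"],
                "domain": row["domain"],
                "category": row["category"],
                "contrast": contrast,
                "granularity": "category",
                "value": float(row["value"]) - float(baseline.loc[key]),
            }
        )
    cat = pd.DataFrame(rows)
    if cat.empty:
        raise ValueError("beta table holds no non-baseline conditions")

    dom = (
        cat.groupby(["subject", "roi", "domain", "contrast"], sort=False, dropna=False)["value"]
        .mean()
        .reset_index()
    )
    dom["category"] = ""
    dom["granularity"] = "domain"
    out = pd.concat([cat, dom[cat.columns]], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class AdaptationLmmResult:
    """Summary of the CONDITION x DOMAIN x ROI mixed model."""

    fixed_effects: pd.DataFrame
    term_tests: pd.DataFrame
    var_subject: float
    var_residual: float
    icc: float
    wald_z_subject: float
    p_subject: float
    n_obs: int
    n_subjects: int
    formula: str
    converged: bool
    result: object = field(repr=False, default=None)


def _term_groups(exog_names) -> dict[str, list[str]]:
    factors = {"condition": "C(condition)", "domain": "C(domain)", "roi": "C(roi)"}
    groups: dict[str, list[str]] = {}
    for term in (
        "condition",
        "domain",
        "roi",
        "condition:domain",
        "condition:roi",
        "domain:roi",
        "condition:domain:roi",
    ):
        wanted = set(term.split(":"))
        members = []
        for name in exog_names:
            if name == "Intercept":
                continue
            present = {f for f, tag in factors.items() if tag in name}
            if present == wanted and name.count(":") == len(wanted) - 1:
                members.append(name)
        groups[term] = members
    return groups


def _summarize_fixed_effects(res) -> tuple[pd.DataFrame, pd.DataFrame]:
    fe = pd.DataFrame(
        {
            "coef": res.fe_params,
            "se": res.bse_fe,
            "z": res.fe_params / res.bse_fe,
            "p": 2 * stats.norm.sf(np.abs(res.fe_params / res.bse_fe)),
        }
    )
    rows = []
    for term, names in _term_groups(res.model.exog_names).items():
        if not names:
            continue
        constraint = ", ".join(f"{n} = 0" for n in names)
        wt = res.wald_test(constraint, scalar=True)
        rows.append(
            {
                "term": term,
                "df": len(names),
                "statistic": float(wt.statistic),
                "p_value": float(wt.pvalue),
            }
        )
    return fe, pd.DataFrame(rows, columns=["term", "df", "statistic", "p_value"])


def fit_adaptation_lmm(contrasts: pd.DataFrame, reml: bool = True) -> AdaptationLmmResult:
    """Fit the contrast mixed model with a participant random intercept.

    ``contrasts`` is a long table with columns (subject, roi, condition,
    domain, value); the ``condition`` factor holds the contrast labels
    (Same Category - Same Word, Different Category - Same Word). Fixed
    effects are the full CONDITION x DOMAIN x ROI factorial; the participant
    enters as a random intercept and the model is estimated by REML.

    Reports joint Wald chi-square tests per factorial term, the random-effect
    variance with its Wald Z, and the intraclass correlation. Raises when a
    factorial cell has no observations (the design would be rank deficient),
    listing the missing cells.
    """
    import warnings

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    _require_columns(contrasts, ("subject", "roi", "condition", "domain", "value"), "contrast table")
    df = contrasts.copy()
    df["value"] = df["value"].astype(float)

    counts = df.groupby(["condition", "domain", "roi"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["condition"].unique()), sorted(df["domain"].unique()), sorted(df["roi"].unique())],
        names=["condition", "domain", "roi"],
    )
    empty_cells = [tuple(c) for c in full.difference(counts.index)]
    if empty_cells:
        raise ValueError(f"design is rank deficient; empty cells: {empty_cells[:10]}")

    formula = "value ~ C(condition) * C(domain) * C(roi)"
    model = smf.mixedlm(formula, df, groups=df["subject"])
    with warnings.catch_warnings():
        # A subject variance estimated at the zero boundary is an expected,
        # meaningful outcome (near-zero between-subject variance), not a
        # numerical failure; the converged flag is still reported.
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        res = None
        for method in (None, "lbfgs", "powell"):
            try:
                res = model.fit(reml=reml) if method is None else model.fit(
                    reml=reml, method=method
                )
                break
            except np.linalg.LinAlgError:
                continue
        if res is None:
            raise np.linalg.LinAlgError(
                "mixed model optimization failed with every optimizer"
            )

        fe, term_tests = _summarize_fixed_effects(res)

    var_subject = float(res.cov_re.iloc[0, 0])
    var_residual = float(res.scale)
    icc = var_subject / (var_subject + var_residual)
    # Asymptotic SE of the subject-variance estimate in a balanced
    # random-intercept model: sqrt(2/n) * (sigma^2_u + sigma^2_e / k), with k
    # the (mean) number of observations per subject.
    n_subj = int(df["subject"].nunique())
    k_bar = len(df) / n_subj
    se_re = np.sqrt(2.0 / n_subj) * (var_subject + var_residual / k_bar)
    wald_z = var_subject / se_re if se_re > 0 else np.nan
    p_subject = float(2 * stats.norm.sf(abs(wald_z))) if np.isfinite(wald_z) else np.nan

    return AdaptationLmmResult(
        fixed_effects=fe,
        term_tests=term_tests,
        var_subject=var_subject,
        var_residual=var_residual,
        icc=icc,
        wald_z_subject=wald_z,
        p_subject=p_subject,
        n_obs=int(len(df)),
        n_subjects=int(df["subject"].nunique()),
        formula=formula,
        converged=bool(res.converged),
        result=res,
    )


def detect_roi_interactions(contrasts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """ROI-specific CONDITION x DOMAIN x ROI interaction probe.

    For every (condition, ROI) cell the abstract and concrete domain values
    (per-subject means across categories) are compared with a paired t-test;
    p-values are Bonferroni-adjusted over the whole family (all conditions x
    ROIs). A significant adjusted comparison localizes a domain-by-condition
    difference to that ROI — the ROI-resolved reading of the three-way
    interaction, complementing the omnibus Wald test of
    :func:`fit_adaptation_lmm`.

    ``contrasts`` needs columns (subject, roi, condition, domain, value).
    Returns one row per (condition, roi) with the mean domain difference, its
    confidence interval, raw and adjusted p-values and a ``significant`` flag.
    """
    _require_columns(contrasts, ("subject", "roi", "condition", "domain", "value"), "contrast table")
    domains = sorted(contrasts["domain"].unique())
    if len(domains) != 2:
        raise ValueError(f"expected exactly two domains, found {domains}")
    cells = [
        (cond, roi)
        for cond in sorted(contrasts["condition"].unique())
        for roi in sorted(contrasts["roi"].unique())
    ]
    family = len(cells)
    rows = []
    for cond, roi in cells:
        sub = contrasts[(contrasts["condition"] == cond) & (contrasts["roi"] == roi)]
        va, vb = _paired_cells(sub, "domain", domains[0], domains[1])
        diff = va - vb
        n = len(diff)
        if n < 2:
            raise ValueError(f"cell ({cond!r}, {roi!r}) has fewer than 2 subjects")
        mean = float(diff.mean())
        if np.allclose(diff, diff[0]):
            t, p = (0.0, 1.0) if np.isclose(mean, 0.0) else (np.inf, 0.0)
            sem = 0.0
        else:
            t, p = stats.ttest_rel(va, vb)
            sem = float(stats.sem(diff))
        half = stats.t.ppf(1 - alpha / 2, n - 1) * sem
        p_adj = min(1.0, float(p) * family) if np.isfinite(p) else 1.0
        rows.append(
            {
                "condition": cond,
                "roi": roi,
                "domain_a": domains[0],
                "domain_b": domains[1],
                "mean_diff": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": p_adj,
                "family_size": family,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Post-hoc comparisons
# ---------------------------------------------------------------------------

def _paired_cells(df: pd.DataFrame, factor: str, a, b) -> tuple[np.ndarray, np.ndarray]:
    wide = df.pivot_table(index="subject", columns=factor, values="value", aggfunc="mean")
    if a not in wide.columns or b not in wide.columns:
        raise ValueError(f"levels {a!r}/{b!r} not found in {factor!r}")
    sub = wide[[a, b]].dropna()
    return sub[a].to_numpy(), sub[b].to_numpy()


def pairwise_comparisons(
    df: pd.DataFrame, factor: str, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise paired t-tests between levels of ``factor``.

    Observations are paired by ``subject``. Reports the mean difference with
    its two-sided (1 - alpha) confidence interval, raw and
    Bonferroni-adjusted p-values (family size = number of comparisons,
    recorded per row) and Cohen's d = mean difference / pooled SD of the two
    cells.
    """
    levels = sorted(df[factor].unique())
    combos = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    family = len(combos)
    rows = []
    for a, b in combos:
        va, vb = _paired_cells(df, factor, a, b)
        if len(va) < 2:
            raise ValueError(f"levels {a!r}/{b!r} have fewer than 2 paired observations")
        diff = va - vb
        n = len(diff)
        mean = float(diff.mean())
        if np.allclose(diff, diff[0]):
            t, p = (0.0, 1.0) if np.isclose(mean, 0.0) else (np.inf, 0.0)
            sem = 0.0
        else:
            t, p = stats.ttest_rel(va, vb)
            t, p = float(t), float(p)
            sem = float(stats.sem(diff))
        half = stats.t.ppf(1 - alpha / 2, n - 1) * sem
        pooled = np.sqrt((va.std(ddof=1) ** 2 + vb.std(ddof=1) ** 2) / 2)
        d = mean / pooled if pooled > 0 else 0.0
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "n": n,
                "mean_diff": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "t": t,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * family),
                "family_size": family,
                "cohen_d": float(d),
            }
        )
    return pd.DataFrame(rows)


def posthoc_categories(
    contrasts: pd.DataFrame, roi, domain: str, alpha: float = 0.05
) -> dict:
    """Category effects on the Same Category - Same Word contrast in one ROI.

    With more than two categories a one-way ANOVA across categories is run
    (observations = subjects); with exactly two, a paired t-test. All
    pairwise category comparisons follow with Bonferroni adjustment and
    Cohen's d. Returns a dict with keys ``omnibus`` (test name, statistic,
    df, p) and ``pairwise`` (table from :func:`pairwise_comparisons`).
    """
    sel = contrasts[
        (contrasts["roi"] == roi)
        & (contrasts["domain"] == domain)
        & (contrasts["contrast"] == CONTRAST_SC)
        & (contrasts["granularity"] == "category")
    ]
    cats = sorted(sel["category"].unique())
    if len(cats) < 2:
        raise ValueError(f"need >= 2 categories in roi={roi!r} domain={domain!r}")
    groups = [sel.loc[sel["category"] == c, "value"].to_numpy(dtype=float) for c in cats]
    for c, g in zip(cats, groups):
        if len(g) < 2:
            raise ValueError(f"category {c!r} has fewer than 2 observations")

    if len(cats) == 2:
        va, vb = _paired_cells(sel, "category", cats[0], cats[1])
        diff = va - vb
        if np.allclose(diff, diff[0]):
            t, p = (0.0, 1.0) if np.isclose(diff.mean(), 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(va, vb)
        omnibus = {
            "test": "paired_t",
            "statistic": float(t),
            "df": len(va) - 1,
            "p_value": float(p),
        }
    else:
        f, p = stats.f_oneway(*groups)
        omnibus = {
            "test": "anova",
            "statistic": float(f),
            "df": (len(cats) - 1, sum(len(g) for g in groups) - len(cats)),
            "p_value": float(p),
        }
    pairwise = pairwise_comparisons(sel, "category", alpha=alpha)
    return {"roi": roi, "domain": domain, "omnibus": omnibus, "pairwise": pairwise}


def flag_adaptation(
    contrasts: pd.DataFrame, roi, category: str, alpha: float = 0.05
) -> str:
    """Decide whether a (roi, category) cell shows adaptation.

    The cell's Same Category - Same Word values (one per subject) are flagged
    ``"adapted"`` when their (1 - alpha) confidence interval excludes zero
    and the cell mean is either negative or strictly the lowest among the
    domain's categories in that ROI; otherwise ``"not_adapted"``. A smaller
    baseline-relative signal change marks a stronger adaptation effect.
    """
    sel = contrasts[
        (contrasts["roi"] == roi)
        & (contrasts["contrast"] == CONTRAST_SC)
        & (contrasts["granularity"] == "category")
    ]
    cell = sel[sel["category"] == category]
    if cell.empty:
        raise ValueError(f"no contrast cells for roi={roi!r} category={category!r}")
    vals = cell["value"].to_numpy(dtype=float)
    mean = float(vals.mean())
    if len(vals) < 2 or np.allclose(vals, vals[0]):
        excludes_zero = mean != 0.0
    else:
        sem = stats.sem(vals)
        half = stats.t.ppf(1 - alpha / 2, len(vals) - 1) * sem
        excludes_zero = (mean - half > 0) or (mean + half < 0)

    domain = str(cell["domain"].iloc[0])
    means = (
        sel[sel["domain"] == domain].groupby("category")["value"].mean().sort_values()
    )
    lowest = (
        len(means) > 1 and means.index[0] == category and means.iloc[0] < means.iloc[1]
    )
    adapted = excludes_zero and (mean < 0 or lowest)
    return "adapted" if adapted else "not_adapted"
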