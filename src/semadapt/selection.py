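"""Combination of literature and database indexes into a final ROI set.

A region enters the semantic set when its paradigm control-type mean exceeds
0.6, and the control set when it falls below -0.6 (strict inequalities; the
dead zone, including the exact boundaries, is excluded). Secondary criteria —
concordance between the two information sources (the semantic-control
differential, sensitivity index minus control-type mean), high domain
specificity, and sign agreement of the literature sensitivity index with the
candidate class — are applied as configurable filters, and every exclusion is
recorded in an audit table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_TYPE_CUT",
    "SelectionConfig",
    "sc_differential",
    "classify_by_control_type",
    "select_rois",
]

#: Control-type mean cut for candidate classification (strict on both sides).
CONTROL_TYPE_CUT = 0.6

_CANDIDATE_COLUMNS = (
    "region_label",
    "sensitivity_index",
    "correction_level_index",
    "control_type_mean",
    "domain_specificity",
)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for the secondary selection criteria.

    ``specificity_quantile``: candidates must reach at least this quantile of
    domain specificity among candidates passing the control-type gate.
    ``max_abs_differential``: largest tolerated |semantic-control
    differential|. ``require_sign_concordance``: the sensitivity index must
    agree in sign with the candidate class. ``min_correction_level``: optional
    hard floor on the correction-level index (carried through and reported
    either way).
    """

    specificity_quantile: float = 0.5
    max_abs_differential: float = 0.5
    require_sign_concordance: bool = True
    min_correction_level: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.specificity_quantile <= 1.0:
            raise ValueError("specificity_quantile must lie in [0, 1]")
        if self.max_abs_differential < 0:
            raise ValueError("max_abs_differential must be non-negative")


def _check_range(name: str, value: float) -> float:
    value = float(value)
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"{name} = {value} outside [-1, 1]")
    return value


def sc_differential(sensitivity_index: float, control_type_mean: float) -> float:
    """Semantic-control differential: sensitivity index minus control-type
    mean, in [-2, 2]. Zero indicates perfect concordance of the two sources."""
    s = _check_range("sensitivity_index", sensitivity_index)
    c = _check_range("control_type_mean", control_type_mean)
    return s - c


def classify_by_control_type(control_type_mean: float) -> str:
    """Classify a region by its control-type mean: > 0.6 semantic candidate,
    < -0.6 control candidate, otherwise (including exactly +/-0.6) excluded."""
    c = _check_range("control_type_mean", control_type_mean)
    if c > CONTROL_TYPE_CUT:
        return "semantic_candidate"
    if c < -CONTROL_TYPE_CUT:
        return "control_candidate"
    return "excluded"


def select_rois(
    candidates: pd.DataFrame, config: SelectionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the selection rule to a candidate table.

    ``candidates`` must contain the columns ``region_label``,
    ``sensitivity_index``, ``correction_level_index``, ``control_type_mean``
    and ``domain_specificity`` with no missing index values.

    Returns ``(selected, audit)``: ``selected`` carries the surviving regions
    with ``assigned_class`` in {semantic, control} and their
    ``sc_differential``; ``audit`` has one row per input candidate listing
    every filter outcome and the reasons for exclusion. The specificity cut is
    the configured quantile of ``domain_specificity`` among candidates passing
    the (fixed) control-type gate, so it does not depend on the tunable
    filters. Selection is deterministic and invariant to candidate order.
    """
    if config is None:
        config = SelectionConfig()
    missing = set(_CANDIDATE_COLUMNS) - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    if candidates.empty:
        warnings.warn("empty candidate table: empty selection", stacklevel=2)
        empty = candidates.copy()
        empty["sc_differential"] = pd.Series(dtype=float)
        empty["assigned_class"] = pd.Series(dtype=object)
        return empty, empty.assign(reasons=pd.Series(dtype=object))

    index_cols = [c for c in _CANDIDATE_COLUMNS if c != "region_label"]
    if candidates[index_cols].isna().any().any():
        bad = candidates.columns[candidates[index_cols].isna().any().reindex(candidates.columns, fill_value=False)]
        raise ValueError(f"candidate table has missing values in {list(bad)}")

    df = candidates.sort_values("region_label", kind="stable").reset_index(drop=True).copy()
    df["sc_differential"] = [
        sc_differential(s, c)
        for s, c in zip(df["sensitivity_index"], df["control_type_mean"])
    ]
    df["candidate_class"] = df["control_type_mean"].map(classify_by_control_type)

    gate = df["candidate_class"] != "excluded"
    if gate.any():
        spec_cut = float(
            np.quantile(df.loc[gate, "domain_specificity"], config.specificity_quantile)
        )
    else:
        spec_cut = np.inf

    reasons = []
    keep = []
    for _, row in df.iterrows():
        why = []
        if row["candidate_class"] == "excluded":
            why.append("control_type_mean in dead zone [-0.6, 0.6]")
        else:
            if abs(row["sc_differential"]) > config.max_abs_differential:
                why.append(
                    f"|sc_differential| {abs(row['sc_differential']):.3f} > "
                    f"{config.max_abs_differential}"
                )
            if config.require_sign_concordance:
                want = 1.0 if row["candidate_class"] == "semantic_candidate" else -1.0
                if np.sign(row["sensitivity_index"]) != want:
                    why.append("sensitivity_index sign discordant with candidate class")
            if row["domain_specificity"] < spec_cut:
                why.append(
                    f"domain_specificity {row['domain_specificity']:.3f} below "
                    f"quantile cut {spec_cut:.3f}"
                )
            if (
                config.min_correction_level is not None
                and row["correction_level_index"] < config.min_correction_level
            ):
                why.append(
                    f"correction_level_index {row['correction_level_index']:.3f} < "
                    f"{config.min_correction_level}"
                )
        reasons.append("; ".join(why) if why else "selected")
        keep.append(not why)

    audit = df.assign(selected=keep, reasons=reasons, specificity_cut=spec_cut)
    selected = df[np.asarray(keep)].copy()
    selected["assigned_class"] = selected["candidate_class"].map(
        {"semantic_candidate": "semantic", "control_candidate": "control"}
    )
    selected = selected.drop(columns=["candidate_class"]).reset_index(drop=True)
    return selected, audit
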