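"""Synthetic behavioral-domain and paradigm-class region profiles.

Emulates a coordinate-database characterization of brain regions. Each region
has a planted class (semantic, control or ambiguous) controlling

* its paradigm control-type code distribution — planted semantic regions draw
  codes concentrated at 1 (expected control-type mean 0.85 > 0.6), planted
  control regions at -1 (expectation -0.8 < -0.6) and ambiguous regions sit
  in the dead zone (expectation 0.25);
* its behavioral-domain profile — semantic regions are active in few domains
  with high activation likelihoods (high domain specificity), control regions
  in many domains with moderate likelihoods.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..brainmap import load_taxonomy

__all__ = ["PARADIGM_CODE_DIST", "PROFILE_SHAPES", "gen_brainmap_profiles"]

#: Per planted class: probabilities of drawing paradigm codes (1, 0.5, -1).
PARADIGM_CODE_DIST = {
    "semantic": {1.0: 0.85, 0.5: 0.10, -1.0: 0.05},
    "control": {1.0: 0.05, 0.5: 0.10, -1.0: 0.85},
    "ambiguous": {1.0: 0.25, 0.5: 0.50, -1.0: 0.25},
}

#: Per planted class: (micro-domain count range, P range) for domain profiles.
PROFILE_SHAPES = {
    "semantic": {"n_micro": (1, 3), "p": (0.6, 0.95)},
    "control": {"n_micro": (4, 8), "p": (0.2, 0.6)},
    "ambiguous": {"n_micro": (2, 5), "p": (0.3, 0.7)},
}


def expected_control_type_mean(planted_class: str) -> float:
    """Expectation of the control-type mean under the configured code
    distribution for a planted class."""
    dist = PARADIGM_CODE_DIST[planted_class]
    return float(sum(code * p for code, p in dist.items()))


def gen_brainmap_profiles(
    region_labels: Sequence,
    planted_class: Mapping | Sequence[str] | str,
    seed: int = 0,
    n_paradigms: int = 12,
    taxonomy: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate domain and paradigm profile tables for the given regions.

    ``planted_class`` is a per-region mapping/sequence (or one label for all)
    with values in {semantic, control, ambiguous}. Returns
    ``(profiles, paradigms)``: ``profiles`` is long format (region_label,
    domain, P, planted_class); ``paradigms`` is (region_label, code,
    planted_class). Fixed seed implies bit-identical output.
    """
    region_labels = [str(r) for r in region_labels]
    if len(region_labels) == 0:
        raise ValueError("region list is empty")
    if isinstance(planted_class, str):
        classes = {r: planted_class for r in region_labels}
    elif isinstance(planted_class, Mapping):
        classes = {str(k): v for k, v in planted_class.items()}
    else:
        if len(planted_class) != len(region_labels):
            raise ValueError("planted_class length must match region_labels")
        classes = dict(zip(region_labels, planted_class))
    bad = set(classes.values()) - set(PARADIGM_CODE_DIST)
    if bad:
        raise ValueError(f"unknown planted classes {sorted(bad)}")
    if n_paradigms < 1:
        raise ValueError("n_paradigms must be positive")

    if taxonomy is None:
        taxonomy = load_taxonomy()
    micros = sorted(taxonomy["micro_domain"])

    rng = np.random.default_rng(seed)
    profile_rows, paradigm_rows = [], []
    for region in region_labels:
        klass = classes[region]
        lo, hi = PROFILE_SHAPES[klass]["n_micro"]
        k = int(rng.integers(lo, hi + 1))
        chosen = sorted(rng.choice(micros, size=min(k, len(micros)), replace=False))
        p_lo, p_hi = PROFILE_SHAPES[klass]["p"]
        for dom in chosen:
            profile_rows.append(
                {
                    "region_label": region,
                    "domain": dom,
                    "P": float(np.round(rng.uniform(p_lo, p_hi), 6)),
                    "planted_class": klass,
                }
            )
        dist = PARADIGM_CODE_DIST[klass]
        codes = rng.choice(
            list(dist.keys()), size=n_paradigms, p=list(dist.values())
        )
        for code in codes:
            paradigm_rows.append(
                {"region_label": region, "code": float(code), "planted_class": klass}
            )
    profiles = pd.DataFrame(
        profile_rows, columns=["region_label", "domain", "P", "planted_class"]
    )
    paradigms = pd.DataFrame(
        paradigm_rows, columns=["region_label", "code", "planted_class"]
    )
    return profiles, paradigms
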