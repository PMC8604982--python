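"""Meta-analytic database profiling of brain regions.

Scores each region of a coordinate database characterization along two axes:

* *domain specificity*: how narrowly the region's activations concentrate in
  a cognitive domain. A heterogeneity weight ``W`` combines the fraction of
  the taxonomy's micro-domains and macro-domains in which the region is
  active, divided by the region's own number of active domains::

      W = (n_micro_region / total_micro + n_macro_region / total_macro)
          / n_domains_region

  and the specificity for a domain with activation likelihood ``P`` is
  ``W * P``. A region-level summary reduces over the region's domains
  (maximum by default, mean optionally).

* *control-type mean*: experimental paradigms associated with the region are
  coded 1 (predominantly semantic), 0.5 (mixed domain-general /
  language-specific) or -1 (control paradigms, e.g. a flanker task); the
  arithmetic mean in [-1, 1] characterizes the region as semantic (positive)
  or control related (negative).

The default taxonomy shipped with the package has the five macro-domains
Action, Cognition, Emotion, Interoception and Perception with six
micro-domains each (30 in total); an alternative taxonomy table can be
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MACRO_DOMAINS",
    "PARADIGM_CODES",
    "DomainProfile",
    "ParadigmProfile",
    "load_taxonomy",
    "heterogeneity_w",
    "domain_specificity",
    "code_paradigm",
    "control_type_mean",
    "score_regions",
]

MACRO_DOMAINS = ("Action", "Cognition", "Emotion", "Interoception", "Perception")

#: Numeric codes for paradigm control types.
PARADIGM_CODES = {"semantic": 1.0, "mixed": 0.5, "control": -1.0}

_ALLOWED_CODES = frozenset(PARADIGM_CODES.values())


def load_taxonomy(path=None) -> pd.DataFrame:
    """Load a micro->macro domain taxonomy table (columns ``micro_domain``,
    ``macro_domain``). Without ``path`` the packaged default is returned."""
    if path is None:
        with resources.files("semadapt.data").joinpath("brainmap_taxonomy.tsv").open() as fh:
            tax = pd.read_csv(fh, sep="\t")
    else:
        tax = pd.read_csv(path, sep="\t")
    missing = {"micro_domain", "macro_domain"} - set(tax.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    if tax["micro_domain"].duplicated().any():
        dupes = tax.loc[tax["micro_domain"].duplicated(), "micro_domain"].tolist()
        raise ValueError(f"micro-domains assigned to more than one macro-domain: {dupes}")
    return tax


@dataclass(frozen=True)
class DomainProfile:
    """Behavioral-domain profile of one region: active micro/macro domains and
    per-domain activation likelihoods ``P`` in [0, 1]."""

    region_label: str
    micro_domains: frozenset
    macro_domains: frozenset
    P: Mapping[str, float]

    def __post_init__(self):
        for dom, p in self.P.items():
            if not 0.0 <= float(p) <= 1.0:
                raise ValueError(f"P[{dom!r}] = {p} outside [0, 1]")


@dataclass(frozen=True)
class ParadigmProfile:
    """Paradigm-class profile of one region: control-type codes in {1, 0.5, -1}."""

    region_label: str
    paradigm_codes: tuple

    def __post_init__(self):
        if len(self.paradigm_codes) == 0:
            raise ValueError(f"region {self.region_label!r} has no paradigm codes")
        bad = set(self.paradigm_codes) - _ALLOWED_CODES
        if bad:
            raise ValueError(f"invalid paradigm codes {sorted(bad)}")


def heterogeneity_w(
    n_micro_region: int,
    total_micro: int,
    n_macro_region: int,
    total_macro: int,
    n_domains_region: int | None = None,
) -> float:
    """Domain-heterogeneity weight ``W`` (dimensionless, >= 0).

    ``n_domains_region`` defaults to the region's own count of active domains,
    ``n_micro_region + n_macro_region``; an externally supplied count may be
    passed instead.
    """
    if total_micro <= 0 or total_macro <= 0:
        raise ValueError("taxonomy totals must be positive")
    if n_micro_region < 0 or n_macro_region < 0:
        raise ValueError("domain counts must be non-negative")
    if n_micro_region > total_micro or n_macro_region > total_macro:
        raise ValueError("region domain count exceeds taxonomy total")
    if n_domains_region is None:
        n_domains_region = n_micro_region + n_macro_region
        if n_domains_region == 0:
            return 0.0
    if n_domains_region <= 0:
        raise ValueError("n_domains_region must be positive")
    return (n_micro_region / total_micro + n_macro_region / total_macro) / n_domains_region


def domain_specificity(w, p):
    """Domain specificity ``W * P``; ``p`` must lie in [0, 1]."""
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(w < 0):
        raise ValueError("W must be non-negative")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P must lie in [0, 1]")
    out = w * p
    return float(out) if out.ndim == 0 else out


def code_paradigm(control_type: str) -> float:
    """Code a paradigm control type: semantic -> 1, mixed -> 0.5, control -> -1."""
    try:
        return PARADIGM_CODES[control_type]
    except KeyError:
        raise ValueError(f"unknown paradigm control type {control_type!r}") from None


def control_type_mean(codes) -> float:
    """Arithmetic mean of paradigm control-type codes; bounded in [-1, 1]."""
    if isinstance(codes, ParadigmProfile):
        codes = codes.paradigm_codes
    arr = np.asarray(list(codes), dtype=float)
    if arr.size == 0:
        raise ValueError("paradigm code list is empty")
    bad = set(arr.tolist()) - _ALLOWED_CODES
    if bad:
        raise ValueError(f"invalid paradigm codes {sorted(bad)}")
    return float(arr.mean())


def _profiles_from_table(profiles: pd.DataFrame, taxonomy: pd.DataFrame):
    """Build DomainProfile objects from a long table (region_label, domain, P).

    A ``domain`` naming a macro-domain contributes to the macro set directly;
    a micro-domain contributes itself plus its parent macro.
    """
    micro2macro = dict(zip(taxonomy["micro_domain"], taxonomy["macro_domain"]))
    macros = set(taxonomy["macro_domain"])
    out = []
    for label, grp in profiles.groupby("region_label", sort=True):
        micro, macro, pmap = set(), set(), {}
        for _, row in grp.iterrows():
            dom = str(row["domain"])
            if dom in macros:
                macro.add(dom)
            elif dom in micro2macro:
                micro.add(dom)
                macro.add(micro2macro[dom])
            else:
                raise ValueError(f"domain {dom!r} not found in the taxonomy")
            pmap[dom] = float(row["P"])
        out.append(
            DomainProfile(
                region_label=str(label),
                micro_domains=frozenset(micro),
                macro_domains=frozenset(macro),
                P=pmap,
            )
        )
    return out


def score_regions(
    profiles: pd.DataFrame,
    paradigms: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    reduce: str = "max",
    n_domains_region: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Score regions from long-format profile tables.

    ``profiles`` needs columns (region_label, domain, P); ``paradigms`` needs
    (region_label, code) or (region_label, control_type). Returns one row per
    region with ``W``, the reduced ``domain_specificity`` and
    ``control_type_mean``.
    """
    if taxonomy is None:
        taxonomy = load_taxonomy()
    if reduce not in ("max", "mean"):
        raise ValueError(f"unknown reduction {reduce!r}")
    total_micro = int(taxonomy["micro_domain"].nunique())
    total_macro = int(taxonomy["macro_domain"].nunique())

    if "code" in paradigms.columns:
        codes = paradigms["code"].astype(float)
    elif "control_type" in paradigms.columns:
        codes = paradigms["control_type"].map(code_paradigm)
        if codes.isna().any():
            bad = paradigms.loc[codes.isna(), "control_type"].unique().tolist()
            raise ValueError(f"unknown paradigm control types {bad}")
    else:
        raise ValueError("paradigm table needs a 'code' or 'control_type' column")
    paradigms = paradigms.assign(_code=codes)

    rows = []
    for prof in _profiles_from_table(profiles, taxonomy):
        n_dom = None if n_domains_region is None else n_domains_region[prof.region_label]
        w = heterogeneity_w(
            len(prof.micro_domains),
            total_micro,
            len(prof.macro_domains),
            total_macro,
            n_dom,
        )
        specs = [domain_specificity(w, p) for p in prof.P.values()]
        spec = max(specs) if reduce == "max" else float(np.mean(specs))
        pcodes = paradigms.loc[
            paradigms["region_label"].astype(str) == prof.region_label, "_code"
        ]
        if pcodes.empty:
            raise ValueError(f"region {prof.region_label!r} has no paradigm rows")
        rows.append(
            {
                "region_label": prof.region_label,
                "n_micro": len(prof.micro_domains),
                "n_macro": len(prof.macro_domains),
                "W": w,
                "domain_specificity": spec,
                "control_type_mean": control_type_mean(pcodes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_label", "n_micro", "n_macro", "W", "domain_specificity", "control_type_mean"],
    )
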