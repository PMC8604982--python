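"""Synthetic word lexicon with psycholinguistic attributes and relatedness.

Emulates a stimulus-norm table: four abstract categories (emotions EM,
cognitions COG, attitudes ATT, human actions ACT; 24 words each) and two
concrete categories (biological entities BIOL, artefacts ART; 48 words each),
plus a small held-out pool per domain for the Same Word baseline. Attribute
distributions are identical across the categories of a domain by default, so
the categories are matched in expectation; across domains the means differ
where real norms do (concreteness, imageability, context availability,
abstractness).

Pairwise relatedness mimics a cosine similarity between dictionary-gloss
vectors: within-category pairs center on ``relatedness_within``, all other
pairs on ``relatedness_between``, clipped to [0, 1], symmetric with unit
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ATTRIBUTES", "LexiconConfig", "Lexicon", "gen_lexicon"]

#: Attribute columns carried by every word.
ATTRIBUTES = (
    "concreteness",
    "imageability",
    "familiarity",
    "age_of_acquisition",
    "context_availability",
    "abstractness",
    "moa",
    "n_letters",
    "written_freq",
    "spoken_freq",
)

_DEF_CATEGORIES = (
    ("EM", "ABS"),
    ("COG", "ABS"),
    ("ATT", "ABS"),
    ("ACT", "ABS"),
    ("BIOL", "CNC"),
    ("ART", "CNC"),
)

_DEF_COUNTS = {"EM": 24, "COG": 24, "ATT": 24, "ACT": 24, "BIOL": 48, "ART": 48}

# Domain-level attribute means (1-7 rating scales; letters count; log10
# frequencies). Within a domain every category shares the same distribution.
_DEF_MEANS = {
    "ABS": {
        "concreteness": 2.4,
        "imageability": 3.0,
        "familiarity": 5.0,
        "age_of_acquisition": 8.0,
        "context_availability": 3.6,
        "abstractness": 5.4,
        "moa": 4.8,
        "n_letters": 8.0,
        "written_freq": 1.4,
        "spoken_freq": 1.2,
    },
    "CNC": {
        "concreteness": 5.6,
        "imageability": 5.8,
        "familiarity": 5.2,
        "age_of_acquisition": 5.5,
        "context_availability": 5.4,
        "abstractness": 2.2,
        "moa": 2.8,
        "n_letters": 7.0,
        "written_freq": 1.5,
        "spoken_freq": 1.3,
    },
}

_DEF_SDS = {
    "concreteness": 0.6,
    "imageability": 0.7,
    "familiarity": 0.7,
    "age_of_acquisition": 1.6,
    "context_availability": 0.8,
    "abstractness": 0.7,
    "moa": 1.0,
    "n_letters": 2.0,
    "written_freq": 0.5,
    "spoken_freq": 0.5,
}


@dataclass(frozen=True)
class LexiconConfig:
    """Configuration of the synthetic lexicon."""

    categories: Sequence[tuple] = _DEF_CATEGORIES
    n_words_per_category: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEF_COUNTS)
    )
    attribute_means: Mapping[str, Mapping[str, float]] | None = None
    attribute_sds: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_SDS))
    relatedness_within: float = 0.7
    relatedness_between: float = 0.3
    relatedness_sd: float = 0.08
    n_baseline_per_domain: int = 6
    match_attributes: bool = True
    matching_floor: float = 0.06
    seed: int = 0

    def __post_init__(self):
        domains = {d for _, d in self.categories}
        if not domains <= {"ABS", "CNC"}:
            raise ValueError("category domains must be ABS or CNC")
        for cat, _ in self.categories:
            n = self.n_words_per_category.get(cat, 0)
            if n < 2:
                raise ValueError(f"category {cat!r} needs at least 2 words, got {n}")
        for name, sd in self.attribute_sds.items():
            if sd < 0:
                raise ValueError(f"attribute sd for {name!r} must be non-negative")
        for v in (self.relatedness_within, self.relatedness_between):
            if not 0.0 <= v <= 1.0:
                raise ValueError("relatedness values must lie in [0, 1]")
        if self.relatedness_sd < 0:
            raise ValueError("relatedness_sd must be non-negative")
        if self.n_baseline_per_domain < 0:
            raise ValueError("n_baseline_per_domain must be non-negative")
        if not 0.0 <= self.matching_floor < 1.0:
            raise ValueError("matching_floor must lie in [0, 1)")

    def means_for(self, category: str, domain: str) -> Mapping[str, float]:
        if self.attribute_means is not None and category in self.attribute_means:
            return self.attribute_means[category]
        return _DEF_MEANS[domain]


@dataclass
class Lexicon:
    """Generated lexicon: a word table and a symmetric relatedness matrix."""

    words: pd.DataFrame
    relatedness: pd.DataFrame
    config: LexiconConfig

    def main_words(self, domain: str | None = None) -> pd.DataFrame:
        sel = self.words[~self.words["is_baseline"]]
        return sel if domain is None else sel[sel["domain"] == domain]


def _match_attributes(words: pd.DataFrame, config: LexiconConfig, rng) -> None:
    """Redraw attributes until categories are matched within each domain.

    Emulates psycholinguistic stimulus selection: for every (domain,
    attribute), category values are redrawn from the same distribution until
    every pairwise Welch test yields p above ``config.matching_floor`` —
    the way experimenters discard candidate stimuli until their lists are
    matched on the norms. Modifies ``words`` in place; deterministic given
    the generator state.
    """
    from itertools import combinations

    from scipy import stats as _stats

    main = ~words["is_baseline"]
    for domain in sorted(words.loc[main, "domain"].unique()):
        dom_mask = main & (words["domain"] == domain)
        cats = sorted(words.loc[dom_mask, "category"].unique())
        if len(cats) < 2:
            continue
        for attr in ATTRIBUTES:
            sd = float(config.attribute_sds[attr])
            if sd == 0:
                continue
            for _ in range(500):
                ok = True
                for a, b in combinations(cats, 2):
                    va = words.loc[dom_mask & (words["category"] == a), attr]
                    vb = words.loc[dom_mask & (words["category"] == b), attr]
                    p = _stats.ttest_ind(va, vb, equal_var=False).pvalue
                    if not p > config.matching_floor:
                        ok = False
                        break
                if ok:
                    break
                for cat in cats:
                    sel = dom_mask & (words["category"] == cat)
                    mu = float(config.means_for(cat, domain)[attr])
                    vals = rng.normal(mu, sd, size=int(sel.sum()))
                    if attr == "n_letters":
                        vals = np.maximum(2, np.round(vals)).astype(int)
                    words.loc[sel, attr] = np.round(vals.astype(float), 6)
            else:
                raise RuntimeError(
                    f"could not match attribute {attr!r} in domain {domain}"
                )


def gen_lexicon(config: LexiconConfig | None = None) -> Lexicon:
    """Generate the synthetic lexicon. Fixed seed implies identical output.

    With ``match_attributes`` (default) the categories of each domain are
    matched on every attribute by redrawing until all pairwise Welch p-values
    exceed ``matching_floor``, emulating matched stimulus selection."""
    if config is None:
        config = LexiconConfig()
    rng = np.random.default_rng(config.seed)

    rows = []
    for cat, domain in config.categories:
        n = config.n_words_per_category[cat]
        means = config.means_for(cat, domain)
        for i in range(n):
            row = {
                "word": f"{domain.lower()}_{cat.lower()}_{i:03d}",
                "category": cat,
                "domain": domain,
                "is_baseline": False,
            }
            for attr in ATTRIBUTES:
                mu = float(means[attr])
                sd = float(config.attribute_sds[attr])
                val = rng.normal(mu, sd)
                if attr == "n_letters":
                    val = max(2, int(round(val)))
                row[attr] = np.round(float(val), 6)
            rows.append(row)

    for domain in ("ABS", "CNC"):
        means = _DEF_MEANS[domain]
        for i in range(config.n_baseline_per_domain):
            row = {
                "word": f"{domain.lower()}_base_{i:03d}",
                "category": f"BASE_{domain}",
                "domain": domain,
                "is_baseline": True,
            }
            for attr in ATTRIBUTES:
                val = rng.normal(float(means[attr]), float(config.attribute_sds[attr]))
                if attr == "n_letters":
                    val = max(2, int(round(val)))
                row[attr] = np.round(float(val), 6)
            rows.append(row)

    words = pd.DataFrame(rows)
    if config.match_attributes:
        _match_attributes(words, config, rng)

    ids = words["word"].tolist()
    cats = dict(zip(words["word"], words["category"]))
    n = len(ids)
    rel = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mu = (
                config.relatedness_within
                if cats[ids[i]] == cats[ids[j]]
                else config.relatedness_between
            )
            rel[i, j] = rel[j, i] = float(
                np.clip(rng.normal(mu, config.relatedness_sd), 0.0, 1.0)
            )
    relatedness = pd.DataFrame(rel, index=ids, columns=ids)
    return Lexicon(words=words, relatedness=relatedness, config=config)
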