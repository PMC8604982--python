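"""Factorial prime-target stimulus design for an adaptation paradigm.

Word pairs are built within the abstract (ABS) and concrete (CNC) domains
only — the two domains are never mixed in a pair. Within each category the
words are split once into a prime half and a target half (primes and targets
are never swapped across pairs), and primes are paired with targets of the
same category (Same Category) or of another category of the same domain
(Different Category). A small held-out word set forms the Same Word
adaptation baseline, in which prime and target are the identical word.

Trials are organized into runs of 54 trials each (24 Same Category,
24 Different Category, 6 Same Word; half abstract, half concrete within each
condition), with fixed event timing (1 s fixation, 0.5 s prime, 0.4 s blank,
0.5 s target) and a jittered inter-trial interval drawn from {3, 5, 7} s.
Ordering is pseudo-randomized with at most three consecutive trials of the
same condition.

``verify_matching`` checks the psycholinguistic matching of the categories
within each domain (Welch two-sample tests per attribute; all p-values must
exceed a configured floor) and the homogeneity of pair relatedness within
the Same and Different Category conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONDITIONS",
    "TRIAL_TIMING_S",
    "ITI_CHOICES_S",
    "RUN_COMPOSITION",
    "StimulusPair",
    "build_pairs",
    "build_sameword_baseline",
    "build_runs",
    "matched_design",
    "pairs_to_table",
    "validate_pairs",
    "verify_matching",
]

CONDITIONS = ("SameCategory", "DifferentCategory", "SameWord")

#: Fixed within-trial event durations, seconds.
TRIAL_TIMING_S = {"fixation_s": 1.0, "prime_s": 0.5, "blank_s": 0.4, "target_s": 0.5}

#: Jittered inter-trial interval support, seconds.
ITI_CHOICES_S = (3.0, 5.0, 7.0)

#: Trials per run: (SameCategory, DifferentCategory, SameWord).
RUN_COMPOSITION = (24, 24, 6)

_MAX_CONSECUTIVE = 3


@dataclass(frozen=True)
class StimulusPair:
    """A prime-target word pair. The prime is rendered lower case and the
    target upper case at presentation; only identifiers are stored here."""

    prime_word: str
    target_word: str
    condition: str
    domain: str
    prime_category: str
    target_category: str
    relatedness: float

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.domain not in ("ABS", "CNC"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.condition == "SameWord" and self.prime_word != self.target_word:
            raise ValueError("SameWord pair must repeat the identical word")
        if self.condition == "SameCategory" and self.prime_category != self.target_category:
            raise ValueError("SameCategory pair must stay within one category")
        if self.condition == "DifferentCategory" and self.prime_category == self.target_category:
            raise ValueError("DifferentCategory pair must cross categories")
        if not 0.0 <= float(self.relatedness) <= 1.0:
            raise ValueError("relatedness must lie in [0, 1]")


def _main_words(lexicon) -> pd.DataFrame:
    words = lexicon.words
    return words[~words["is_baseline"]]


def _relatedness(lexicon, a: str, b: str) -> float:
    return float(np.clip(lexicon.relatedness.loc[a, b], 0.0, 1.0))


def build_pairs(lexicon, seed: int) -> list[StimulusPair]:
    """Build the Same- and Different-Category pairs from a lexicon.

    Each category's words are shuffled once (seeded) and split in half into a
    prime pool and a target pool; each half is split again into the words
    reserved for the Same-Category and the Different-Category condition, so
    every per-category count must be divisible by 4. Different-Category
    targets come from another category of the same domain, assigned by a
    seeded cyclic shift of the domain's categories so that every category's
    target pool is used exactly once. No pair mixes the ABS and CNC domains,
    and every main word is used in exactly one pair.
    """
    rng = np.random.default_rng(seed)
    words = _main_words(lexicon)
    pairs: list[StimulusPair] = []

    for domain in ("ABS", "CNC"):
        dom_words = words[words["domain"] == domain]
        categories = sorted(dom_words["category"].unique())
        if len(categories) < 2:
            raise ValueError(f"domain {domain} needs at least two categories")
        pools = {}
        for cat in categories:
            cat_words = sorted(dom_words.loc[dom_words["category"] == cat, "word"])
            n = len(cat_words)
            if n % 4 != 0:
                raise ValueError(
                    f"category {cat!r} has {n} words; counts must be divisible by 4 "
                    "to split into prime/target and same/different halves"
                )
            shuffled = list(rng.permutation(cat_words))
            half, quarter = n // 2, n // 4
            primes, targets = shuffled[:half], shuffled[half:]
            pools[cat] = {
                "sc_primes": primes[:quarter],
                "dc_primes": primes[quarter:],
                "sc_targets": targets[:quarter],
                "dc_targets": targets[quarter:],
            }

        for cat in categories:
            for p, t in zip(pools[cat]["sc_primes"], pools[cat]["sc_targets"]):
                pairs.append(
                    StimulusPair(
                        prime_word=p,
                        target_word=t,
                        condition="SameCategory",
                        domain=domain,
                        prime_category=cat,
                        target_category=cat,
                        relatedness=_relatedness(lexicon, p, t),
                    )
                )

        # Different Category: category i primes take category i+shift targets.
        shift = int(rng.integers(1, len(categories)))
        for i, cat in enumerate(categories):
            other = categories[(i + shift) % len(categories)]
            targets = list(rng.permutation(pools[other]["dc_targets"]))
            if len(targets) != len(pools[cat]["dc_primes"]):
                raise ValueError(
                    f"unbalanced Different-Category pools for {cat!r} vs {other!r}"
                )
            for p, t in zip(pools[cat]["dc_primes"], targets):
                pairs.append(
                    StimulusPair(
                        prime_word=p,
                        target_word=t,
                        condition="DifferentCategory",
                        domain=domain,
                        prime_category=cat,
                        target_category=other,
                        relatedness=_relatedness(lexicon, p, t),
                    )
                )

    validate_pairs(pairs)
    return pairs


def build_sameword_baseline(
    lexicon,
    n_abs: int = 6,
    n_cnc: int = 6,
    exclusion_set: Iterable[str] = (),
) -> list[StimulusPair]:
    """Build the Same Word baseline: identical prime and target, from words
    not used in the main sample (``exclusion_set``)."""
    excl = set(exclusion_set)
    words = lexicon.words
    base = words[words["is_baseline"]]
    if base.empty:  # fall back to any unused main words
        base = words
    overlap = set(base["word"]) & excl
    base = base[~base["word"].isin(excl)]
    pairs = []
    for domain, n in (("ABS", n_abs), ("CNC", n_cnc)):
        pool = sorted(base.loc[base["domain"] == domain, "word"])
        if len(pool) < n:
            raise ValueError(
                f"need {n} unused {domain} baseline words, found {len(pool)}"
                + (f" (excluded {len(overlap)} overlapping)" if overlap else "")
            )
        for w in pool[:n]:
            cat = str(words.loc[words["word"] == w, "category"].iloc[0])
            pairs.append(
                StimulusPair(
                    prime_word=w,
                    target_word=w,
                    condition="SameWord",
                    domain=domain,
                    prime_category=cat,
                    target_category=cat,
                    relatedness=1.0,
                )
            )
    return pairs


def validate_pairs(pairs: Sequence[StimulusPair]) -> None:
    """Full-enumeration check of the pair invariants (dataclass validation
    covers each pair; this additionally checks that no main word is reused)."""
    used = {}
    for p in pairs:
        if p.condition == "SameWord":
            continue
        for w in (p.prime_word, p.target_word):
            if w in used:
                raise ValueError(f"word {w!r} used in more than one main pair")
            used[w] = p


def _order_with_constraint(conditions: list[str], rng, max_run: int = _MAX_CONSECUTIVE):
    """Permutation of trial indices such that no more than ``max_run``
    consecutive trials share a condition (rejection sampling, then greedy)."""
    idx = np.arange(len(conditions))
    conds = np.asarray(conditions)

    def ok(order):
        run = 1
        for a, b in zip(order[:-1], order[1:]):
            run = run + 1 if conds[a] == conds[b] else 1
            if run > max_run:
                return False
        return True

    for _ in range(200):
        order = rng.permutation(idx)
        if ok(order):
            return order
    # Greedy fallback: place the most frequent remaining condition that does
    # not extend the current run beyond the limit.
    remaining = {c: [i for i in idx if conds[i] == c] for c in np.unique(conds)}
    for c in remaining:
        rng.shuffle(remaining[c])
    order, run_cond, run_len = [], None, 0
    for _ in range(len(idx)):
        cands = sorted(remaining, key=lambda c: -len(remaining[c]))
        placed = False
        for c in cands:
            if not remaining[c]:
                continue
            if c == run_cond and run_len >= max_run:
                continue
            order.append(remaining[c].pop())
            run_cond, run_len = c, (run_len + 1 if c == run_cond else 1)
            placed = True
            break
        if not placed:
            raise RuntimeError("could not satisfy the ordering constraint")
    return np.asarray(order)


def build_runs(
    main_pairs: Sequence[StimulusPair],
    sameword_pairs: Sequence[StimulusPair],
    seed: int,
    n_runs: int = 2,
    composition: tuple[int, int, int] = RUN_COMPOSITION,
) -> pd.DataFrame:
    """Assemble pairs into runs and return a trial table.

    Each run holds ``composition`` = (SameCategory, DifferentCategory,
    SameWord) trials with half abstract / half concrete within each condition,
    a pseudo-randomized order (at most three consecutive trials of one
    condition) and inter-trial intervals sampled uniformly from {3, 5, 7} s.
    Every main pair is used exactly once across the runs. Deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_sc, n_dc, n_sw = composition
    by = {}
    for p in list(main_pairs) + list(sameword_pairs):
        by.setdefault((p.condition, p.domain), []).append(p)

    need = {
        ("SameCategory", d): n_runs * n_sc // 2 for d in ("ABS", "CNC")
    } | {
        ("DifferentCategory", d): n_runs * n_dc // 2 for d in ("ABS", "CNC")
    } | {
        ("SameWord", d): n_runs * n_sw // 2 for d in ("ABS", "CNC")
    }
    for key, n in need.items():
        have = len(by.get(key, []))
        if have < n:
            raise ValueError(f"need {n} pairs for {key}, found {have}")

    # Seeded assignment of pairs to runs, balanced per condition x domain.
    run_pairs: dict[int, list[StimulusPair]] = {r: [] for r in range(1, n_runs + 1)}
    for (cond, dom), count in need.items():
        per_run = count // n_runs
        pool = list(rng.permutation(np.array(by[(cond, dom)], dtype=object)))[:count]
        for r in range(1, n_runs + 1):
            run_pairs[r].extend(pool[(r - 1) * per_run : r * per_run])

    rows = []
    for r in range(1, n_runs + 1):
        conds = [p.condition for p in run_pairs[r]]
        order = _order_with_constraint(conds, rng)
        for t, i in enumerate(order, start=1):
            p = run_pairs[r][i]
            rows.append(
                {
                    "run": r,
                    "trial": t,
                    "condition": p.condition,
                    "domain": p.domain,
                    "prime_word": p.prime_word,
                    "target_word": p.target_word,
                    "prime_category": p.prime_category,
                    "target_category": p.target_category,
                    "relatedness": p.relatedness,
                    **TRIAL_TIMING_S,
                    "iti_s": float(rng.choice(ITI_CHOICES_S)),
                }
            )
    return pd.DataFrame(rows)


def pairs_to_table(pairs: Sequence[StimulusPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])


def matched_design(
    lexicon,
    seed: int,
    n_abs: int = 6,
    n_cnc: int = 6,
    max_attempts: int = 100,
    alpha_abs: float = 0.055,
    alpha_cnc: float = 0.056,
) -> tuple[list[StimulusPair], list[StimulusPair], pd.DataFrame]:
    """Build pairs + baseline whose matching report PASSes.

    Candidate pairings are generated from deterministic sub-seeds of ``seed``
    until :func:`verify_matching` passes (attribute matching is a property of
    the lexicon; what varies between attempts is the relatedness homogeneity
    of the realized pairings) — emulating how pseudo-randomized stimulus
    lists are constructed under matching constraints. Returns
    ``(pairs, sameword_pairs, report)``; raises after ``max_attempts``.
    """
    from ._seed import stage_seed

    last_report = None
    for attempt in range(max_attempts):
        sub = stage_seed(seed, f"pairing{attempt}")
        pairs = build_pairs(lexicon, seed=sub)
        used = {p.prime_word for p in pairs} | {p.target_word for p in pairs}
        sw = build_sameword_baseline(lexicon, n_abs=n_abs, n_cnc=n_cnc, exclusion_set=used)
        report = verify_matching(lexicon, pairs + sw, alpha_abs=alpha_abs, alpha_cnc=alpha_cnc)
        last_report = report
        if report.attrs["pass"]:
            return pairs, sw, report
    failing = last_report[~last_report["passed"]]
    raise RuntimeError(
        f"no matched pairing found in {max_attempts} attempts; "
        f"failing measures: {failing['measure'].unique().tolist()}"
    )


# ---------------------------------------------------------------------------
# Matching verification
# ---------------------------------------------------------------------------

def verify_matching(
    lexicon,
    pairs: Sequence[StimulusPair],
    alpha_abs: float = 0.055,
    alpha_cnc: float = 0.056,
    attributes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Check psycholinguistic matching of categories within each domain.

    For every attribute and every pair of categories within a domain a Welch
    two-sample test is run; the check PASSes when every p-value exceeds the
    domain's floor (``alpha_abs`` for ABS, ``alpha_cnc`` for CNC). Pair
    relatedness homogeneity across categories is checked the same way within
    the Same-Category and the Different-Category condition. Returns the full
    report (one row per attribute x category pair) with a ``passed`` column;
    the report's ``attrs['pass']`` flag summarizes it.
    """
    words = _main_words(lexicon)
    if attributes is None:
        attributes = [
            c
            for c in words.columns
            if c not in ("word", "category", "domain", "is_baseline")
        ]
    missing = [a for a in attributes if a not in words.columns]
    if missing:
        raise ValueError(f"lexicon is missing attribute columns: {missing}")

    floors = {"ABS": alpha_abs, "CNC": alpha_cnc}
    rows = []
    for domain in ("ABS", "CNC"):
        dom = words[words["domain"] == domain]
        for attr in attributes:
            for a, b in combinations(sorted(dom["category"].unique()), 2):
                va = dom.loc[dom["category"] == a, attr].to_numpy(dtype=float)
                vb = dom.loc[dom["category"] == b, attr].to_numpy(dtype=float)
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
                rows.append(
                    {
                        "domain": domain,
                        "measure": attr,
                        "category_a": a,
                        "category_b": b,
                        "p_value": p,
                        "floor": floors[domain],
                        "passed": p > floors[domain],
                    }
                )

    for cond in ("SameCategory", "DifferentCategory"):
        rel = {}
        for p_ in pairs:
            if p_.condition == cond:
                rel.setdefault((p_.domain, p_.prime_category), []).append(p_.relatedness)
        for domain in ("ABS", "CNC"):
            cats = sorted(c for d, c in rel if d == domain)
            for a, b in combinations(cats, 2):
                va, vb = rel[(domain, a)], rel[(domain, b)]
                if len(va) < 2 or len(vb) < 2:
                    continue
                p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
                rows.append(
                    {
                        "domain": domain,
                        "measure": f"relatedness[{cond}]",
                        "category_a": a,
                        "category_b": b,
                        "p_value": p,
                        "floor": floors[domain],
                        "passed": p > floors[domain],
                    }
                )

    report = pd.DataFrame(
        rows,
        columns=["domain", "measure", "category_a", "category_b", "p_value", "floor", "passed"],
    )
    report.attrs["pass"] = bool(report["passed"].all()) if len(report) else True
    return report
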