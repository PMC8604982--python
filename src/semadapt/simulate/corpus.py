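"""Synthetic literature corpus of activation contrasts.

Emulates a coordinate-based literature screening: each contrast reports one
to three activation foci scattered around a planted region center, carries a
multiple-comparison correction label and a semantics/control contrast class,
and a configurable fraction of contrasts is reported in Talairach rather than
MNI space. Label counts follow the configured mixes *exactly* (largest
remainder allocation), so the default configuration reproduces the reference
accounting of 195 contrasts: 122 corrected (61 voxel- and 61 cluster-level
under the default sub-mix), 56 uncorrected and 17 with unknown correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..literature import ContrastRecord, mni2tal

__all__ = ["CorpusConfig", "DEFAULT_REGION_CENTERS", "gen_literature_corpus"]

#: Default planted region centers (mm, MNI): anterior/posterior temporal,
#: fusiform, inferior frontal, parietal and medial frontal sites typical of
#: semantic and control networks.
DEFAULT_REGION_CENTERS = (
    (-53.0, 2.0, -30.0),
    (-33.0, -16.0, -32.0),
    (-57.0, -40.0, 0.0),
    (-48.0, 30.0, 2.0),
    (-40.0, -62.0, 36.0),
    (-6.0, 22.0, 40.0),
    (46.0, 28.0, 26.0),
    (-30.0, -88.0, 2.0),
)

_DEF_CORRECTION_MIX = {
    "voxel": 61 / 195,
    "cluster": 61 / 195,
    "uncorrected": 56 / 195,
    "unknown": 17 / 195,
}
_DEF_CLASS_MIX = {"concrete_semantic": 0.4, "abstract_semantic": 0.3, "control": 0.3}


def _check_mix(name: str, mix: Mapping[str, float], keys: tuple) -> None:
    if set(mix) != set(keys):
        raise ValueError(f"{name} must have keys {keys}, got {sorted(mix)}")
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} proportions sum to {total}, expected 1")
    if any(v < 0 for v in mix.values()):
        raise ValueError(f"{name} proportions must be non-negative")


@dataclass(frozen=True)
class CorpusConfig:
    """Configuration of the synthetic literature corpus."""

    n_contrasts: int = 195
    correction_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEF_CORRECTION_MIX)
    )
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_CLASS_MIX))
    region_centers: Sequence[tuple] = DEFAULT_REGION_CENTERS
    focus_noise_sd: float = 4.0
    talairach_fraction: float = 0.2
    max_foci_per_contrast: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_contrasts <= 0:
            raise ValueError("n_contrasts must be positive")
        if self.focus_noise_sd < 0:
            raise ValueError("focus_noise_sd must be non-negative")
        if not 0.0 <= self.talairach_fraction <= 1.0:
            raise ValueError("talairach_fraction must lie in [0, 1]")
        if len(self.region_centers) == 0:
            raise ValueError("at least one region center is required")
        _check_mix(
            "correction_mix",
            self.correction_mix,
            ("voxel", "cluster", "uncorrected", "unknown"),
        )
        _check_mix(
            "class_mix",
            self.class_mix,
            ("concrete_semantic", "abstract_semantic", "control"),
        )


def _allocate(mix: Mapping[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of ``n`` labels to the mix proportions."""
    keys = sorted(mix)
    exact = {k: mix[k] * n for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))[:short]:
        counts[k] += 1
    labels = []
    for k in keys:
        labels.extend([k] * counts[k])
    return labels


def gen_literature_corpus(config: CorpusConfig | None = None) -> list[ContrastRecord]:
    """Generate a corpus of :class:`~semadapt.literature.ContrastRecord`.

    Exactly ``n_contrasts`` records are produced. Correction and class labels
    are allocated deterministically per the mixes, then assigned to records in
    a seeded shuffle. Each record draws 1..max_foci foci as Gaussian scatter
    (sd ``focus_noise_sd``) around one planted region center. A seeded subset
    of exactly ``round(talairach_fraction * n)`` records is converted to and
    flagged as Talairach space. Fixed seed implies bit-identical output.
    """
    if config is None:
        config = CorpusConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_contrasts

    corrections = np.array(_allocate(config.correction_mix, n), dtype=object)
    classes = np.array(_allocate(config.class_mix, n), dtype=object)
    rng.shuffle(corrections)
    rng.shuffle(classes)

    centers = np.asarray(config.region_centers, dtype=float)
    center_idx = rng.integers(0, len(centers), size=n)
    n_foci = rng.integers(1, config.max_foci_per_contrast + 1, size=n)

    n_tal = int(round(config.talairach_fraction * n))
    tal_flags = np.zeros(n, dtype=bool)
    tal_flags[rng.choice(n, size=n_tal, replace=False)] = True

    records = []
    for i in range(n):
        foci = centers[center_idx[i]] + rng.normal(
            0.0, config.focus_noise_sd, size=(n_foci[i], 3)
        )
        space = "MNI"
        if tal_flags[i]:
            foci = mni2tal(foci)
            space = "Talairach"
        records.append(
            ContrastRecord(
                study_id=f"study{i:04d}",
                contrast_id=f"contrast{i:04d}",
                foci=tuple(tuple(np.round(f, 4)) for f in np.atleast_2d(foci)),
                space=space,
                correction=str(corrections[i]),
                contrast_class=str(classes[i]),
            )
        )
    return records
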