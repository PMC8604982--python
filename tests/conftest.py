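import pytest

from semadapt.design import build_runs, matched_design
from semadapt.simulate import LexiconConfig, gen_atlas, gen_lexicon


@pytest.fixture(scope="session")
def lexicon():
    """Full-size matched lexicon (4x24 abstract, 2x48 concrete, 6+6 baseline)."""
    return gen_lexicon(LexiconConfig(seed=42))


@pytest.fixture(scope="session")
def small_lexicon():
    """Scaled-down lexicon for fast combinatorial tests (counts divisible by 4)."""
    cfg = LexiconConfig(
        n_words_per_category={"EM": 4, "COG": 4, "ATT": 4, "ACT": 4, "BIOL": 8, "ART": 8},
        match_attributes=False,
        seed=7,
    )
    return gen_lexicon(cfg)


@pytest.fixture(scope="session")
def atlas_img():
    """Small synthetic atlas: 3x3x3 parcels of 20 mm, 2 mm voxels."""
    return gen_atlas(grid_shape=(3, 3, 3), parcel_size_mm=20.0, voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def trials(lexicon):
    """Default two-run trial design from the full lexicon."""
    pairs, sw, _ = matched_design(lexicon, seed=42)
    return build_runs(pairs, sw, seed=42)
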