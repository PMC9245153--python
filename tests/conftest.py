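import numpy as np
import pytest

from lexsys import SyntheticConfig, boxcox_z, build_study_table, generate_aoa, generate_lexicon

CONTROLS = [
    "frequency",
    "concreteness",
    "length_phonemes",
    "valence",
    "morph_complex",
    "pnd",
    "snd",
]

NUMERIC_CONTROLS = [c for c in CONTROLS if c != "morph_complex"]


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        vocab_size=300,
        phoneme_inventory=tuple("ptkbdmnszaeiou"),
        length_range=(2, 6),
        vector_dim=24,
        systematicity=0.6,
        seed=7,
        aoa_coefficients={
            "intercept": 8.0,
            "frequency": -0.4,
            "concreteness": -0.3,
            "fsc_ld": -0.5,
        },
        aoa_noise_sd=0.8,
    )


@pytest.fixture(scope="session")
def small_lexicon(small_config):
    return generate_lexicon(small_config)


@pytest.fixture(scope="session")
def analysis_table(small_config, small_lexicon):
    """Transformed study table with a generated AoA column carrying a true
    fsc_ld effect."""
    study, _ = build_study_table(small_lexicon, seed=small_config.seed)
    transformed, _ = boxcox_z(study, NUMERIC_CONTROLS + ["fsc_te", "fsc_ld"])
    withaoa = generate_aoa(small_lexicon, transformed, small_config)
    transformed = transformed.copy()
    transformed["aoa"] = withaoa.aoa.to_numpy()
    return transformed


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
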