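import pytest

from nucoloc import generate_scene, genotype_preset


@pytest.fixture(scope="session")
def wt_scene():
    """Small noisy wild-type scene with ground truth (session-cached)."""
    cfg = genotype_preset("Wt")
    cfg.n_nuclei = 3
    cfg.seed = 42
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free wild-type scene for exact construction checks."""
    cfg = genotype_preset("Wt")
    cfg.n_nuclei = 3
    cfg.seed = 7
    cfg.noise_sd = 0.0
    return generate_scene(cfg)
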