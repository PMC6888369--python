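import pytest

from rnacomposite.simulate import SimConfig, generate


@pytest.fixture(scope="session")
def small_noise_free_bundle():
    """Compact noise-free bundle shared by unit tests (fast to assemble)."""
    return generate(
        SimConfig.noise_free(
            seed=11, transcript_len=600, n_helices=8, n_long_range=1, n_pk=1, n_homologs=20
        )
    )


@pytest.fixture(scope="session")
def default_bundle():
    """Default-noise bundle at the spec'd defaults (1000 nt, seed 7)."""
    return generate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_assembly(small_noise_free_bundle):
    from rnacomposite.composite import assemble

    b = small_noise_free_bundle
    return assemble(b.track, b.duplexes, b.seq)
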