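import pytest

from teescape.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort shared by read-only tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast structural / round-trip tests."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=400,
        n_tes=200,
        immune_set_size=30,
        n_contacts_background=60,
        n_decoy_sets=5,
        genome=(("chr1", 15_000_000), ("chr2", 15_000_000)),
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    """The small cohort written out as a fixture bundle."""
    from teescape.simulate import write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_bundle(small_cohort, out, force=True)
    return out, manifest
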