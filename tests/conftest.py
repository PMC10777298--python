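import pytest

from tripkit.simulate import (
    GenomeConfig,
    LibraryDepths,
    make_genome,
    plant_insertions,
    simulate_libraries,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Two-chromosome toy genome shared by most tests."""
    cfg = GenomeConfig(chromosomes={"chrA": 80_000, "chrB": 60_000}, gc=0.41)
    return make_genome(cfg, seed=7)


@pytest.fixture(scope="session")
def truth60(toy_genome):
    """60 planted insertions with moderate clone-abundance spread."""
    return plant_insertions(
        toy_genome, 60, silent_fraction=0.5, seed=7, abundance_sigma=0.5
    )


@pytest.fixture(scope="session")
def clean_sim(toy_genome, truth60, tmp_path_factory):
    """Noise-free libraries: every read is an exact copy of its template."""
    outdir = tmp_path_factory.mktemp("clean_sim")
    return simulate_libraries(
        truth60,
        toy_genome,
        outdir,
        depths=LibraryDepths(80, 80, 20),
        error_rate=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noisy_sim(toy_genome, truth60, tmp_path_factory):
    """Same truth with realistic substitution errors."""
    outdir = tmp_path_factory.mktemp("noisy_sim")
    return simulate_libraries(
        truth60,
        toy_genome,
        outdir,
        depths=LibraryDepths(80, 80, 20),
        error_rate=0.005,
        seed=7,
    )
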