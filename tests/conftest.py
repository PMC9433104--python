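import pytest

from timing.kinetics import analyze_chip
from timing.migration import migration_table
from timing.synthetic import AssayConfig, simulate_chip


@pytest.fixture(scope="session")
def chip500():
    """One 500-well chip with the default phenotype mixture, shared by the
    simulation-scale checks (kinetics invariants, label recovery, migration)."""
    cfg = AssayConfig(wells=500, rng_seed=42)
    return simulate_chip(cfg)


@pytest.fixture(scope="session")
def analysis500(chip500):
    chip, _ = chip500
    return analyze_chip(chip.tracks, chip.bead_endpoint)


@pytest.fixture(scope="session")
def migration500(chip500, analysis500):
    chip, _ = chip500
    return migration_table(
        chip.tracks, analysis500.conjugations, analysis500.selected_wells
    )


@pytest.fixture(scope="session")
def small_chip():
    """A 30-well, 2-hour chip with enough effectorless (control) wells for
    the secretion threshold; used by imaging round-trip tests."""
    cfg = AssayConfig(
        wells=30, rng_seed=9, duration_h=2.0, e_per_well={0: 0.4, 1: 0.6}
    )
    return simulate_chip(cfg)
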