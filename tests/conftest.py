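import pytest

from obgenome.simulate import GenomeSimConfig, simulate_genome, simulate_pileup
from obgenome.variants import call_polymorphisms


@pytest.fixture(scope="session")
def default_fixture():
    """The package's default synthetic study fixture (seed 42)."""
    cfg = GenomeSimConfig(seed=42)
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def default_pileup(default_fixture):
    """Pileup and calls for the default fixture at 941x (seed = cfg.seed + 1)."""
    cfg, genome, truth = default_fixture
    columns = simulate_pileup(genome, truth, depth=cfg.depth, seed=cfg.seed + 1)
    calls = call_polymorphisms(columns)
    return columns, calls


@pytest.fixture(scope="session")
def small_fixture():
    """A scaled-down genome for faster end-to-end checks."""
    cfg = GenomeSimConfig(
        length=30_000, n_orfs=20, orf_codon_range=(50, 150),
        hr_plan=[(2, 0.08), (3, 0.08)], n_bulk_snps=40, seed=9,
    )
    genome, truth = simulate_genome(cfg)
    return cfg, genome, truth
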