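import pytest

from chromprint.sim import SimConfig, fragment_assembly, simulate_pedigree


@pytest.fixture(scope="session")
def clean_truth():
    """Error-free pedigree at the default study conditions (21 chromosomes,
    69 offspring, paternal-only recombination)."""
    cfg = SimConfig(genotype_error_rate=0.0, missing_rate=0.0, seed=11)
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def clean_assembly(clean_truth):
    return fragment_assembly(clean_truth)


@pytest.fixture(scope="session")
def clean_chain(clean_truth, clean_assembly):
    from chromprint.pipeline import run_chain

    return run_chain(clean_truth, clean_assembly)


@pytest.fixture(scope="session")
def unmerged_chain(clean_truth, clean_assembly):
    """Chain without haplotype merging: pools still contain the planted
    haplotigs, exercising the purge rules."""
    from chromprint.pipeline import run_chain

    return run_chain(clean_truth, clean_assembly, do_merge=False)


@pytest.fixture(scope="session")
def small_truth():
    """Small error-free pedigree for fast unit tests."""
    cfg = SimConfig(
        n_chromosomes=4,
        chromosome_length_bp=200_000,
        n_offspring=30,
        genotype_error_rate=0.0,
        missing_rate=0.0,
        n_misassemblies=2,
        seed=7,
    )
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def small_assembly(small_truth):
    return fragment_assembly(small_truth)


@pytest.fixture(scope="session")
def small_sites(small_truth, small_assembly):
    return small_truth.site_records(small_assembly)


@pytest.fixture(scope="session")
def small_filtered(small_truth, small_sites):
    from chromprint.markers import Pedigree, filter_snps

    return filter_snps(
        small_sites, small_truth.samples,
        Pedigree.from_samples(small_truth.samples),
    )
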