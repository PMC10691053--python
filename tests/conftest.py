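import numpy as np
import pytest

from cladespace.synthetic import (SyntheticSpec, make_genome,
                                  simulate_expression, simulate_fragments)


def tiny_spec(**overrides) -> SyntheticSpec:
    """Desk-scale-down of the default study conditions for fast unit tests."""
    base = dict(
        n_chromosomes=2, chrom_length_bp=250_000, n_cell_types=3,
        n_cells_per_type=30, n_shared_sites=30, n_private_sites_per_type=10,
        site_width_bp=300, depth_mean=200.0, noise_rate=0.05,
        marker_genes_per_type=3, n_samples=2, n_genes=40, gene_min_bp=2_000,
        gene_max_bp=6_000, negative_markers_per_type=1, n_housekeeping=5,
        n_cell_cycle=4, seed=7,
    )
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture(scope="session")
def tiny_world():
    """Genome + fragments + truth + expression from one tiny simulation."""
    spec = tiny_spec()
    genome = make_genome(spec)
    fragments, truth = simulate_fragments(genome, spec)
    expr = simulate_expression(truth, spec)
    return spec, genome, fragments, truth, expr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230)
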