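import numpy as np
import pandas as pd
import pytest

from nucdis import (
    CoverageTrack,
    DisassemblyObservables,
    GeneratorConfig,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort, small enough for fast tests."""
    return generate_cohort(GeneratorConfig(n_genes=400, seed=7))


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Observables equal their latent values exactly (no tracks needed)."""
    return generate_cohort(
        GeneratorConfig(n_genes=2000, seed=1, sigma_obs=0.0, sigma_P=0.0),
        tracks=False,
    )


@pytest.fixture()
def flat_tracks():
    """IP flat 4.0 and control flat 1.0 over one 1 kb chromosome."""
    ip = CoverageTrack(step_bp=10, data={"chr1": np.full(100, 4.0)})
    control = CoverageTrack(step_bp=10, data={"chr1": np.full(100, 1.0)})
    return ip, control


@pytest.fixture()
def simple_genes():
    return pd.DataFrame(
        {
            "gene_id": ["geneA", "geneB"],
            "chrom": ["chr1", "chr1"],
            "start": [100, 500],
            "end": [300, 900],
            "strand": ["+", "-"],
        }
    )


def observables_from(cohort) -> DisassemblyObservables:
    return DisassemblyObservables.from_table(cohort.gene_table)
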