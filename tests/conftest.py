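import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phagedyn.matrices import AbundanceMatrix, CountMatrix, Unit, sample_index
from phagedyn.synthetic_data import SimulationConfig, simulate_scenario

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


def make_annotation(rows):
    """rows: list of (gene_id, entity, length_nt, biotype)."""
    df = pd.DataFrame(
        [{"gene_id": g, "entity": e, "length_nt": n, "biotype": b, "name": g} for g, e, n, b in rows]
    ).set_index("gene_id")
    return df


def make_counts(values, genes, samples, lengths=None):
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_index(samples))
    lengths = pd.Series(lengths, index=data.index) if lengths is not None else None
    return CountMatrix(data, lengths=lengths)


def make_abundance(values, genes, columns, unit=Unit.TPM):
    """columns: list of times (averaged) or (time, rep) tuples (per sample)."""
    if columns and isinstance(columns[0], tuple):
        cols = sample_index(columns)
    else:
        cols = pd.Index([float(t) for t in columns], name="time_min")
    data = pd.DataFrame(np.asarray(values, dtype=float), index=pd.Index(genes, name="gene_id"), columns=cols)
    return AbundanceMatrix(data, unit)


@pytest.fixture
def simple_annotation():
    return make_annotation(
        [
            ("hostA", "host", 500, "mRNA"),
            ("hostB", "host", 1000, "mRNA"),
            ("hostR", "host", 1500, "rRNA"),
            ("hostN", "host", 300, "ncRNA"),
            ("phg1", "phage", 800, "mRNA"),
            ("phg2", "phage", 1200, "mRNA"),
        ]
    )


@pytest.fixture(scope="session")
def small_config():
    """A reduced scenario used where full size is unnecessary."""
    return SimulationConfig(
        seed=7,
        n_host_genes=120,
        n_phage_genes=60,
        n_host_trna=10,
        n_host_rrna=5,
        n_host_ncrna=8,
        n_stable_host=3,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    return simulate_scenario(small_config)


@pytest.fixture(scope="session")
def small_noisefree_scenario(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, count_noise="none", lfq_noise=False)
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def default_scenario():
    """The reference study conditions at the fixed acceptance seed."""
    return simulate_scenario(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_noisefree_scenario():
    return simulate_scenario(SimulationConfig(seed=1, count_noise="none", lfq_noise=False))
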