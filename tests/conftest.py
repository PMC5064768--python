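import numpy as np
import pandas as pd
import pytest

from germreprog.core_io import CpGCallSet, FeatureSet, GeneModel, GenomeIndex
from germreprog.synthetic import (
    SimulationConfig,
    simulate_genome_and_annotation,
    simulate_methylomes,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, chrom_sizes={"chr1": 500_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def annotation(small_config):
    return simulate_genome_and_annotation(small_config)


@pytest.fixture(scope="session")
def methylomes(small_config, annotation):
    return simulate_methylomes(small_config, annotation)


@pytest.fixture
def genome():
    return GenomeIndex({"chr1": 100_000, "chr2": 50_000})


def make_calls(sample_id, rows):
    """rows: (chrom, pos, meth, unmeth)."""
    return CpGCallSet(
        sample_id=sample_id,
        records=pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"]),
    )


def make_features(rows, **extra):
    """rows: (chrom, start, end[, strand, name, feature_class])."""
    cols = ["chrom", "start", "end", "strand", "name", "feature_class"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    return FeatureSet(df, **extra)
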