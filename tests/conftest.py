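import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tailmap.annotate import LocusIndex, annotate_collapsed
from tailmap.genome import generate_genome
from tailmap.mapper import GenomeIndex
from tailmap.preprocess import demultiplex, preprocess_library
from tailmap.simulate import (
    DEFAULT_ADAPTER,
    TreatmentSpec,
    genotype_preset,
    simulate_library,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

TOY_PLAN = {"21U": 30, "miRNA": 5, "mRNA": 10, "rRNA": 1, "tRNA": 2}


@pytest.fixture(scope="session")
def toy_bundle():
    return generate_genome(1, [50_000], TOY_PLAN, seed=7)


@pytest.fixture(scope="session")
def genome_index(toy_bundle):
    return GenomeIndex(toy_bundle.chromosomes)


@pytest.fixture(scope="session")
def locus_index(toy_bundle):
    return LocusIndex(toy_bundle.loci)


def process_library(sim, bundle, genome_index=None, locus_index=None,
                    barcode="ACTA", multimap="fractional"):
    """Demux + trim + collapse + map + annotate one simulated library."""
    gi = genome_index or GenomeIndex(bundle.chromosomes)
    li = locus_index or LocusIndex(bundle.loci)
    assigned, _ = demultiplex([s for _, s in sim.reads], [barcode])
    collapsed, pstats = preprocess_library(assigned[barcode], DEFAULT_ADAPTER)
    df, mstats = annotate_collapsed(collapsed, gi, li, multimap=multimap)
    return df, pstats, mstats


@pytest.fixture(scope="session")
def null_library(toy_bundle):
    return simulate_library(
        toy_bundle, genotype_preset("null"), TreatmentSpec(), 20_000, seed=1
    )


@pytest.fixture(scope="session")
def null_annotated(toy_bundle, null_library, genome_index, locus_index):
    df, _, _ = process_library(null_library, toy_bundle, genome_index, locus_index)
    return df
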