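import numpy as np
import pytest

from poolseg.cross import MarkerMap, SegregantSet, build_parents
from poolseg.genome import GenomeModel

import pandas as pd


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Two small chromosomes, 1:3 length ratio."""
    return GenomeModel(chrom_lengths={"chrA": 100_000, "chrB": 300_000})


@pytest.fixture(scope="session")
def study_markers() -> MarkerMap:
    """Full-size default marker map (900 induced + 30,000 background)."""
    return build_parents(GenomeModel(), seed=11)


def make_pool(genotype_column: np.ndarray, chrom: str = "chrA") -> SegregantSet:
    """A pool of segregants scored at a single marker."""
    genome = GenomeModel(chrom_lengths={chrom: 100_000})
    markers = MarkerMap(
        df=pd.DataFrame(
            {"chrom": [chrom], "pos": [50_000], "klass": ["induced"],
             "ref": ["A"], "alt": ["T"]}
        ),
        genome=genome,
    )
    n = len(genotype_column)
    return SegregantSet(
        ids=np.array([f"s{i}" for i in range(n)]),
        genotypes=np.asarray(genotype_column, dtype=np.int8).reshape(n, 1),
        mito=np.ones(n, dtype=bool),
        markers=markers,
    )
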