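import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from chickpop.data_io import (
    GenotypeLikelihoodMatrix,
    LocusRecord,
    SampleTable,
)


def make_sample_table(n_per_site: int = 4) -> SampleTable:
    """Six sites on three transects, n individuals each."""
    rows = []
    layout = [
        ("SH_H", "SH", "high", 39.41881, -120.30687, 2428.0),
        ("SH_L", "SH", "low", 39.44510, -120.21723, 1952.0),
        ("MR_H", "MR", "high", 39.31992, -119.89655, 2590.8),
        ("MR_L", "MR", "low", 39.35778, -119.85749, 1891.59),
        ("RL_H", "RL", "high", 38.69641, -120.00704, 2535.33),
        ("RL_L", "RL", "low", 38.54683, -120.30694, 1973.58),
    ]
    for site, tr, cls, lat, lon, elev in layout:
        for k in range(n_per_site):
            rows.append(
                dict(
                    individual_id=f"{site}_{k}", site_id=site, transect_id=tr,
                    elevation_class=cls, latitude=lat, longitude=lon,
                    elevation_m=elev,
                )
            )
    return SampleTable(pd.DataFrame(rows))


def make_gl(
    likelihoods: np.ndarray, depths: np.ndarray, individuals=None, contigs=None
) -> GenotypeLikelihoodMatrix:
    """Wrap raw arrays in a GenotypeLikelihoodMatrix with generated ids."""
    n, l_, _ = likelihoods.shape
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n)]
    if contigs is None:
        contigs = [f"c{j}" for j in range(l_)]
    loci = [LocusRecord(f"{contigs[j]}:10", contigs[j], 10, "A", "G") for j in range(l_)]
    return GenotypeLikelihoodMatrix(individuals, loci, likelihoods, depths)


class TrueGenotypeView:
    """GenotypeMatrix-like adapter exposing true genotypes as composites.

    Lets differentiation/AMOVA/parallel tests run on noiseless genotype
    calls without the MCMC stage.
    """

    def __init__(self, genotypes: np.ndarray, individuals, locus_ids=None):
        self.composite = np.asarray(genotypes, dtype=float)
        self.individuals = list(individuals)
        self._locus_ids = (
            list(locus_ids)
            if locus_ids is not None
            else [f"L{j}" for j in range(self.composite.shape[1])]
        )

    @property
    def locus_ids(self):
        return self._locus_ids

    @property
    def loci(self):
        return self._locus_ids


@pytest.fixture(scope="session")
def samples6():
    return make_sample_table(n_per_site=4)
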