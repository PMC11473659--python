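import numpy as np
import pandas as pd
import pytest

from glacialsfs.core import Demography, FoldedSFS, GenotypeMatrix
from glacialsfs.simdata import simulate_genotype_matrix


@pytest.fixture(scope="session")
def const_dem():
    return Demography(((10_000.0, 0.0),))


@pytest.fixture(scope="session")
def small_gm(const_dem):
    """A clean genotype matrix without missing data (8 diploids)."""
    return simulate_genotype_matrix(
        const_dem, n_ind=8, L=5e4, mu=5e-8, missing_rate=0.0, seed=101
    )


@pytest.fixture(scope="session")
def missing_gm(const_dem):
    """Genotype matrix with 20% missing calls."""
    return simulate_genotype_matrix(
        const_dem, n_ind=10, L=5e4, mu=5e-8, missing_rate=0.2, seed=102
    )


@pytest.fixture(scope="session")
def calib_gm():
    """Population-scale matrix (25 diploids, probe-sized loci) for
    paralog-filter calibration."""
    return simulate_genotype_matrix(
        Demography(((20_000.0, 0.0),)), n_ind=25, L=1e5, mu=1e-7, seed=31, reps=250
    )


def make_gm(genotypes, positions=None, dp=30, gq=99, site_class=None, contig=None,
            pop=None, L_total=None, info=None):
    """Hand-rolled genotype matrix for toy tests."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    if info is None:
        info = pd.DataFrame(
            {
                "QD": np.full(n_sites, 20.0),
                "QUAL": np.full(n_sites, 100.0),
                "SOR": np.full(n_sites, 1.0),
                "MQ": np.full(n_sites, 50.0),
                "MQRankSum": np.zeros(n_sites),
                "ReadPosRankSum": np.zeros(n_sites),
            }
        )
    return GenotypeMatrix(
        genotypes=genotypes,
        dp=np.full((n_ind, n_sites), dp),
        gq=np.full((n_ind, n_sites), gq),
        positions=np.asarray(positions),
        info=info,
        site_class=np.asarray(site_class if site_class is not None else ["other"] * n_sites, dtype=object),
        pop=np.asarray(pop if pop is not None else ["pop1"] * n_ind, dtype=object),
        L_total=float(L_total if L_total is not None else n_sites),
        contig=contig,
    )
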