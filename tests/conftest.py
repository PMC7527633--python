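import numpy as np
import pandas as pd
import pytest

from sweepscan.genotypes import GenotypeMatrix
from sweepscan.synthetic_data import SimulationConfig, simulate_cohort


def make_matrix(dosages, positions=None, chrom="chr1", populations=None,
                ref=None, alt=None, qual=None):
    """Hand-build a GenotypeMatrix from a samples-x-sites dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if populations is None:
        half = n_samples // 2 or 1
        populations = ["pop1"] * half + ["pop2"] * (n_samples - half)
    sites = pd.DataFrame({
        "chrom": [chrom] * n_sites,
        "pos": np.asarray(positions, dtype=np.int64),
        "ref": ref if ref is not None else ["A"] * n_sites,
        "alt": alt if alt is not None else ["G"] * n_sites,
        "qual": qual if qual is not None else [100.0] * n_sites,
    })
    ids = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(dosages, sites, ids, np.array(populations,
                                                        dtype=object))


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort: one 5-Mb chromosome, one 300-kb sweep."""
    return SimulationConfig(
        chrom_lengths={"chr1": 5_000_000},
        n_sites=5_000,
        sweep_intervals=[("chr1", 2_000_000, 2_300_000)],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    """The small cohort written to disk (VCF/GFF3/FASTA/BED)."""
    from sweepscan.synthetic_data import write_cohort

    genotypes, truth = small_cohort
    outdir = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(genotypes, truth, outdir)
    return paths
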