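"""Simulate a two-population cohort with planted sweeps and write it out.

The generator draws ancestral allele frequencies from the neutral 1/i
spectrum and diverges the two populations under the Balding–Nichols
model; inside sweep intervals the domestic population is pushed toward
fixation so heterozygosity drops ten-fold.
"""

import tempfile
from pathlib import Path

from sweepscan import SimulationConfig, simulate_cohort, write_cohort
from sweepscan.variants_io import tstv_ratio

config = SimulationConfig(
    chrom_lengths={"chr1": 5_000_000},
    n_sites=5_000,
    sweep_intervals=[("chr1", 2_000_000, 2_300_000)],
    seed=1,
)
genotypes, truth = simulate_cohort(config)

print(f"samples: {genotypes.n_samples} "
      f"({(genotypes.populations == 'domestic').sum()} domestic + "
      f"{(genotypes.populations == 'wild').sum()} wild)")
print(f"biallelic SNVs: {genotypes.n_sites}")
print(f"Ts/Tv of REF/ALT pairs: {tstv_ratio(genotypes):.2f} "
      f"(target {config.tstv_target})")
print(f"missing genotypes: {(genotypes.dosages == -1).mean():.1%} "
      f"(target {config.missing_rate:.1%})")

outdir = Path(tempfile.mkdtemp()) / "cohort"
paths = write_cohort(genotypes, truth, outdir)
print("\nwritten files (VCF + truth BED + gene models + reference):")
for name, path in paths.items():
    print(f"  {name:12s} {path}")
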