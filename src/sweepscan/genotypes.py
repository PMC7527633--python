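"""Genotype matrix container shared by every analysis stage.

Genotypes are stored as ALT-allele dosages (0, 1, 2) in a dense
``samples x sites`` int8 array, with :data:`MISSING` (-1) marking
uncalled genotypes.  Site metadata (chromosome, 1-based position,
REF/ALT nucleotides, QUAL) lives in a parallel :class:`pandas.DataFrame`
sorted by (chrom, pos).  Each sample carries a population label; all
two-population statistics address populations through these labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "qual")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for a two-population cohort.

    Parameters
    ----------
    dosages
        ``(n_samples, n_sites)`` int8 array of ALT-allele counts;
        ``-1`` encodes a missing genotype.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, qual`` (``pos``
        1-based as in VCF), sorted by (chrom, pos).
    sample_ids
        Sample identifiers, one per dosage row.
    populations
        Population label per sample (two labels for two-population
        statistics, e.g. ``"domestic"`` / ``"wild"``).
    """

    dosages: np.ndarray
    sites: pd.DataFrame
    sample_ids: list[str]
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x sites)")
        n_samples, n_sites = self.dosages.shape
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.populations) != n_samples:
            raise ValueError("populations length does not match dosage rows")
        if len(self.sites) != n_sites:
            raise ValueError("sites length does not match dosage columns")
        missing_cols = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing_cols:
            raise ValueError(f"sites missing columns: {missing_cols}")
        self.sites = self.sites.reset_index(drop=True)
        if not self._sites_sorted():
            raise ValueError("sites must be sorted by (chrom, pos)")
        bad = self.sites["ref"] == self.sites["alt"]
        if bad.any():
            raise ValueError("REF must differ from ALT at every site")

    def _sites_sorted(self) -> bool:
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for i in range(1, len(chrom)):
            if chrom[i] < chrom[i - 1]:
                return False
            if chrom[i] == chrom[i - 1] and pos[i] <= pos[i - 1]:
                return False
        return True

    # -- basic shape ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def pop_labels(self) -> list[str]:
        """Distinct population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, label: str) -> np.ndarray:
        mask = self.populations == label
        if not mask.any():
            raise KeyError(f"no samples labelled {label!r}")
        return mask

    # -- per-site summaries --------------------------------------------

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes (samples x sites)."""
        return self.dosages != MISSING

    def allele_counts(self, pop: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (ALT allele count, called allele count).

        Restricted to one population when ``pop`` is given, otherwise
        pooled over all samples.
        """
        d = self.dosages if pop is None else self.dosages[self.pop_mask(pop)]
        called = d != MISSING
        alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
        total = 2 * called.sum(axis=0, dtype=np.int64)
        return alt, total

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a called genotype, per site."""
        return self.called().mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency over called alleles pooled across populations.

        Sites with zero called alleles get MAF 0.
        """
        alt, total = self.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, alt / np.maximum(total, 1), 0.0)
        return np.minimum(p, 1.0 - p)

    def alt_freq(self, pop: str | None = None) -> np.ndarray:
        """ALT-allele frequency over called alleles (NaN when none called)."""
        alt, total = self.allele_counts(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, alt / np.maximum(total, 1), np.nan)

    # -- subsetting ----------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            sites=self.sites.iloc[index].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            populations=self.populations.copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[index].copy(),
            sites=self.sites.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
            populations=self.populations[index].copy(),
        )

    def __eq__(self, other: object) -> bool:  # element-wise identity
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and list(self.populations) == list(other.populations)
            and np.array_equal(self.dosages, other.dosages)
            and self.sites[list(SITE_COLUMNS)].equals(other.sites[list(SITE_COLUMNS)])
        )
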