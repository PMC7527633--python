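"""Synthetic two-population cohorts with planted selective sweeps.

The generator emulates a domestication scenario: a "domestic" population
(default 20 diploids) and a "wild" population (default 13 diploids)
diverged from a common ancestral gene pool.  Site frequencies follow the
Balding–Nichols model: given an ancestral frequency ``p`` and a
divergence parameter ``F``, each population's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose expected Weir–Cockerham F_ST is
``F`` — the quantity the downstream scan measures.  Inside planted sweep
intervals the domestic population diverges with a larger ``sweep_F`` and
its frequency is pushed toward the nearer of {0, 1} so that expected
heterozygosity shrinks by ``sweep_diversity_scale``, producing the
low-diversity / high-differentiation signature of a selective sweep.

Everything downstream (VCF, GFF3, FASTA, BED) can be written to disk so
the full pipeline runs without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

DEFAULT_CHROM_LENGTHS = {f"chr{i}": 30_000_000 for i in range(1, 6)}
# One 300-kb sweep per chromosome, placed away from chromosome ends.
DEFAULT_SWEEPS = [
    (f"chr{i}", 10_000_000, 10_300_000) for i in range(1, 6)
]


@dataclass
class SimulationConfig:
    """Parameters of the two-population cohort simulation.

    Defaults describe the study conditions the package is exercised
    under: 20 domestic + 13 wild diploids, a 150-Mb genome in five
    chromosomes carrying ~0.7 SNVs/kb (about 70 SNVs per 100-kb window),
    moderate background differentiation and five strong 300-kb sweeps.
    """

    n_pop1: int = 20                      # domestic samples
    n_pop2: int = 13                      # wild samples
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    n_sites: int = 105_000
    background_F: float = 0.05
    sweep_intervals: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_SWEEPS))
    sweep_F: float = 0.6
    sweep_diversity_scale: float = 0.1
    missing_rate: float = 0.02
    tstv_target: float = 2.29
    seed: int = 0
    pop1_label: str = "domestic"
    pop2_label: str = "wild"

    def validate(self) -> None:
        if self.n_pop1 < 1 or self.n_pop2 < 1:
            raise ValueError("each population needs at least one sample")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if any(length < 1 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not (0.0 < self.background_F < 1.0):
            raise ValueError("background_F must lie in (0, 1)")
        if self.sweep_intervals and not (
                self.background_F < self.sweep_F < 1.0):
            raise ValueError("need background_F < sweep_F < 1")
        if not (0.0 < self.sweep_diversity_scale <= 1.0):
            raise ValueError("sweep_diversity_scale must lie in (0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.tstv_target <= 0:
            raise ValueError("tstv_target must be positive")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.sweep_intervals:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"sweep ({chrom}, {start}, {end}) outside chromosome")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping sweep intervals on {chrom}")

    def to_dict(self) -> dict:
        return {
            "n_pop1": self.n_pop1,
            "n_pop2": self.n_pop2,
            "chrom_lengths": dict(self.chrom_lengths),
            "n_sites": self.n_sites,
            "background_F": self.background_F,
            "sweep_intervals": [list(iv) for iv in self.sweep_intervals],
            "sweep_F": self.sweep_F,
            "sweep_diversity_scale": self.sweep_diversity_scale,
            "missing_rate": self.missing_rate,
            "tstv_target": self.tstv_target,
            "seed": self.seed,
            "pop1_label": self.pop1_label,
            "pop2_label": self.pop2_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "sweep_intervals" in d:
            d["sweep_intervals"] = [tuple(iv) for iv in d["sweep_intervals"]]
        if "chrom_lengths" in d:
            d["chrom_lengths"] = {
                str(k): int(v) for k, v in d["chrom_lengths"].items()}
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery scoring.

    ``ancestral_freq`` and ``pop_freqs`` are per-site allele frequencies
    (kept in memory; the JSON sidecar stores only intervals and
    parameters).
    """

    sweep_intervals: list[tuple[str, int, int]]
    ancestral_freq: np.ndarray
    pop_freqs: dict[str, np.ndarray]
    seed: int
    config: SimulationConfig


def _allocate_sites(config: SimulationConfig) -> dict[str, int]:
    """Distribute n_sites over chromosomes proportionally to length."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    exact = config.n_sites * lengths / lengths.sum()
    counts = np.floor(exact).astype(int)
    # hand remaining sites to the largest fractional parts
    remainder = config.n_sites - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:remainder]] += 1
    alloc = dict(zip(chroms, counts))
    if any(n == 0 for n in alloc.values()):
        raise ValueError(
            "site allocation gives zero sites on some chromosome; "
            "increase n_sites or drop the chromosome")
    return alloc


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """Sorted distinct 1-based positions, uniform on [1, length]."""
    if n > length:
        raise ValueError("more sites requested than chromosome positions")
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    # subsample back to exactly n while keeping order
    keep = np.sort(rng.choice(len(pos), size=n, replace=False))
    return pos[keep]


def _ancestral_frequencies(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ancestral frequencies from the neutral spectrum P(i) ∝ 1/i.

    Allele counts i over a notional pool of 100 alleles are converted to
    frequencies i/100 and truncated to [0.02, 0.98]; the 1/i shape is
    the standard neutral site-frequency spectrum.
    """
    i = np.arange(1, 100)
    w = 1.0 / i
    counts = rng.choice(i, size=n, p=w / w.sum())
    return np.clip(counts / 100.0, 0.02, 0.98)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     F: np.ndarray | float) -> np.ndarray:
    """Population frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    F = np.broadcast_to(np.asarray(F, dtype=float), p.shape)
    scale = (1.0 - F) / F
    return rng.beta(p * scale, (1.0 - p) * scale)


def _shrink_heterozygosity(q: np.ndarray, scale: float) -> np.ndarray:
    """Push frequencies toward the nearer boundary of {0, 1}.

    Solves q'(1-q') = scale * q(1-q) on the same side of 1/2 as q, so
    expected heterozygosity 2q'(1-q') is exactly ``scale`` times the
    original.
    """
    prod = scale * q * (1.0 - q)
    low = 0.5 * (1.0 - np.sqrt(np.maximum(1.0 - 4.0 * prod, 0.0)))
    return np.where(q <= 0.5, low, 1.0 - low)


def _in_intervals(chrom: np.ndarray, pos: np.ndarray,
                  intervals: list[tuple[str, int, int]]) -> np.ndarray:
    """Mask of 1-based positions falling in 0-based half-open intervals."""
    mask = np.zeros(len(pos), dtype=bool)
    for c, start, end in intervals:
        mask |= (chrom == c) & (pos - 1 >= start) & (pos - 1 < end)
    return mask


def _draw_ref_alt(rng: np.random.Generator, n: int,
                  tstv_target: float) -> tuple[np.ndarray, np.ndarray]:
    """REF/ALT pairs with transitions at probability t/(t+1)."""
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, size=n)]
    is_ts = rng.random(n) < tstv_target / (tstv_target + 1.0)
    alt = np.empty(n, dtype=object)
    pick = rng.integers(0, 2, size=n)
    for b in bases:
        sel = ref == b
        alt[sel & is_ts] = TRANSITION[b]
        for k in (0, 1):
            alt[sel & ~is_ts & (pick == k)] = TRANSVERSIONS[b][k]
    return ref.astype(object), alt


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate genotypes for a two-population cohort with planted sweeps.

    Returns the genotype matrix (population labels from the config) and
    the simulation truth.  Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    alloc = _allocate_sites(config)
    chrom_arr: list[np.ndarray] = []
    pos_arr: list[np.ndarray] = []
    for chrom in config.chrom_lengths:  # insertion order = sorted by caller
        n = alloc[chrom]
        pos = _draw_positions(rng, config.chrom_lengths[chrom], n)
        chrom_arr.append(np.full(n, chrom, dtype=object))
        pos_arr.append(pos)
    chrom = np.concatenate(chrom_arr)
    pos = np.concatenate(pos_arr)
    m = len(pos)

    p_anc = _ancestral_frequencies(rng, m)
    sweep_mask = _in_intervals(chrom, pos, config.sweep_intervals)

    # wild (pop2): background divergence everywhere
    q2 = _balding_nichols(rng, p_anc, config.background_F)
    # domestic (pop1): background outside sweeps, strong divergence inside
    F1 = np.where(sweep_mask, config.sweep_F, config.background_F)
    q1 = _balding_nichols(rng, p_anc, F1)
    q1[sweep_mask] = _shrink_heterozygosity(
        q1[sweep_mask], config.sweep_diversity_scale)

    n_total = config.n_pop1 + config.n_pop2
    dosages = np.empty((n_total, m), dtype=np.int8)
    dosages[:config.n_pop1] = rng.binomial(
        2, q1, size=(config.n_pop1, m)).astype(np.int8)
    dosages[config.n_pop1:] = rng.binomial(
        2, q2, size=(config.n_pop2, m)).astype(np.int8)
    if config.missing_rate > 0:
        drop = rng.random(dosages.shape) < config.missing_rate
        dosages[drop] = MISSING

    ref, alt = _draw_ref_alt(rng, m, config.tstv_target)
    sites = pd.DataFrame({
        "chrom": chrom,
        "pos": pos.astype(np.int64),
        "ref": ref,
        "alt": alt,
        "qual": np.full(m, 100.0),
    })
    width = len(str(max(config.n_pop1, config.n_pop2)))
    sample_ids = (
        [f"dom{i+1:0{width}d}" for i in range(config.n_pop1)]
        + [f"wild{i+1:0{width}d}" for i in range(config.n_pop2)]
    )
    populations = np.array(
        [config.pop1_label] * config.n_pop1
        + [config.pop2_label] * config.n_pop2, dtype=object)

    genotypes = GenotypeMatrix(dosages, sites, sample_ids, populations)
    truth = SimTruth(
        sweep_intervals=sorted(config.sweep_intervals),
        ancestral_freq=p_anc,
        pop_freqs={config.pop1_label: q1, config.pop2_label: q2},
        seed=config.seed,
        config=config,
    )
    return genotypes, truth


def inject_missingness(genotypes: GenotypeMatrix, rate: float,
                       seed: int) -> GenotypeMatrix:
    """Set each genotype to missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return genotypes
    rng = np.random.default_rng(seed)
    dosages = genotypes.dosages.copy()
    dosages[rng.random(dosages.shape) < rate] = MISSING
    return GenotypeMatrix(dosages, genotypes.sites.copy(),
                          list(genotypes.sample_ids),
                          genotypes.populations.copy())


# ---------------------------------------------------------------------------
# synthetic gene models
# ---------------------------------------------------------------------------

# Relative single-transcript gene layout (0-based half-open, span 6 kb);
# CDS totals 1800 bp (divisible by 3).  Minus-strand genes mirror it.
_GENE_SPAN = 6_000
_PLUS_LAYOUT = {
    "exons": [(0, 1000), (2000, 3000), (4000, 6000)],
    "cds": [(500, 1000), (2000, 3000), (4000, 4300)],
    "utr5": [(0, 500)],
    "utr3": [(4300, 6000)],
}


def _reflect(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    return sorted((_GENE_SPAN - e, _GENE_SPAN - s) for s, e in intervals)


_MINUS_LAYOUT = {key: _reflect(val) for key, val in _PLUS_LAYOUT.items()}


def synthetic_gene_models(chrom_lengths: dict[str, int],
                          spacing: int = 200_000,
                          offset: int = 50_000) -> list:
    """Tile single-transcript genes across the genome.

    One gene every ``spacing`` bp, strands alternating so both
    orientations of the coding-annotation path are exercised.  Returns
    :class:`~sweepscan.variants_io.GeneModel` objects.
    """
    from .variants_io import GeneModel  # local import to avoid a cycle

    genes = []
    k = 0
    for chrom, length in chrom_lengths.items():
        start = offset
        while start + _GENE_SPAN <= length:
            strand = "+" if k % 2 == 0 else "-"
            layout = _PLUS_LAYOUT if strand == "+" else _MINUS_LAYOUT
            shift = lambda ivs: [(start + s, start + e) for s, e in ivs]
            genes.append(GeneModel(
                gene_id=f"gene{k+1:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=start + _GENE_SPAN,
                exons=shift(layout["exons"]),
                cds=shift(layout["cds"]),
                utr5=shift(layout["utr5"]),
                utr3=shift(layout["utr3"]),
            ))
            k += 1
            start += spacing
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(genotypes: GenotypeMatrix, path: Path | str,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    path = Path(path)
    gt_lookup = np.array([_GT_STRINGS[0], _GT_STRINGS[1], _GT_STRINGS[2],
                          _GT_STRINGS[-1]], dtype=object)
    codes = genotypes.dosages.copy()
    codes[codes == MISSING] = 3
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(genotypes.sites["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        chroms = genotypes.sites["chrom"].to_numpy()
        poss = genotypes.sites["pos"].to_numpy()
        refs = genotypes.sites["ref"].to_numpy()
        alts = genotypes.sites["alt"].to_numpy()
        quals = genotypes.sites["qual"].to_numpy()
        for j in range(genotypes.n_sites):
            qual = quals[j]
            qual_str = "." if not np.isfinite(qual) else (
                f"{qual:g}" if qual != int(qual) else str(int(qual)))
            row = gt_lookup[codes[:, j]]
            fh.write(f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t"
                     f"{qual_str}\t.\t.\tGT\t" + "\t".join(row) + "\n")


def write_populations_tsv(genotypes: GenotypeMatrix, path: Path | str) -> None:
    with Path(path).open("w") as fh:
        for sid, pop in zip(genotypes.sample_ids, genotypes.populations):
            fh.write(f"{sid}\t{pop}\n")


def write_truth_bed(truth: SimTruth, path: Path | str) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in truth.sweep_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\tsweep\n")


def write_gff3(genes: list, path: Path | str) -> None:
    """Write single-transcript gene models as GFF3 (1-based inclusive)."""
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(f"{g.chrom}\tsweepscan\tgene\t{g.start+1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsweepscan\tmRNA\t{g.start+1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tsweepscan\texon\t{s+1}\t{e}\t.\t"
                         f"{g.strand}\t.\tParent={tid}\n")
            for (s, e), frame in zip(g.cds, g.cds_frames()):
                fh.write(f"{g.chrom}\tsweepscan\tCDS\t{s+1}\t{e}\t.\t"
                         f"{g.strand}\t{frame}\tParent={tid}\n")
            for s, e in g.utr5:
                fh.write(f"{g.chrom}\tsweepscan\tfive_prime_UTR\t{s+1}\t{e}"
                         f"\t.\t{g.strand}\t.\tParent={tid}\n")
            for s, e in g.utr3:
                fh.write(f"{g.chrom}\tsweepscan\tthree_prime_UTR\t{s+1}\t{e}"
                         f"\t.\t{g.strand}\t.\tParent={tid}\n")


def write_reference_fasta(genotypes: GenotypeMatrix,
                          chrom_lengths: dict[str, int],
                          path: Path | str, seed: int = 0,
                          line_width: int = 80) -> None:
    """Random reference sequence consistent with the cohort's REF alleles."""
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sites = genotypes.sites
    with Path(path).open("wb") as fh:
        for chrom, length in chrom_lengths.items():
            seq = bases[rng.integers(0, 4, size=length)]
            sel = sites["chrom"] == chrom
            pos = sites.loc[sel, "pos"].to_numpy() - 1
            refs = sites.loc[sel, "ref"].to_numpy()
            seq[pos] = np.char.encode(refs.astype(str))
            fh.write(f">{chrom}\n".encode())
            data = seq.tobytes()
            for i in range(0, length, line_width):
                fh.write(data[i:i + line_width])
                fh.write(b"\n")


def write_cohort(genotypes: GenotypeMatrix, truth: SimTruth,
                 outdir: Path | str) -> dict[str, Path]:
    """Write VCF + truth BED + synthetic GFF3 + reference FASTA + sidecars.

    Round-tripping the VCF through :func:`sweepscan.variants_io.read_vcf`
    reproduces the dosage matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = truth.config
    paths = {
        "vcf": outdir / "cohort.vcf",
        "populations": outdir / "populations.tsv",
        "truth_bed": outdir / "truth_sweeps.bed",
        "truth_json": outdir / "truth.json",
        "gff3": outdir / "genes.gff3",
        "fasta": outdir / "reference.fa",
    }
    write_vcf(genotypes, paths["vcf"], config.chrom_lengths)
    write_populations_tsv(genotypes, paths["populations"])
    write_truth_bed(truth, paths["truth_bed"])
    genes = synthetic_gene_models(config.chrom_lengths)
    write_gff3(genes, paths["gff3"])
    write_reference_fasta(genotypes, config.chrom_lengths, paths["fasta"],
                          seed=config.seed)
    with paths["truth_json"].open("w") as fh:
        json.dump({
            "sweep_intervals": [list(iv) for iv in truth.sweep_intervals],
            "seed": truth.seed,
            "config": config.to_dict(),
        }, fh, indent=2)
    return paths


def load_truth_json(path: Path | str) -> SimTruth:
    """Rehydrate intervals/parameters from a truth sidecar (no frequencies)."""
    with Path(path).open() as fh:
        payload = json.load(fh)
    config = SimulationConfig.from_dict(payload["config"])
    return SimTruth(
        sweep_intervals=[tuple(iv) for iv in payload["sweep_intervals"]],
        ancestral_freq=np.empty(0),
        pop_freqs={},
        seed=payload["seed"],
        config=config,
    )
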