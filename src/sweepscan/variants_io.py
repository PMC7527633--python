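"""Variant I/O, site filters, LD pruning, Ts/Tv and functional annotation.

Reads multi-sample VCF into a :class:`~sweepscan.genotypes.GenotypeMatrix`,
applies the scan / structure site filters, prunes linked sites the way
``plink --indep-pairwise`` does, and assigns each SNV one functional
category (intergenic, upstream, downstream, UTR, splicing, intron,
synonymous or non-synonymous coding) against single-transcript gene
models, translating codons on the coding strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

CATEGORIES = (
    "intergenic", "upstream", "downstream", "utr5", "utr3",
    "splicing", "intron", "coding_synonymous", "coding_nonsynonymous",
)

# most severe first; used both for within-gene precedence and to resolve
# variants overlapping two genes
_SEVERITY = (
    "coding_nonsynonymous", "coding_synonymous", "splicing",
    "utr5", "utr3", "intron", "upstream", "downstream", "intergenic",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(_SEVERITY)}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class AnnotationError(ValueError):
    """Raised when a variant contradicts the reference sequence."""


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """Single-transcript stranded gene model (0-based half-open intervals)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_frames(self) -> list[int]:
        """GFF3 phase per CDS segment, aligned to genomic order."""
        order = self.cds if self.strand == "+" else self.cds[::-1]
        frames, cum = [], 0
        for s, e in order:
            frames.append((3 - cum % 3) % 3)
            cum += e - s
        return frames if self.strand == "+" else frames[::-1]

    def coding_positions(self) -> np.ndarray:
        """Genomic 0-based positions of CDS bases in translation order."""
        parts = [np.arange(s, e) for s, e in self.cds]
        pos = np.concatenate(parts) if parts else np.empty(0, dtype=int)
        return pos if self.strand == "+" else pos[::-1]


def read_populations_tsv(path: Path | str) -> dict[str, str]:
    """Two-column sample -> population map (tab-separated, no header)."""
    out: dict[str, str] = {}
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_gff3(path: Path | str) -> list[GeneModel]:
    """Parse GFF3 gene models (first transcript per gene wins).

    Exons and CDS are taken from the file; UTRs are derived as the exon
    bases outside the CDS span, which is robust to files that omit
    explicit UTR features.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:",
                            merge_strategy="create_unique", force=True)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, level=1))
        transcripts = [t for t in transcripts
                       if t.featuretype not in ("exon", "CDS")]
        if len(transcripts) > 1:
            logger.info("gene %s: %d transcripts, using the first",
                        gene.id, len(transcripts))
        parent = transcripts[0] if transcripts else gene
        exons = sorted((f.start - 1, f.end)
                       for f in db.children(parent, featuretype="exon"))
        cds = sorted((f.start - 1, f.end)
                     for f in db.children(parent, featuretype="CDS"))
        if not exons:
            exons = cds or [(gene.start - 1, gene.end)]
        utr5, utr3 = _derive_utrs(exons, cds, gene.strand)
        genes.append(GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
            start=gene.start - 1, end=gene.end,
            exons=exons, cds=cds, utr5=utr5, utr3=utr3))
    return genes


def _derive_utrs(exons, cds, strand):
    """Exonic bases before/after the CDS span, split by strand polarity."""
    if not cds:
        return [], []
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    left, right = [], []
    for s, e in exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    return (left, right) if strand == "+" else (right, left)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_vcf(path: Path | str, sample_populations: dict[str, str],
             with_stats: bool = False):
    """Read a VCF v4.2 into a genotype matrix.

    Multiallelic and non-SNV records are skipped (counts logged).
    Dosage is the ALT-allele count; half-calls count as missing.

    Parameters
    ----------
    sample_populations
        Map covering every sample in the VCF.
    with_stats
        Also return a dict with ``skipped_multiallelic`` /
        ``skipped_non_snv`` / ``n_records`` counters.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_populations]
    if unknown:
        raise ValueError(f"samples missing from population map: {unknown}")
    populations = np.array([sample_populations[s] for s in samples],
                           dtype=object)

    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    stats = {"skipped_multiallelic": 0, "skipped_non_snv": 0, "n_records": 0}
    for v in vcf:
        stats["n_records"] += 1
        if len(v.ALT) != 1:
            stats["skipped_multiallelic"] += 1
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            stats["skipped_non_snv"] += 1
            continue
        arr = v.genotype.array()  # (n_samples, ploidy+1), alleles then phase
        alleles = arr[:, :-1]
        called = (alleles >= 0).all(axis=1)
        dos = np.where(called, (alleles > 0).sum(axis=1), MISSING)
        rows.append(dos.astype(np.int8))
        qual = v.QUAL if v.QUAL is not None else np.nan
        meta.append((v.CHROM, v.POS, ref, alt, qual))
    vcf.close()
    if stats["skipped_multiallelic"] or stats["skipped_non_snv"]:
        logger.info("read_vcf: skipped %d multiallelic, %d non-SNV records",
                    stats["skipped_multiallelic"], stats["skipped_non_snv"])

    sites = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt", "qual"])
    dosages = (np.array(rows, dtype=np.int8).T if rows
               else np.empty((len(samples), 0), dtype=np.int8))
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy())) if len(sites) else []
    g = GenotypeMatrix(dosages[:, order] if len(sites) else dosages,
                       sites.iloc[order].reset_index(drop=True) if len(sites) else sites,
                       samples, populations)
    return (g, stats) if with_stats else g


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

def filter_sites_scan(g: GenotypeMatrix, min_call_rate: float = 0.90,
                      min_maf: float = 0.05, max_missing: float = 0.20,
                      ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Site filter for the selection scan.

    Retains sites with call rate >= ``min_call_rate``, pooled MAF >=
    ``min_maf`` and missing fraction <= ``max_missing`` (boundary values
    are kept; the filters exclude strictly beyond each threshold).
    Returns the filtered matrix and per-criterion removal counts; a
    criterion's count includes every site it would remove on its own.
    """
    call_rate = g.call_rate()
    maf = g.maf()
    missing = 1.0 - call_rate
    fail_call = call_rate < min_call_rate
    fail_maf = maf < min_maf
    fail_missing = missing > max_missing
    keep = ~(fail_call | fail_maf | fail_missing)
    removed = {
        "call_rate": int(fail_call.sum()),
        "maf": int(fail_maf.sum()),
        "missing": int(fail_missing.sum()),
        "total_removed": int((~keep).sum()),
    }
    if not keep.any():
        logger.warning("filter_sites_scan: no sites retained")
    return g.take_sites(keep), removed


def filter_sites_structure(g: GenotypeMatrix, min_maf: float = 0.05,
                           max_missing: float = 0.05, min_qual: float = 30,
                           ) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Site filter for structure analyses (PCA / tree / LD).

    Removes sites with MAF < ``min_maf``, missing fraction >
    ``max_missing`` or QUAL < ``min_qual``.  LD pruning is a separate
    step (:func:`ld_prune`).  When QUAL is absent the quality criterion
    is skipped with a warning.
    """
    maf = g.maf()
    missing = 1.0 - g.call_rate()
    qual = g.sites["qual"].to_numpy(dtype=float)
    fail_maf = maf < min_maf
    fail_missing = missing > max_missing
    if np.isnan(qual).all():
        logger.warning("filter_sites_structure: QUAL absent, skipping "
                       "quality filter")
        fail_qual = np.zeros(len(qual), dtype=bool)
    else:
        fail_qual = np.where(np.isnan(qual), False, qual < min_qual)
    keep = ~(fail_maf | fail_missing | fail_qual)
    removed = {
        "maf": int(fail_maf.sum()),
        "missing": int(fail_missing.sum()),
        "qual": int(fail_qual.sum()),
        "total_removed": int((~keep).sum()),
    }
    return g.take_sites(keep), removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _imputed_standardized(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages and center each site (columns)."""
    d = dosages.astype(float)
    d[dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    inds = np.where(np.isnan(d))
    d[inds] = mean[inds[1]]
    return d - d.mean(axis=0)


def ld_prune(g: GenotypeMatrix, window_snps: int = 100, step_snps: int = 10,
             r2_max: float = 0.01) -> GenotypeMatrix:
    """Greedy within-window LD pruning (``plink --indep-pairwise`` style).

    Within each sliding window of ``window_snps`` sites (per
    chromosome, advancing by ``step_snps``): while any retained pair has
    squared dosage correlation above ``r2_max``, drop the lower-MAF
    member of the worst pair (ties broken toward the later position).
    Missing dosages are mean-imputed for the correlation computation.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    maf = g.maf()
    keep = np.ones(g.n_sites, dtype=bool)
    chroms = g.sites["chrom"].to_numpy()
    X = _imputed_standardized(g.dosages)
    norms = np.sqrt((X ** 2).sum(axis=0))

    for chrom in dict.fromkeys(chroms):
        idx_all = np.flatnonzero(chroms == chrom)
        for w0 in range(0, len(idx_all), step_snps):
            widx = idx_all[w0:w0 + window_snps]
            widx = widx[keep[widx]]
            if len(widx) < 2:
                if w0 + window_snps >= len(idx_all):
                    break
                continue
            Xw = X[:, widx]
            nw = norms[widx]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (Xw.T @ Xw) / np.outer(nw, nw)
            r2 = np.nan_to_num(r ** 2, nan=0.0)
            np.fill_diagonal(r2, 0.0)
            active = np.ones(len(widx), dtype=bool)
            while active.sum() >= 2:
                ai = np.flatnonzero(active)
                sub = r2[np.ix_(ai, ai)]
                if sub.max() <= r2_max:
                    break
                i, j = divmod(int(np.argmax(sub)), len(ai))
                si, sj = widx[ai[i]], widx[ai[j]]
                # drop lower MAF; tie -> later position
                if maf[si] < maf[sj]:
                    drop = ai[i]
                elif maf[sj] < maf[si]:
                    drop = ai[j]
                else:
                    drop = ai[i] if si > sj else ai[j]
                active[drop] = False
                keep[widx[drop]] = False
            if w0 + window_snps >= len(idx_all):
                break
    return g.take_sites(keep)


# ---------------------------------------------------------------------------
# Ts/Tv
# ---------------------------------------------------------------------------

def tstv_ratio(g: GenotypeMatrix) -> float:
    """Transition/transversion ratio of the REF/ALT pairs.

    Returns ``inf`` with a warning when there are no transversions.
    """
    pairs = [frozenset((r, a)) for r, a in
             zip(g.sites["ref"], g.sites["alt"])]
    ts = sum(p in TRANSITION_PAIRS for p in pairs)
    tv = len(pairs) - ts
    if tv == 0:
        logger.warning("tstv_ratio: no transversions, ratio undefined")
        return float("inf")
    return ts / tv


# ---------------------------------------------------------------------------
# functional annotation
# ---------------------------------------------------------------------------

class _Reference:
    """Uniform base access over pyfaidx.Fasta, a path, or a dict of strings."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta
            self._fa = Fasta(str(source))
            self._dict = None
        elif isinstance(source, dict):
            self._fa = None
            self._dict = source
        else:
            self._fa = source
            self._dict = None

    def base(self, chrom: str, pos0: int) -> str:
        if self._dict is not None:
            return self._dict[chrom][pos0].upper()
        return str(self._fa[chrom][pos0:pos0 + 1]).upper()


def _categorize_in_gene(pos0: int, gene: GeneModel, coding_pos: np.ndarray,
                        reference: _Reference | None, ref_base: str,
                        alt_base: str, splice_bp: int,
                        upstream_bp: int, downstream_bp: int) -> str | None:
    """Category of a variant relative to one gene, or None if out of range."""
    if gene.start <= pos0 < gene.end:
        # coding?
        if coding_pos is not None and len(coding_pos):
            where = np.flatnonzero(coding_pos == pos0)
            if len(where):
                if reference is None:
                    raise AnnotationError(
                        f"coding variant at {gene.chrom}:{pos0 + 1} but no "
                        "reference sequence provided")
                return _coding_effect(pos0, int(where[0]), gene, coding_pos,
                                      reference, ref_base, alt_base)
        # exonic?
        in_exon = any(s <= pos0 < e for s, e in gene.exons)
        if in_exon:
            if any(s <= pos0 < e for s, e in gene.utr5):
                return "utr5"
            if any(s <= pos0 < e for s, e in gene.utr3):
                return "utr3"
            # exonic but neither CDS nor UTR (e.g. non-coding gene)
            return "intron"
        # intronic: splicing if within splice_bp of an exon boundary
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            if e1 <= pos0 < s2:
                if pos0 - e1 < splice_bp or s2 - 1 - pos0 < splice_bp:
                    return "splicing"
                return "intron"
        return "intron"
    # flanking, strand-aware
    if gene.strand == "+":
        if gene.start - upstream_bp <= pos0 < gene.start:
            return "upstream"
        if gene.end <= pos0 < gene.end + downstream_bp:
            return "downstream"
    else:
        if gene.end <= pos0 < gene.end + upstream_bp:
            return "upstream"
        if gene.start - downstream_bp <= pos0 < gene.start:
            return "downstream"
    return None


def _coding_effect(pos0: int, coding_index: int, gene: GeneModel,
                   coding_pos: np.ndarray, reference: _Reference,
                   ref_base: str, alt_base: str) -> str:
    genome_base = reference.base(gene.chrom, pos0)
    if genome_base != ref_base:
        raise AnnotationError(
            f"variant REF {ref_base!r} at {gene.chrom}:{pos0 + 1} disagrees "
            f"with reference base {genome_base!r}")
    codon_idx = coding_index // 3
    offset = coding_index % 3
    codon_positions = coding_pos[3 * codon_idx: 3 * codon_idx + 3]
    if len(codon_positions) < 3:  # incomplete terminal codon
        return "coding_synonymous"
    bases = [reference.base(gene.chrom, int(p)) for p in codon_positions]
    if gene.strand == "-":
        bases = [_COMPLEMENT[b] for b in bases]
        var = _COMPLEMENT[alt_base]
    else:
        var = alt_base
    ref_codon = "".join(bases)
    alt_codon = bases[:offset] + [var] + bases[offset + 1:]
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq("".join(alt_codon)).translate())
    return ("coding_synonymous" if aa_ref == aa_alt
            else "coding_nonsynonymous")


def annotate_variants(g: GenotypeMatrix, genes: list[GeneModel],
                      reference=None, upstream_bp: int = 1000,
                      downstream_bp: int = 1000,
                      splice_bp: int = 2) -> pd.DataFrame:
    """Assign one functional category per variant.

    Precedence within a gene: coding / splicing > UTR > intron >
    upstream / downstream.  Variants overlapping several genes take the
    most severe category (ambiguity counts are logged).  Coding variants
    are translated with the standard codon table on the coding strand;
    genes whose CDS length is not divisible by 3 are skipped.

    Returns a DataFrame with columns ``chrom, pos, category, gene_id``
    aligned to ``g.sites``.
    """
    usable: list[GeneModel] = []
    for gene in genes:
        if gene.cds and gene.cds_length % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3, "
                           "skipped", gene.gene_id, gene.cds_length)
            continue
        usable.append(gene)

    trees: dict[str, IntervalTree] = {}
    flank = max(upstream_bp, downstream_bp)
    for gene in usable:
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            max(gene.start - flank, 0), gene.end + flank, gene)
    coding_cache = {gene.gene_id: gene.coding_positions() for gene in usable}
    ref = _Reference(reference) if reference is not None else None

    chroms = g.sites["chrom"].to_numpy()
    poss = g.sites["pos"].to_numpy()
    refs = g.sites["ref"].to_numpy()
    alts = g.sites["alt"].to_numpy()
    categories = np.full(g.n_sites, "intergenic", dtype=object)
    gene_ids = np.full(g.n_sites, "", dtype=object)
    n_ambiguous = 0
    for j in range(g.n_sites):
        tree = trees.get(chroms[j])
        if tree is None:
            continue
        pos0 = int(poss[j]) - 1
        hits = tree[pos0]
        best, best_gene = None, ""
        n_hit = 0
        for iv in hits:
            gene = iv.data
            cat = _categorize_in_gene(
                pos0, gene, coding_cache[gene.gene_id], ref,
                refs[j], alts[j], splice_bp, upstream_bp, downstream_bp)
            if cat is None:
                continue
            n_hit += 1
            if best is None or _SEVERITY_RANK[cat] < _SEVERITY_RANK[best]:
                best, best_gene = cat, gene.gene_id
        if n_hit > 1:
            n_ambiguous += 1
        if best is not None:
            categories[j] = best
            gene_ids[j] = best_gene
    if n_ambiguous:
        logger.info("annotate_variants: %d variants overlap multiple genes; "
                    "most severe category kept", n_ambiguous)
    return pd.DataFrame({
        "chrom": chroms, "pos": poss,
        "category": categories, "gene_id": gene_ids,
    })


def annotation_summary(annotations: pd.DataFrame) -> pd.DataFrame:
    """Category counts and percentages (rows sum to the SNV total)."""
    counts = annotations["category"].value_counts()
    rows = []
    total = len(annotations)
    for cat in _SEVERITY[::-1]:
        n = int(counts.get(cat, 0))
        rows.append((cat, n, 100.0 * n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


# ---------------------------------------------------------------------------
# region membership
# ---------------------------------------------------------------------------

def variants_in_regions(g: GenotypeMatrix,
                        regions: list[tuple[str, int, int]]) -> np.ndarray:
    """SNV count per region (regions 0-based half-open, sites 1-based)."""
    chroms = g.sites["chrom"].to_numpy()
    pos0 = g.sites["pos"].to_numpy() - 1
    counts = np.zeros(len(regions), dtype=int)
    by_chrom = {c: np.sort(pos0[chroms == c]) for c in dict.fromkeys(chroms)}
    for k, (chrom, start, end) in enumerate(regions):
        p = by_chrom.get(chrom)
        if p is None:
            continue
        counts[k] = np.searchsorted(p, end, "left") - np.searchsorted(p, start, "left")
    return counts
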