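"""Independent brute-force oracles used by the unit and acceptance tests.

Each function re-derives a quantity by the most literal possible route
(explicit enumeration, full-transcript translation, textbook formula
transcription) so it shares no code path with the package internals it
checks.
"""

import numpy as np
from Bio.Seq import Seq

from sweepscan.genotypes import MISSING


def explicit_window_pi(g, pop, grid):
    """π per window by explicit enumeration of all allele pairs.

    O(n_alleles² · m): for every site, list the called alleles and count
    differing pairs over all C(c, 2) pairs; sum over window sites and
    divide by the window span.
    """
    mask = g.populations == pop
    out = np.zeros(len(grid))
    for w, (_, row) in enumerate(grid.iterrows()):
        total = 0.0
        for j in range(g.n_sites):
            if g.sites["chrom"][j] != row["chrom"]:
                continue
            pos0 = g.sites["pos"][j] - 1
            if not (row["start"] <= pos0 < row["end"]):
                continue
            alleles = []
            for d in g.dosages[mask, j]:
                if d != MISSING:
                    alleles.extend([1] * d + [0] * (2 - d))
            c = len(alleles)
            if c < 2:
                continue
            diff = sum(1 for a in range(c) for b in range(a + 1, c)
                       if alleles[a] != alleles[b])
            total += diff / (c * (c - 1) / 2)
        out[w] = total / (row["end"] - row["start"])
    return out


def wc_theta_literal(counts1, counts2):
    """Literal transcription of the Weir & Cockerham (1984) estimator.

    ``counts1``/``counts2`` are genotype counts (n_AA, n_Aa, n_aa) for
    the two populations; returns (a, b, c) for the 'a' allele.  Written
    from the published component formulas with r = 2, independently of
    the package's vectorized version.
    """
    r = 2
    n_i, p_i, h_i = [], [], []
    for (n_AA, n_Aa, n_aa) in (counts1, counts2):
        n = n_AA + n_Aa + n_aa
        n_i.append(n)
        p_i.append((2 * n_aa + n_Aa) / (2 * n))
        h_i.append(n_Aa / n)
    n_i = np.array(n_i, float)
    p_i = np.array(p_i, float)
    h_i = np.array(h_i, float)
    n_bar = n_i.sum() / r
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar)
                                - (r - 1) / r * s2 - h_bar / 4))
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a, b, c


def independent_category(pos0, ref_base, alt_base, gene, reference,
                         upstream_bp=1000, downstream_bp=1000, splice_bp=2):
    """Functional category of a variant against one gene, derived naively.

    Coding effects are decided by mutating the FULL spliced CDS string
    and translating both proteins end-to-end with Biopython — a
    different route than per-codon lookup.  Returns None when the
    variant is out of the gene's reach.
    """
    seq = reference[gene.chrom]
    in_cds = any(s <= pos0 < e for s, e in gene.cds)
    if in_cds:
        cds_seq = "".join(seq[s:e] for s, e in gene.cds)
        offsets = [i for s, e in gene.cds for i in range(s, e)]
        idx = offsets.index(pos0)
        assert cds_seq[idx].upper() == ref_base
        mutated = cds_seq[:idx] + alt_base + cds_seq[idx + 1:]
        if gene.strand == "-":
            prot_ref = str(Seq(cds_seq).reverse_complement().translate())
            prot_alt = str(Seq(mutated).reverse_complement().translate())
        else:
            prot_ref = str(Seq(cds_seq).translate())
            prot_alt = str(Seq(mutated).translate())
        return ("coding_synonymous" if prot_ref == prot_alt
                else "coding_nonsynonymous")
    if gene.start <= pos0 < gene.end:
        if not any(s <= pos0 < e for s, e in gene.exons):
            # nearest intron-facing exon edge
            dists = []
            for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
                if e1 <= pos0 < s2:
                    dists = [pos0 - e1, s2 - 1 - pos0]
            if dists and min(dists) < splice_bp:
                return "splicing"
            return "intron"
        if any(s <= pos0 < e for s, e in gene.utr5):
            return "utr5"
        if any(s <= pos0 < e for s, e in gene.utr3):
            return "utr3"
        return "intron"
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
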