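"""Population-structure analyses: IBS distances, NJ tree, PCA, LD decay.

These mirror the standard toolbox applied to two-population
resequencing cohorts: an identity-by-state distance matrix feeding a
neighbor-joining tree, a genotype PCA on standardized allele dosages
with per-component variance explained, and the decay of pairwise r²
with physical distance.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Identity-by-state dissimilarity between all sample pairs.

    ``d(i, j)`` is the mean over co-called sites of ``|dosage_i -
    dosage_j| / 2``: 0 for identical genotypes everywhere, 1 for
    opposite homozygotes everywhere.  A pair with no co-called site is
    an error.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    dos = g.dosages.astype(float)
    called = g.dosages != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(
                    f"samples {g.sample_ids[i]} and {g.sample_ids[j]} share "
                    "no co-called sites")
            d[i, j] = d[j, i] = np.abs(
                dos[i, both] - dos[j, both]).mean() / 2.0
    return DistanceMatrix(list(g.sample_ids), d)


def write_phylip(dist: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.labels)}\n")
        for label, row in zip(dist.labels, dist.d):
            name = f"{label[:10]:<10}"
            fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Classic Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing the Q-criterion (ties broken
    by lexicographic label order), computes branch lengths from the
    standard formulas, and finishes with the three-point formulas when
    three nodes remain, yielding an unrooted tree represented with a
    trifurcating root.  Negative branch-length estimates are clamped to
    zero with the deficit moved to the sibling edge.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dist.d.astype(float).copy()
    nodes = [TreeNode(name=label) for label in dist.labels]
    # sort keys: lexicographic; a merged node inherits its smallest key
    keys = [str(label) for label in dist.labels]

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[3]):
                    best = (q, i, j, key)
        _, i, j, _ = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        parent = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # three-point formulas for the final trifurcation
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def is_monophyletic(tree: TreeNode, leaf_names: set[str]) -> bool:
    """True when some edge of the (unrooted) tree splits ``leaf_names``
    exactly from the remaining tips."""
    all_tips = {t.name for t in tree.tips()}
    target = set(leaf_names)
    if not target or not target <= all_tips:
        return False
    if target == all_tips:
        return True
    for node in tree.non_tips(include_self=True):
        for child in node.children:
            clade = ({child.name} if child.is_tip()
                     else {t.name for t in child.tips()})
            if clade == target or all_tips - clade == target:
                return True
    return False


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(g: GenotypeMatrix, n_components: int = 10,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of standardized genotype dosages.

    Each site is centered by ``2 p̂`` and scaled by ``sqrt(2 p̂ (1 -
    p̂))`` (p̂ the sample ALT frequency); missing entries are imputed to
    the site mean (hence zero after centering).  Eigendecomposition of
    the sample-by-sample covariance gives coordinates ``eigvec_k *
    sqrt(λ_k)`` and ``variance_explained = λ / Σλ`` over all
    components.  Sign convention: first nonzero loading of each
    component is positive.

    Returns ``(coordinates (n_samples, n_components), variance_explained
    (n_samples,))``; ``variance_explained`` sums to 1.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    d = g.dosages.astype(float)
    d[g.dosages == MISSING] = np.nan
    p_hat = np.nanmean(d, axis=0) / 2.0
    keep = ~np.isnan(p_hat) & (p_hat > 0) & (p_hat < 1)
    if not keep.any():
        raise ValueError("no polymorphic sites for PCA")
    d = d[:, keep]
    p = p_hat[keep]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    z[np.isnan(z)] = 0.0  # mean imputation after standardization
    cov = z @ z.T / z.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if len(nz) and col[nz[0]] < 0:
            eigvec[:, k] = -col
    total = eigval.sum()
    var_explained = eigval / total if total > 0 else eigval
    n_components = min(n_components, eigvec.shape[1])
    coords = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])
    return coords, var_explained


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def ld_decay(g: GenotypeMatrix, population: str | None = None,
             max_dist: int = 300_000, bin_width: int = 500) -> pd.DataFrame:
    """Mean r² between site pairs as a function of physical distance.

    For every intra-chromosomal pair separated by at most ``max_dist``
    bp, the squared Pearson correlation of dosages is computed over
    co-called samples and averaged within ``bin_width``-bp distance
    bins.  Returns ``bin_start, bin_end, mean_r2, n_pairs`` (empty bins
    have count 0 and NaN mean).
    """
    sub = g if population is None else g.take_samples(g.pop_mask(population))
    d = sub.dosages.astype(float)
    d[sub.dosages == MISSING] = np.nan
    chroms = sub.sites["chrom"].to_numpy()
    pos = sub.sites["pos"].to_numpy()

    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero(chroms == chrom)
        p = pos[sel]
        X = d[:, sel]
        for ii in range(len(sel) - 1):
            hi = np.searchsorted(p, p[ii] + max_dist, "right")
            if hi <= ii + 1:
                continue
            x = X[:, ii][:, None]
            Y = X[:, ii + 1:hi]
            mask = ~np.isnan(x) & ~np.isnan(Y)
            n = mask.sum(axis=0)
            xm = np.where(mask, x, 0.0)
            ym = np.where(mask, Y, 0.0)
            sx = xm.sum(axis=0)
            sy = ym.sum(axis=0)
            sxy = (xm * ym).sum(axis=0)
            sxx = (xm ** 2).sum(axis=0)
            syy = (ym ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                num = n * sxy - sx * sy
                den = (n * sxx - sx ** 2) * (n * syy - sy ** 2)
                r2 = num ** 2 / den
            ok = (n >= 2) & (den > 0)
            dists = p[ii + 1:hi] - p[ii]
            bins = np.minimum((dists - 1) // bin_width, n_bins - 1)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)
    edges = np.arange(n_bins + 1) * bin_width
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:],
        "mean_r2": mean_r2, "n_pairs": counts,
    })
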