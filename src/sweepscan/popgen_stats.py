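"""Sliding-window population-genetic statistics.

Implements the window grid (100-kb windows sliding in 10-kb steps by
default), per-site and per-window nucleotide diversity π, Watterson's
θ, the Weir–Cockerham variance-component F_ST estimator (ratio of
averages over window sites) with a Hudson-style alternative, and the
π-ratio (wild π over domestic π) used by the sweep scan.

Coordinates: windows are 0-based half-open; site positions are 1-based
(VCF convention), so a site at position ``pos`` falls in window
``[start, end)`` iff ``start <= pos - 1 < end``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

WINDOW_SIZE = 100_000
STEP_SIZE = 10_000
MIN_SNVS = 10


# ---------------------------------------------------------------------------
# window grid
# ---------------------------------------------------------------------------

def make_windows(chrom_lengths: dict[str, int],
                 window_size: int = WINDOW_SIZE,
                 step_size: int = STEP_SIZE) -> pd.DataFrame:
    """Sliding-window grid over the genome.

    Full windows ``[k*step, k*step + window_size)`` are emitted while
    they fit inside the chromosome.  One trailing partial window is
    appended when the remaining span is at least half a window (flagged
    ``partial``); a chromosome shorter than one window yields a single
    partial window with a warning.
    """
    if not (1 <= step_size <= window_size):
        raise ValueError("need window_size >= step_size >= 1")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < window_size:
            logger.warning("%s shorter than one window (%d < %d): single "
                           "partial window", chrom, length, window_size)
            rows.append((chrom, 0, length, True))
            continue
        n_full = (length - window_size) // step_size + 1
        for k in range(n_full):
            start = k * step_size
            rows.append((chrom, start, start + window_size, False))
        tail_start = n_full * step_size
        if tail_start < length and length - tail_start >= window_size // 2:
            rows.append((chrom, tail_start, length, True))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def site_pi(dosages: np.ndarray) -> float:
    """Unbiased per-site heterozygosity for one population at one site.

    ``2 * c_ref * c_alt / (c * (c - 1))`` over called alleles; 0 when
    fewer than two alleles are called.
    """
    dosages = np.asarray(dosages)
    called = dosages != MISSING
    c = 2 * int(called.sum())
    if c < 2:
        return 0.0
    c_alt = int(dosages[called].sum())
    c_ref = c - c_alt
    return 2.0 * c_ref * c_alt / (c * (c - 1))


def per_site_pi(g: GenotypeMatrix, pop: str) -> np.ndarray:
    """Vectorized :func:`site_pi` across all sites for one population."""
    alt, total = g.allele_counts(pop)
    ref = total - alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * ref * alt / (total * (total - 1.0))
    return np.where(total >= 2, pi, 0.0)


def wc_fst_components(dosages_pop1: np.ndarray, dosages_pop2: np.ndarray,
                      ) -> tuple[float, float, float]:
    """Weir–Cockerham variance components (a, b, c) at one biallelic site.

    ``a`` is the among-population component, ``b`` among individuals
    within populations, ``c`` within individuals; the per-site estimate
    is ``a / (a + b + c)`` and windows combine components as ratios of
    sums.  Requires at least one fully called diploid per population.
    """
    stats = []
    for d in (np.asarray(dosages_pop1), np.asarray(dosages_pop2)):
        called = d != MISSING
        n = int(called.sum())
        if n < 1:
            raise ValueError("population with no called genotypes")
        dc = d[called]
        p = dc.sum() / (2.0 * n)
        h = float((dc == 1).mean())
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    a, b, c = _wc_abc(np.array([float(n1)]), np.array([p1]),
                      np.array([h1]), np.array([float(n2)]),
                      np.array([p2]), np.array([h2]))
    return float(a[0]), float(b[0]), float(c[0])


def _wc_abc(n1, p1, h1, n2, p2, h2):
    """Vectorized Weir–Cockerham components for two populations (r = 2)."""
    n_bar = (n1 + n2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = 2.0 * n_bar - (n1 ** 2 + n2 ** 2) / (2.0 * n_bar)
        p_bar = (n1 * p1 + n2 * p2) / (2.0 * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / (2.0 * n_bar)
        inner = p_bar * (1 - p_bar) - s2 / 2.0 - h_bar / 4.0
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - s2 / 2.0
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    return a, b, c


def _pop_site_stats(g: GenotypeMatrix, pop: str):
    """(n called diploids, ALT freq, observed het fraction) per site."""
    d = g.dosages[g.pop_mask(pop)]
    called = d != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, (d == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def per_site_wc(g: GenotypeMatrix, pop1: str, pop2: str):
    """Per-site WC numerator ``a`` and denominator ``a+b+c`` plus a
    usability mask (sites needing >= 1 called diploid per population and
    a combined sample allowing the n-1 correction)."""
    n1, p1, h1 = _pop_site_stats(g, pop1)
    n2, p2, h2 = _pop_site_stats(g, pop2)
    usable = (n1 >= 1) & (n2 >= 1) & ((n1 + n2) / 2.0 > 1.0)
    a, b, c = _wc_abc(n1, p1, h1, n2, p2, h2)
    a = np.where(usable, np.nan_to_num(a, nan=0.0), 0.0)
    b = np.where(usable, np.nan_to_num(b, nan=0.0), 0.0)
    c = np.where(usable, np.nan_to_num(c, nan=0.0), 0.0)
    return a, a + b + c, usable


def per_site_hudson(g: GenotypeMatrix, pop1: str, pop2: str):
    """Hudson F_ST per-site numerator/denominator (ratio-of-averages form).

    Numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` with
    ``n`` counted in alleles, denominator ``p1(1-p2) + p2(1-p1)``; this
    is ``between-pop heterozygosity - unbiased within-pop
    heterozygosity`` over ``between-pop heterozygosity``.
    """
    a1, t1 = g.allele_counts(pop1)
    a2, t2 = g.allele_counts(pop2)
    usable = (t1 >= 2) & (t2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / np.maximum(t1, 1)
        p2 = a2 / np.maximum(t2, 1)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(t1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(t2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    return num, den, usable


# ---------------------------------------------------------------------------
# window aggregation
# ---------------------------------------------------------------------------

def _window_slices(g: GenotypeMatrix, grid: pd.DataFrame):
    """(lo, hi, site_index) per grid row: half-open slice bounds into the
    chromosome-local sorted site arrays."""
    chroms = g.sites["chrom"].to_numpy()
    pos0 = g.sites["pos"].to_numpy() - 1
    lo = np.zeros(len(grid), dtype=np.int64)
    hi = np.zeros(len(grid), dtype=np.int64)
    offset = np.zeros(len(grid), dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        idx = np.flatnonzero(sel)
        p = pos0[idx]
        rows = grid.index[grid["chrom"] == chrom]
        if len(rows) == 0:
            continue
        starts = grid.loc[rows, "start"].to_numpy()
        ends = grid.loc[rows, "end"].to_numpy()
        lo[rows] = np.searchsorted(p, starts, "left")
        hi[rows] = np.searchsorted(p, ends, "left")
        offset[rows] = idx[0] if len(idx) else 0
    return lo, hi, offset


def _window_sums(values: np.ndarray, g: GenotypeMatrix,
                 grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-window sum of per-site values and per-window site counts."""
    chroms = g.sites["chrom"].to_numpy()
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=np.int64)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        vals = values[sel]
        p = g.sites.loc[sel, "pos"].to_numpy() - 1
        cum = np.concatenate([[0.0], np.cumsum(vals)])
        rows = grid.index[grid["chrom"] == chrom].to_numpy()
        if len(rows) == 0:
            continue
        lo = np.searchsorted(p, grid.loc[rows, "start"].to_numpy(), "left")
        hi = np.searchsorted(p, grid.loc[rows, "end"].to_numpy(), "left")
        sums[rows] = cum[hi] - cum[lo]
        counts[rows] = hi - lo
    return sums, counts


def window_pi(g: GenotypeMatrix, pop: str, grid: pd.DataFrame,
              per_variant: bool = False) -> np.ndarray:
    """Per-window π: sum of per-site π over window span in bp.

    With ``per_variant=True`` the sum is divided by the number of SNVs
    in the window instead of the span.
    """
    pi = per_site_pi(g, pop)
    sums, counts = _window_sums(pi, g, grid)
    span = (grid["end"] - grid["start"]).to_numpy(dtype=float)
    if per_variant:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return sums / span


def watterson_theta(g: GenotypeMatrix, pop: str,
                    grid: pd.DataFrame) -> np.ndarray:
    """Per-window Watterson's θ per bp.

    ``S / (a_n * span)`` with ``S`` the count of sites segregating in
    the population and ``a_n`` the harmonic number for the window's
    median called allele count.
    """
    alt, total = g.allele_counts(pop)
    seg = ((alt > 0) & (alt < total)).astype(float)
    S, _ = _window_sums(seg, g, grid)

    chroms = g.sites["chrom"].to_numpy()
    theta = np.zeros(len(grid))
    span = (grid["end"] - grid["start"]).to_numpy(dtype=float)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        tot = total[sel]
        p = g.sites.loc[sel, "pos"].to_numpy() - 1
        rows = grid.index[grid["chrom"] == chrom].to_numpy()
        if len(rows) == 0:
            continue
        lo = np.searchsorted(p, grid.loc[rows, "start"].to_numpy(), "left")
        hi = np.searchsorted(p, grid.loc[rows, "end"].to_numpy(), "left")
        for r, l, h in zip(rows, lo, hi):
            if h > l:
                n_alleles = int(np.median(tot[l:h]))
                if n_alleles >= 2:
                    a_n = np.sum(1.0 / np.arange(1, n_alleles))
                    theta[r] = S[r] / (a_n * span[r])
    return theta


def window_fst(g: GenotypeMatrix, grid: pd.DataFrame, pop1: str, pop2: str,
               estimator: str = "wc") -> tuple[np.ndarray, np.ndarray]:
    """Per-window F_ST (ratio of per-site component sums) and the count
    of usable sites per window.

    ``estimator`` is ``"wc"`` (Weir–Cockerham, default) or ``"hudson"``.
    Windows whose denominator vanishes get NaN.
    """
    if estimator == "wc":
        num, den, usable = per_site_wc(g, pop1, pop2)
    elif estimator == "hudson":
        num, den, usable = per_site_hudson(g, pop1, pop2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    num_sum, _ = _window_sums(num, g, grid)
    den_sum, _ = _window_sums(den, g, grid)
    n_usable, _ = _window_sums(usable.astype(float), g, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den_sum != 0.0, num_sum / np.where(den_sum == 0, 1, den_sum), np.nan)
    return fst, n_usable.astype(np.int64)


def pi_ratio(pi_pop1: np.ndarray, pi_pop2: np.ndarray) -> np.ndarray:
    """π-ratio = wild π (pop2) over domestic π (pop1).

    Diversity loss in the domestic population inflates the ratio.
    ``pi_pop1 == 0`` with ``pi_pop2 > 0`` gives +inf (kept; sorts above
    any finite value); 0/0 gives NaN (invalid window).
    """
    pi_pop1 = np.asarray(pi_pop1, dtype=float)
    pi_pop2 = np.asarray(pi_pop2, dtype=float)
    out = np.full(pi_pop1.shape, np.nan)
    pos = pi_pop1 > 0
    out[pos] = pi_pop2[pos] / pi_pop1[pos]
    inf = (pi_pop1 == 0) & (pi_pop2 > 0)
    out[inf] = np.inf
    return out


def window_statistics(g: GenotypeMatrix, grid: pd.DataFrame,
                      pop1: str | None = None, pop2: str | None = None,
                      estimator: str = "wc",
                      min_snvs: int = MIN_SNVS) -> pd.DataFrame:
    """Full per-window statistics table for the sweep scan.

    ``pop1`` is the focal (domestic) population whose diversity loss is
    scanned for, ``pop2`` the reference (wild) population; they default
    to the first and second population labels of the matrix.  A window
    is ``valid`` when it is a full window with at least ``min_snvs``
    SNVs and a defined F_ST.
    """
    labels = g.pop_labels()
    if pop1 is None or pop2 is None:
        if len(labels) != 2:
            raise ValueError("need exactly two populations or explicit labels")
        pop1 = pop1 or labels[0]
        pop2 = pop2 or labels[1]
    pi1 = window_pi(g, pop1, grid)
    pi2 = window_pi(g, pop2, grid)
    fst, _ = window_fst(g, grid, pop1, pop2, estimator)
    _, n_snvs = _window_sums(np.ones(g.n_sites), g, grid)
    ratio = pi_ratio(pi1, pi2)
    valid = ((~grid["partial"].to_numpy())
             & (n_snvs >= min_snvs)
             & ~np.isnan(fst)
             & ~np.isnan(ratio))
    out = grid.copy()
    out["n_snvs"] = n_snvs
    out["pi_pop1"] = pi1
    out["pi_pop2"] = pi2
    out["pi_ratio"] = ratio
    out["fst"] = fst
    out["valid"] = valid
    return out
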