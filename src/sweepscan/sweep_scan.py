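"""Joint top-1% selection scan and region summaries.

Candidate sweep windows are those simultaneously in the upper empirical
tail (default 1%) of both the F_ST distribution and the π-ratio
distribution over valid windows — an intersection, not a union.
Selected windows are merged into maximal overlapping/book-ended runs,
annotated with overlapping genes and BED features, and scored against
planted-sweep truth when available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ScanThresholds:
    """Empirical upper-quantile thresholds of the two scan statistics."""

    fst_threshold: float
    ratio_threshold: float
    q: float


def empirical_threshold(values, q: float = 0.01) -> float:
    """Nearest-rank upper-quantile threshold.

    Sort descending and return the value at rank ``ceil(q * N)``; the
    selection rule downstream is ``value >= threshold``.  Infinities
    rank above every finite value; NaNs are excluded.
    """
    if not (0.0 < q < 0.5):
        raise ValueError("q must lie in (0, 0.5)")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no values to threshold")
    if len(vals) < 1.0 / q:
        logger.warning("empirical_threshold: only %d values for q=%g "
                       "(fewer than 1/q)", len(vals), q)
    if np.all(vals == vals[0]):
        logger.warning("empirical_threshold: all values equal; every "
                       "window will be selected")
    rank = math.ceil(q * len(vals))
    return float(np.sort(vals)[::-1][rank - 1])


def compute_thresholds(stats: pd.DataFrame, q: float = 0.01) -> ScanThresholds:
    """Top-``q`` thresholds of F_ST and π-ratio over valid windows."""
    valid = stats[stats["valid"]]
    if valid.empty:
        raise ValueError("no valid windows")
    return ScanThresholds(
        fst_threshold=empirical_threshold(valid["fst"], q),
        ratio_threshold=empirical_threshold(valid["pi_ratio"], q),
        q=q,
    )


def select_windows(stats: pd.DataFrame,
                   thresholds: ScanThresholds) -> pd.DataFrame:
    """Windows meeting BOTH thresholds; invalid windows never selected."""
    mask = (stats["valid"]
            & (stats["fst"] >= thresholds.fst_threshold)
            & (stats["pi_ratio"] >= thresholds.ratio_threshold))
    return stats[mask].copy()


def merge_regions(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended selected windows per chromosome.

    Region statistics are the max over member windows.  Returns a
    DataFrame ``chrom, start, end, n_windows, max_fst, max_ratio``
    sorted by (chrom, start) with pairwise-disjoint regions.
    """
    cols = ["chrom", "start", "end", "n_windows", "max_fst", "max_ratio"]
    if selected.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    ordered = selected.sort_values(["chrom", "start"])
    for chrom, group in ordered.groupby("chrom", sort=True):
        cur = None
        for _, w in group.iterrows():
            if cur is not None and w["start"] <= cur["end"]:
                cur["end"] = max(cur["end"], w["end"])
                cur["n_windows"] += 1
                cur["max_fst"] = max(cur["max_fst"], w["fst"])
                cur["max_ratio"] = max(cur["max_ratio"], w["pi_ratio"])
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(w["start"]),
                       "end": int(w["end"]), "n_windows": 1,
                       "max_fst": w["fst"], "max_ratio": w["pi_ratio"]}
        rows.append(cur)
    return pd.DataFrame(rows, columns=cols)


def genes_in_regions(regions: pd.DataFrame, genes: list,
                     full_containment: bool = False,
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Overlay gene models on regions (any-overlap by default).

    Returns the regions table with a ``genes`` column (comma-joined
    gene ids) and the deduplicated genome-wide list of hit genes.
    """
    out = regions.copy()
    per_region: list[str] = []
    all_genes: dict[str, None] = {}
    for _, r in regions.iterrows():
        hits = []
        for g in genes:
            if g.chrom != r["chrom"]:
                continue
            if full_containment:
                ok = r["start"] <= g.start and g.end <= r["end"]
            else:
                ok = g.start < r["end"] and r["start"] < g.end
            if ok:
                hits.append(g.gene_id)
                all_genes.setdefault(g.gene_id, None)
        per_region.append(",".join(hits))
    out["genes"] = per_region
    return out, list(all_genes)


def read_bed(path: Path | str) -> pd.DataFrame:
    """Read a BED file (0-based half-open) with an optional name column."""
    rows = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed BED line") from exc
            name = parts[3] if len(parts) > 3 else "feature"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def feature_overlap(regions: pd.DataFrame,
                    features: pd.DataFrame) -> pd.DataFrame:
    """Per-class counts of features overlapping any detected region.

    Percentages are shares of all overlapping features, emulating a
    QTL-class overlap table.  ``features`` is a BED-style DataFrame
    (``chrom, start, end, name``) with the class label in ``name``.
    """
    if features.empty:
        return pd.DataFrame(columns=["class", "n_overlapping", "percent"])
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, r in regions.iterrows():
        by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"]))
    counts: dict[str, int] = {}
    for _, f in features.iterrows():
        hit = any(f["start"] < e and s < f["end"]
                  for s, e in by_chrom.get(f["chrom"], []))
        if hit:
            counts[f["name"]] = counts.get(f["name"], 0) + 1
    total = sum(counts.values())
    rows = [(cls, n, 100.0 * n / total) for cls, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["class", "n_overlapping", "percent"])


# ---------------------------------------------------------------------------
# recovery scoring against planted truth
# ---------------------------------------------------------------------------

def _merge_intervals(ivals):
    merged = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _intersection_bp(a, b):
    """Total overlap of two merged interval lists on one chromosome."""
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def score_recovery(regions: pd.DataFrame,
                   truth_intervals: list[tuple[str, int, int]]) -> dict:
    """Base-pair precision/recall/Jaccard and interval-level recall.

    A planted sweep counts as recovered when at least half its span is
    covered by detected regions.  With no detections, precision is
    reported as 0 with ``no_detections`` set.
    """
    det: dict[str, list] = {}
    for _, r in regions.iterrows():
        det.setdefault(r["chrom"], []).append((int(r["start"]), int(r["end"])))
    det = {c: _merge_intervals(v) for c, v in det.items()}
    tru: dict[str, list] = {}
    for chrom, s, e in truth_intervals:
        tru.setdefault(chrom, []).append((s, e))
    tru = {c: _merge_intervals(v) for c, v in tru.items()}

    det_bp = sum(e - s for v in det.values() for s, e in v)
    tru_bp = sum(e - s for v in tru.values() for s, e in v)
    inter_bp = sum(_intersection_bp(det.get(c, []), tru.get(c, []))
                   for c in set(det) | set(tru))
    union_bp = det_bp + tru_bp - inter_bp

    recovered = 0
    for chrom, s, e in truth_intervals:
        cov = _intersection_bp(det.get(chrom, []), [[s, e]])
        if cov >= 0.5 * (e - s):
            recovered += 1

    no_detections = det_bp == 0
    return {
        "precision": 0.0 if no_detections else inter_bp / det_bp,
        "recall": inter_bp / tru_bp if tru_bp else 0.0,
        "jaccard": inter_bp / union_bp if union_bp else 0.0,
        "interval_recall": (recovered / len(truth_intervals)
                            if truth_intervals else 0.0),
        "no_detections": no_detections,
    }


def scan_summary(stats: pd.DataFrame, selected: pd.DataFrame,
                 regions: pd.DataFrame,
                 thresholds: ScanThresholds) -> dict:
    """Headline numbers of a scan: counts, spans, thresholds."""
    span_bp = int((regions["end"] - regions["start"]).sum()) if len(regions) else 0
    return {
        "n_windows": int(len(stats)),
        "n_valid_windows": int(stats["valid"].sum()),
        "fst_threshold": thresholds.fst_threshold,
        "ratio_threshold": thresholds.ratio_threshold,
        "q": thresholds.q,
        "n_selected_windows": int(len(selected)),
        "n_regions": int(len(regions)),
        "total_region_bp": span_bp,
        "mean_snvs_per_selected_window": (
            float(selected["n_snvs"].mean()) if len(selected) else 0.0),
    }
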