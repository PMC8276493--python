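"""varLD: contrasting LD structure between two populations.

For every window of ``window_snps`` consecutive SNPs (step one SNP) the
pairwise r-squared matrix of genotype dosages is computed in each
population; the raw varLD score of the window is the summed absolute
difference of the two descending-sorted eigenvalue spectra.  Raw scores
are standardized per chromosome (mean 0, sd 1, sample sd with n-1), and
windows at or above a genome-wide percentile of the standardized score
are *relevant*.  Three comparisons drive the biology: regions relevant
in both Base-High and Base-Low are putative signatures of selection;
regions relevant only in High-Low are attributed to drift.

r-squared is the squared Pearson correlation of unphased dosage vectors
(the composite-LD convention for unphased array data); a monomorphic SNP
contributes zero off-diagonal correlation so that windows stay aligned
across populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genio import GenotypeMatrix, MISSING
from .intervals import Interval, intersect, merge_intervals, overlaps_any

log = logging.getLogger(__name__)

BASE_HIGH, BASE_LOW, HIGH_LOW = "BASE_HIGH", "BASE_LOW", "HIGH_LOW"
COMPARISONS = (BASE_HIGH, BASE_LOW, HIGH_LOW)


@dataclass
class VarLDWindow:
    chrom: str
    start_bp: int      # position of first SNP in window
    end_bp: int        # position of last SNP in window
    first_snp_index: int
    raw_score: float
    std_score: float = np.nan

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start_bp, self.end_bp)


# ---------------------------------------------------------------------------
# r-squared matrices
# ---------------------------------------------------------------------------

def _corr_matrix(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between SNP dosage columns (samples x SNPs),
    pairwise-complete over missing entries; zero-variance SNPs get zero
    off-diagonal correlation and a unit diagonal."""
    v = values.astype(float)
    mask = values != MISSING
    if mask.all():
        sd = v.std(axis=0)
        ok = sd > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.corrcoef(v, rowvar=False)
        r[~ok, :] = 0.0
        r[:, ~ok] = 0.0
        np.fill_diagonal(r, 1.0)
        return r
    # pairwise-complete: masked covariance
    v = np.where(mask, v, 0.0)
    m = mask.astype(float)
    n = m.T @ m                        # pairwise sample counts
    s = v.T @ m                        # sum of x over pairwise-complete rows
    sxy = v.T @ v
    sxx = (v * v).T @ m
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_x = s / n
        cov = sxy / n - mean_x * mean_x.T
        var_x = sxx / n - mean_x ** 2
        var_y = sxx.T / n - mean_x.T ** 2
        r = cov / np.sqrt(var_x * var_y)
    r[~np.isfinite(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def r2_matrix(g: GenotypeMatrix, samples: Sequence[str],
              snp_slice: slice | None = None) -> np.ndarray:
    """Pairwise r-squared matrix for a window of SNPs in one population."""
    if len(list(samples)) < 2:
        raise ValueError("need at least 2 samples for r2")
    sub = g.subset_samples(samples)
    v = sub.values if snp_slice is None else sub.values[:, snp_slice]
    return _corr_matrix(v) ** 2


def varld_raw_score(m1: np.ndarray, m2: np.ndarray) -> float:
    """Summed absolute difference of descending-sorted eigenvalues."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and of equal dimension")
    e1 = np.sort(np.linalg.eigvalsh(m1))[::-1]
    e2 = np.sort(np.linalg.eigvalsh(m2))[::-1]
    return float(np.abs(e1 - e2).sum())


# ---------------------------------------------------------------------------
# windowed scores
# ---------------------------------------------------------------------------

def varld_scores(g: GenotypeMatrix, samples1: Sequence[str], samples2: Sequence[str],
                 window_snps: int = 50) -> list[VarLDWindow]:
    """Raw varLD scores for all full windows of ``window_snps`` SNPs,
    advancing one SNP at a time, chromosome by chromosome.  Trailing
    windows with fewer SNPs are dropped."""
    out: list[VarLDWindow] = []
    for chrom, sl in g.markers.chrom_slices().items():
        n = sl.stop - sl.start
        if n < window_snps:
            log.debug("chromosome %s: %d SNPs < window of %d; skipped",
                      chrom, n, window_snps)
            continue
        r2_full_1 = r2_matrix(g, samples1, sl)
        r2_full_2 = r2_matrix(g, samples2, sl)
        pos = g.markers.pos_bp[sl]
        for j in range(n - window_snps + 1):
            w = slice(j, j + window_snps)
            score = varld_raw_score(r2_full_1[w, w], r2_full_2[w, w])
            out.append(VarLDWindow(chrom, int(pos[j]), int(pos[j + window_snps - 1]),
                                   sl.start + j, score))
    return out


def standardize_scores(windows: Sequence[VarLDWindow], ddof: int = 1) -> list[VarLDWindow]:
    """Standardize raw scores per chromosome: (raw - mean) / sd.

    Sample standard deviation (n-1) by default.  If all raw scores on a
    chromosome coincide the standardized scores are set to 0 with a
    warning.  Returns the same window objects with std_score filled in.
    """
    by_chrom: dict[str, list[VarLDWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        raw = np.array([w.raw_score for w in ws])
        if len(raw) < 2:
            raise ValueError(f"chromosome {chrom}: need >= 2 windows to standardize")
        sd = raw.std(ddof=ddof)
        if sd == 0:
            log.warning("chromosome %s: all varLD scores equal; std_score set to 0", chrom)
            for w in ws:
                w.std_score = 0.0
            continue
        mean = raw.mean()
        for w, z in zip(ws, (raw - mean) / sd):
            w.std_score = float(z)
    return list(windows)


def relevant_varld_windows(windows: Sequence[VarLDWindow],
                           percentile: float = 0.999) -> list[VarLDWindow]:
    """Windows with standardized score at or above the genome-wide
    percentile (linear interpolation, ties included)."""
    if not windows:
        raise ValueError("no windows to rank")
    z = np.array([w.std_score for w in windows])
    if np.isnan(z).any():
        raise ValueError("standardize_scores must run before relevance ranking")
    threshold = float(np.quantile(z, percentile))
    return [w for w in windows if w.std_score >= threshold]


def varld_signatures(scored: Mapping[str, Sequence[VarLDWindow]],
                     percentile: float = 0.999) -> tuple[list[Interval], list[Interval]]:
    """Three-comparison selection/drift logic.

    ``scored`` maps comparison labels (BASE_HIGH, BASE_LOW, HIGH_LOW) to
    standardized windows.  SELECTION intervals are the base-pair
    intersections of relevant Base-High and Base-Low regions (>= 1 bp
    overlap); DRIFT intervals are relevant High-Low regions overlapping
    neither relevant base comparison.  Returns (selection, drift).
    """
    missing = set(COMPARISONS) - set(scored)
    if missing:
        raise ValueError(f"missing comparisons: {sorted(missing)}")
    rel = {}
    for label in COMPARISONS:
        rel[label] = merge_intervals(
            w.interval for w in relevant_varld_windows(scored[label], percentile))
    selection = intersect(rel[BASE_HIGH], rel[BASE_LOW])
    drift = [iv for iv in rel[HIGH_LOW]
             if not overlaps_any(iv, rel[BASE_HIGH])
             and not overlaps_any(iv, rel[BASE_LOW])]
    return selection, drift


def windows_to_frame(windows: Sequence[VarLDWindow]):
    import pandas as pd

    return pd.DataFrame([{
        "chrom": w.chrom, "start_bp": w.start_bp, "end_bp": w.end_bp,
        "first_snp_index": w.first_snp_index, "raw_score": w.raw_score,
        "std_score": w.std_score,
    } for w in windows])
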