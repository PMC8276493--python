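"""Windowed Weir-Cockerham FST between two selected lines.

Per SNP the two-population (r = 2) variance components of the
Weir & Cockerham (1984) estimator are computed from per-line non-missing
sample sizes, alt-allele frequencies and observed heterozygote
fractions.  Window values are the sample-size-weighted "ratio of sums"
form sum(a) / sum(a + b + c) over the SNPs of 500-kb windows advancing in
250-kb steps.  Windows at or above a genome-wide percentile of the
weighted FST distribution are *relevant*; a relevant window counts as a
putative signature of selection only when the two lines moved the
base-population minor allele in opposite directions (the drift-versus-
selection MAF rule) — parallel or absent change is attributed to drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .genio import GenotypeMatrix, MISSING, allele_freq
from .intervals import Interval

log = logging.getLogger(__name__)


class Classification(str, Enum):
    SELECTION = "SELECTION"
    DRIFT = "DRIFT"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class WCComponents:
    """Variance components per SNP: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def theta(self) -> np.ndarray:
        """Per-SNP estimate a / (a + b + c); NaN where the denominator
        vanishes (near-monomorphic sites)."""
        denom = self.a + self.b + self.c
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom != 0, self.a / denom, np.nan)


@dataclass
class FstWindow:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    weighted_fst: float
    maf_base: float = np.nan
    maf_high: float = np.nan
    maf_low: float = np.nan
    classification: Classification = Classification.UNCLASSIFIED

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start_bp, self.end_bp)


def wc_components(n1, p1, h1, n2, p2, h2) -> WCComponents:
    """Weir-Cockerham (1984) variance components for two populations.

    Arguments are arrays (or scalars) of per-SNP diploid sample sizes,
    alt-allele frequencies and observed heterozygote fractions.  SNPs
    where the mean sample size n_bar <= 1 are returned as NaN (the
    estimator needs within-population degrees of freedom).
    """
    n1 = np.asarray(n1, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    nbar = (n1 + n2) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0)
                           / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 / 2.0
                                     - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    bad = ~(nbar > 1.0)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    c = np.where(bad, np.nan, c)
    return WCComponents(np.atleast_1d(a), np.atleast_1d(b), np.atleast_1d(c))


def _per_snp_stats(g: GenotypeMatrix, samples: Sequence[str]):
    """(n, p, h) per SNP for a cohort: non-missing diploid count,
    alt-allele frequency, observed heterozygote fraction."""
    sub = g.subset_samples(samples)
    v = sub.values
    called = v != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, np.where(called, v, 0).sum(axis=0) / (2.0 * n), np.nan)
        h = np.where(n > 0, (v == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def _window_starts(max_pos: int, window_bp: int, step_bp: int) -> np.ndarray:
    """Window start positions tiling a chromosome from position 1."""
    n = max(1, int(np.ceil((max_pos - window_bp) / step_bp)) + 1) if max_pos > window_bp else 1
    return 1 + step_bp * np.arange(n)


def windowed_fst(g: GenotypeMatrix, high_samples: Sequence[str],
                 low_samples: Sequence[str],
                 base_samples: Sequence[str] | None = None,
                 window_kb: float = 500.0, step_kb: float = 250.0,
                 min_snps: int = 10, epsilon: float = 0.01) -> list[FstWindow]:
    """Weighted FST in sliding windows between the HIGH and LOW cohorts.

    Window value = sum(a) / sum(a+b+c) over window SNPs for which both
    cohorts have data; per-SNP sample sizes reflect missingness.  Windows
    with fewer than ``min_snps`` usable SNPs, or with a vanishing
    denominator, are excluded.  When ``base_samples`` is given, each
    window also carries the mean base-minor-allele frequency in the
    three cohorts and its selection/drift classification.
    """
    if not list(high_samples) or not list(low_samples):
        raise ValueError("both cohorts must be non-empty")
    n1, p1, h1 = _per_snp_stats(g, high_samples)
    n2, p2, h2 = _per_snp_stats(g, low_samples)
    comp = wc_components(n1, p1, h1, n2, p2, h2)
    usable = (n1 >= 1) & (n2 >= 1) & ~np.isnan(comp.a)

    if base_samples is not None:
        p_base = allele_freq(g, base_samples)
        # track the base-population minor allele in all three cohorts
        flip = p_base > 0.5
        t_base = np.where(flip, 1.0 - p_base, p_base)
        t_high = np.where(flip, 1.0 - p1, p1)
        t_low = np.where(flip, 1.0 - p2, p2)
        # Re-polarize per SNP so that the base->HIGH change is
        # non-negative.  Minor/major folding is an arbitrary per-SNP
        # orientation: averaging signed changes under it cancels a true
        # divergence signal across a window.  With a consistent
        # orientation, parallel drift keeps Δ(high) and Δ(low) on the
        # same side while divergent selection drives them apart.
        flip2 = (t_high - t_base) < 0
        t_base = np.where(flip2, 1.0 - t_base, t_base)
        t_high = np.where(flip2, 1.0 - t_high, t_high)
        t_low = np.where(flip2, 1.0 - t_low, t_low)
        base_poly = (p_base > 0) & (p_base < 1)
    else:
        t_base = t_high = t_low = None
        base_poly = None

    window_bp, step_bp = int(window_kb * 1000), int(step_kb * 1000)
    windows: list[FstWindow] = []
    for chrom, sl in g.markers.chrom_slices().items():
        pos = g.markers.pos_bp[sl]
        for start in _window_starts(int(pos.max()), window_bp, step_bp):
            end = start + window_bp - 1
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            cols = np.arange(sl.start + lo, sl.start + hi)
            cols = cols[usable[cols]]
            if len(cols) < min_snps:
                continue
            denom = float((comp.a[cols] + comp.b[cols] + comp.c[cols]).sum())
            if denom == 0.0:
                continue
            w = FstWindow(chrom, int(start), int(end), len(cols),
                          float(comp.a[cols].sum()) / denom)
            if t_base is not None:
                wcols = cols[base_poly[cols] & ~np.isnan(t_high[cols])
                             & ~np.isnan(t_low[cols])]
                if len(wcols):
                    w.maf_base = float(t_base[wcols].mean())
                    w.maf_high = float(t_high[wcols].mean())
                    w.maf_low = float(t_low[wcols].mean())
                    w.classification = classify_selection_vs_drift(
                        w.maf_base, w.maf_high, w.maf_low, epsilon)
            windows.append(w)
    if not windows:
        log.warning("no eligible FST windows (min_snps=%d)", min_snps)
    return windows


def classify_selection_vs_drift(f_base: float, f_high: float, f_low: float,
                                epsilon: float = 0.01) -> Classification:
    """Drift-versus-selection rule on window-level tracked-allele
    frequencies: a window is SELECTION only when both lines changed by
    more than ``epsilon`` relative to the base population and in opposite
    directions; parallel change, or no change in either line, is DRIFT."""
    if any(np.isnan(x) for x in (f_base, f_high, f_low)):
        return Classification.UNCLASSIFIED
    dh, dl = f_high - f_base, f_low - f_base
    if abs(dh) <= epsilon or abs(dl) <= epsilon:
        return Classification.DRIFT
    if np.sign(dh) == np.sign(dl):
        return Classification.DRIFT
    return Classification.SELECTION


def relevant_windows(windows: Sequence[FstWindow],
                     percentile: float = 0.999) -> list[FstWindow]:
    """Windows with weighted FST at or above the genome-wide percentile
    (linear-interpolation definition, ties included)."""
    if not windows:
        raise ValueError("no windows to rank")
    values = np.array([w.weighted_fst for w in windows])
    threshold = float(np.quantile(values, percentile))
    return [w for w in windows if w.weighted_fst >= threshold]


def fst_signatures(windows: Sequence[FstWindow],
                   percentile: float = 0.999) -> list[Interval]:
    """Putative signatures: relevant windows classified SELECTION."""
    return [w.interval for w in relevant_windows(windows, percentile)
            if w.classification is Classification.SELECTION]


def windows_to_frame(windows: Sequence[FstWindow]):
    import pandas as pd

    return pd.DataFrame([{
        "chrom": w.chrom, "start_bp": w.start_bp, "end_bp": w.end_bp,
        "n_snps": w.n_snps, "weighted_fst": w.weighted_fst,
        "maf_base": w.maf_base, "maf_high": w.maf_high, "maf_low": w.maf_low,
        "classification": w.classification.value,
    } for w in windows])
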