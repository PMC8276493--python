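"""Runs of homozygosity: per-individual calling and per-line consensus.

The caller is the classic SNP-count scanning-window algorithm: windows of
``window_snps`` consecutive SNPs slide one SNP at a time; a window passes
when it contains at most ``max_het_in_window`` heterozygotes and at most
``max_missing_in_window`` missing calls; a homozygous SNP qualifies when
the fraction of passing windows covering it reaches
``min_hom_window_fraction``; maximal runs of qualifying SNPs (split at
gaps over ``max_gap_kb``) become ROH when they have at least
``min_snps_in_roh`` SNPs and a density of at most ``max_kb_per_snp``.
Defaults suit a livestock SNP array of roughly one SNP per 10 kb.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genio import MISSING, GenotypeMatrix, MarkerMap
from .intervals import Interval

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    window_snps: int = 50
    max_het_in_window: int = 1
    max_missing_in_window: int = 0
    min_hom_window_fraction: float = 0.05
    max_gap_kb: float = 1000.0
    min_snps_in_roh: int = 50
    max_kb_per_snp: float = 30.0
    #: ">= min_snps_in_roh" when True, strict ">" when False
    inclusive_min_snps: bool = True

    def __post_init__(self):
        if min(self.window_snps, self.max_het_in_window, self.max_missing_in_window,
               self.min_snps_in_roh) < 0 or min(self.min_hom_window_fraction,
                                                self.max_gap_kb, self.max_kb_per_snp) < 0:
            raise ValueError("ROH parameters must be non-negative")
        if self.window_snps < min(2, self.min_snps_in_roh):
            raise ValueError("window_snps too small")


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def span_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


@dataclass(frozen=True)
class ConsensusRegion:
    chrom: str
    start_bp: int
    end_bp: int
    count_high: int
    count_low: int

    @property
    def interval(self) -> Interval:
        return (self.chrom, self.start_bp, self.end_bp)


# ---------------------------------------------------------------------------
# per-individual calling
# ---------------------------------------------------------------------------

def call_roh(dosages: np.ndarray, markers: MarkerMap, params: ROHParams = ROHParams(),
             sample_id: str = "") -> list[ROHSegment]:
    """Call ROH on one individual's dosage row.

    Homozygosity is symmetric in ref/alt (dosage 0 and 2 are both
    homozygous).  Chromosomes with fewer SNPs than the window size yield
    no windows hence no ROH.  Segments are reported with the outermost
    qualifying SNP positions (1-based inclusive).
    """
    dosages = np.asarray(dosages)
    if dosages.shape != (len(markers),):
        raise ValueError("dosage row length does not match marker count")
    out: list[ROHSegment] = []
    for chrom, sl in markers.chrom_slices().items():
        d = dosages[sl]
        pos = markers.pos_bp[sl]
        out.extend(_call_roh_chrom(d, pos, chrom, params, sample_id))
    return out


def _call_roh_chrom(d: np.ndarray, pos: np.ndarray, chrom: str,
                    params: ROHParams, sample_id: str) -> list[ROHSegment]:
    n, W = len(d), params.window_snps
    if n < W:
        log.debug("chromosome %s has %d SNPs < window of %d; skipped", chrom, n, W)
        return []
    het = (d == 1).astype(np.int64)
    miss = (d == MISSING).astype(np.int64)
    hom = (d == 0) | (d == 2)

    # per-window counts via cumulative sums; window j covers SNPs [j, j+W)
    csum_het = np.concatenate(([0], np.cumsum(het)))
    csum_miss = np.concatenate(([0], np.cumsum(miss)))
    n_win = n - W + 1
    win_pass = ((csum_het[W:] - csum_het[:-W] <= params.max_het_in_window)
                & (csum_miss[W:] - csum_miss[:-W] <= params.max_missing_in_window))

    # fraction of passing windows among windows covering each SNP
    csum_pass = np.concatenate(([0], np.cumsum(win_pass)))
    i = np.arange(n)
    jlo = np.maximum(0, i - W + 1)
    jhi = np.minimum(i, n_win - 1)
    n_cover = jhi - jlo + 1
    n_passing = csum_pass[jhi + 1] - csum_pass[jlo]
    qual = hom & (miss == 0) & (n_passing / n_cover >= params.min_hom_window_fraction)

    # maximal runs of qualifying SNPs, split at large gaps
    segments = []
    idx = np.flatnonzero(qual)
    if not len(idx):
        return segments
    max_gap_bp = params.max_gap_kb * 1000.0
    breaks = np.flatnonzero((np.diff(idx) > 1)
                            | (np.diff(pos[idx]) > max_gap_bp)) + 1
    for run in np.split(idx, breaks):
        n_snps = len(run)
        ok_count = (n_snps >= params.min_snps_in_roh if params.inclusive_min_snps
                    else n_snps > params.min_snps_in_roh)
        if not ok_count:
            continue
        span_kb = (pos[run[-1]] - pos[run[0]]) / 1000.0
        if span_kb / n_snps <= params.max_kb_per_snp:
            segments.append(ROHSegment(sample_id, chrom, int(pos[run[0]]),
                                       int(pos[run[-1]]), n_snps))
    return segments


def call_roh_all(g: GenotypeMatrix, params: ROHParams = ROHParams(),
                 samples: Sequence[str] | None = None) -> list[ROHSegment]:
    """Call ROH for every (or the given) sample of a genotype matrix."""
    if samples is None:
        samples = g.sample_ids
    idx = g.sample_indices(samples)
    out: list[ROHSegment] = []
    for i, sid in zip(idx, samples):
        out.extend(call_roh(g.values[i], g.markers, params, sample_id=sid))
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_roh(segments: Iterable[ROHSegment], markers: MarkerMap,
                  min_count: int = 2,
                  line_of: Mapping[str, str] | None = None) -> list[ConsensusRegion]:
    """Overlay individual ROH into consensus regions.

    Per-SNP coverage = number of individuals with a ROH covering that
    SNP; consensus regions are maximal runs of consecutive SNPs with
    coverage >= ``min_count``, subdivided wherever the per-line coverage
    profile (count_high, count_low) changes, so every region carries
    exact per-line counts.  Downstream thresholding on these counts is
    therefore equivalent to evaluating the predicate SNP by SNP.
    """
    slices = markers.chrom_slices()
    cover = {c: np.zeros(sl.stop - sl.start, dtype=np.int64) for c, sl in slices.items()}
    cover_line = {ln: {c: np.zeros(sl.stop - sl.start, dtype=np.int64)
                       for c, sl in slices.items()} for ln in ("HIGH", "LOW")}
    for seg in segments:
        sl = slices.get(seg.chrom)
        if sl is None:
            continue
        pos = markers.pos_bp[sl]
        a = np.searchsorted(pos, seg.start_bp, side="left")
        b = np.searchsorted(pos, seg.end_bp, side="right")
        cover[seg.chrom][a:b] += 1
        line = line_of.get(seg.sample_id) if line_of else None
        if line in cover_line:
            cover_line[line][seg.chrom][a:b] += 1

    regions: list[ConsensusRegion] = []
    for chrom, sl in slices.items():
        pos = markers.pos_bp[sl]
        ok = cover[chrom] >= min_count
        idx = np.flatnonzero(ok)
        if not len(idx):
            continue
        hi_cov = cover_line["HIGH"][chrom]
        lo_cov = cover_line["LOW"][chrom]
        breaks = np.flatnonzero((np.diff(idx) > 1)
                                | (np.diff(hi_cov[idx]) != 0)
                                | (np.diff(lo_cov[idx]) != 0)) + 1
        for run in np.split(idx, breaks):
            regions.append(ConsensusRegion(chrom, int(pos[run[0]]),
                                           int(pos[run[-1]]),
                                           int(hi_cov[run[0]]), int(lo_cov[run[0]])))
    return regions


def roh_signatures(consensus: Sequence[ConsensusRegion], n_high: int, n_low: int,
                   fraction: float = 0.5,
                   thresholds: tuple[int, int] | None = None) -> list[Interval]:
    """Consensus regions present in enough animals of *both* lines.

    Thresholds default to ceil(fraction x line size); explicit absolute
    (threshold_high, threshold_low) values override, which allows
    reproducing published absolute cut-offs directly.
    """
    if thresholds is None:
        th, tl = math.ceil(fraction * n_high), math.ceil(fraction * n_low)
    else:
        th, tl = thresholds
    if th > n_high or tl > n_low:
        log.warning("ROH consensus thresholds (%d, %d) exceed line sizes (%d, %d); "
                    "no region can qualify", th, tl, n_high, n_low)
        return []
    return [r.interval for r in consensus
            if r.count_high >= th and r.count_low >= tl]
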