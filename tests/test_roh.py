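import numpy as np
import pytest

from selsig.genio import MISSING
from selsig.intervals import contains_point, merge_intervals
from selsig.roh import (ConsensusRegion, ROHParams, ROHSegment, call_roh,
                        call_roh_all, consensus_roh, roh_signatures)
from selsig.simdata import SelectedLocus, SimConfig, simulate_experiment

from conftest import make_markers


# ---------------------------------------------------------------------------
# exhaustive reference implementation of the four-step window definition
# ---------------------------------------------------------------------------

def brute_force_roh(d, pos, params, sample_id=""):
    n, W = len(d), params.window_snps
    if n < W:
        return []
    win_pass = []
    for j in range(n - W + 1):
        w = d[j:j + W]
        win_pass.append(sum(1 for x in w if x == 1) <= params.max_het_in_window
                        and sum(1 for x in w if x == MISSING) <= params.max_missing_in_window)
    qual = []
    for i in range(n):
        covering = [j for j in range(n - W + 1) if j <= i <= j + W - 1]
        frac = sum(win_pass[j] for j in covering) / len(covering)
        qual.append(d[i] in (0, 2) and frac >= params.min_hom_window_fraction)
    runs, run = [], []
    for i in range(n):
        if not qual[i]:
            if run:
                runs.append(run)
            run = []
            continue
        if run and (pos[i] - pos[run[-1]]) > params.max_gap_kb * 1000:
            runs.append(run)
            run = []
        run.append(i)
    if run:
        runs.append(run)
    out = []
    for run in runs:
        n_snps = len(run)
        if n_snps < params.min_snps_in_roh:
            continue
        span_kb = (pos[run[-1]] - pos[run[0]]) / 1000
        if span_kb / n_snps <= params.max_kb_per_snp:
            out.append(ROHSegment(sample_id, "1", int(pos[run[0]]),
                                  int(pos[run[-1]]), n_snps))
    return out


def random_chromosome(rng, n=300):
    """Heterozygous background with planted homozygous tracts and noise."""
    d = rng.integers(0, 3, size=n).astype(np.int8)
    for _ in range(rng.integers(1, 4)):
        start = rng.integers(0, n - 80)
        length = min(int(rng.integers(40, 120)), n - start)
        d[start:start + length] = rng.choice([0, 2], size=length)
    # sprinkle het / missing noise
    noise = rng.random(n)
    d[noise < 0.03] = 1
    d[(noise >= 0.03) & (noise < 0.05)] = MISSING
    pos = np.sort(rng.choice(np.arange(1, 6_000_000, 100), size=n, replace=False))
    return d, pos


class TestCallROH:
    def test_uniform_homozygous_chromosome_is_one_roh(self):
        markers = make_markers(200)
        segs = call_roh(np.zeros(200, dtype=np.int8), markers, sample_id="x")
        assert len(segs) == 1
        s = segs[0]
        assert (s.n_snps, s.start_bp, s.end_bp) == (200, markers.pos_bp[0],
                                                    markers.pos_bp[-1])

    def test_alternating_heterozygotes_yield_no_roh(self):
        d = np.zeros(200, dtype=np.int8)
        d[::2] = 1
        assert call_roh(d, make_markers(200)) == []

    def test_chromosome_shorter_than_window_yields_nothing(self):
        assert call_roh(np.zeros(10, dtype=np.int8), make_markers(10)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        d, pos = random_chromosome(rng)
        markers = make_markers(len(d))
        markers.pos_bp[:] = pos
        params = ROHParams(max_gap_kb=100.0)   # tighter gap to exercise splitting
        got = call_roh(d, markers, params, sample_id="s")
        expected = brute_force_roh(d, pos, params, sample_id="s")
        assert got == expected

    def test_invariant_under_allele_relabeling(self, rng):
        d, pos = random_chromosome(rng)
        markers = make_markers(len(d))
        markers.pos_bp[:] = pos
        flipped = np.where(d == MISSING, MISSING, 2 - d).astype(np.int8)
        assert call_roh(d, markers) == call_roh(flipped, markers)

    def test_segments_respect_their_own_invariants(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            d, pos = random_chromosome(r)
            markers = make_markers(len(d))
            markers.pos_bp[:] = pos
            for s in call_roh(d, markers, ROHParams()):
                assert s.start_bp <= s.end_bp
                assert s.n_snps >= 50
                assert s.span_kb / s.n_snps <= 30


class TestConsensus:
    def make_seg(self, sid, start, end, n):
        return ROHSegment(sid, "1", start, end, n)

    def test_single_individual_below_min_count_is_empty(self):
        markers = make_markers(100)
        segs = [self.make_seg("a", 10_000, 500_000, 50)]
        assert consensus_roh(segs, markers, min_count=2) == []

    def test_two_identical_sets_reproduce_the_segment(self):
        markers = make_markers(100)
        segs = [self.make_seg("a", 110_000, 600_000, 50),
                self.make_seg("b", 110_000, 600_000, 50)]
        line_of = {"a": "HIGH", "b": "LOW"}
        regions = consensus_roh(segs, markers, 2, line_of)
        assert regions == [ConsensusRegion("1", 110_000, 600_000, 1, 1)]

    def test_matches_per_snp_counting_oracle(self, rng):
        markers = make_markers(150)
        pos = markers.pos_bp
        segs, line_of = [], {}
        for i in range(12):
            sid = f"s{i}"
            line_of[sid] = "HIGH" if i % 2 else "LOW"
            a, b = sorted(rng.integers(0, 150, size=2))
            segs.append(self.make_seg(sid, int(pos[a]), int(pos[b]), b - a + 1))
        regions = consensus_roh(segs, markers, 3, line_of)
        # oracle: per-SNP counts, runs with constant line profile
        cov = np.zeros(150, int)
        ch = np.zeros(150, int)
        cl = np.zeros(150, int)
        for s in segs:
            m = (pos >= s.start_bp) & (pos <= s.end_bp)
            cov[m] += 1
            (ch if line_of[s.sample_id] == "HIGH" else cl)[m] += 1
        expected = []
        run = []
        for i in range(151):
            open_ok = i < 150 and cov[i] >= 3
            if run and (not open_ok or ch[i] != ch[run[-1]] or cl[i] != cl[run[-1]]
                        or i != run[-1] + 1):
                expected.append(ConsensusRegion("1", int(pos[run[0]]), int(pos[run[-1]]),
                                                int(ch[run[0]]), int(cl[run[0]])))
                run = []
            if open_ok:
                run.append(i)
        assert regions == expected


class TestROHSignatures:
    def region(self, ch, cl):
        return ConsensusRegion("1", 1000, 2000, ch, cl)

    def test_absolute_thresholds_at_published_values(self):
        qualifying = self.region(70, 65)
        failing = self.region(70, 0)
        out = roh_signatures([qualifying, failing], n_high=139, n_low=135,
                             thresholds=(70, 65))
        assert out == [qualifying.interval]

    def test_fractional_thresholds_match_predicate(self, rng):
        regions = [self.region(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
                   for _ in range(50)]
        out = roh_signatures(regions, n_high=20, n_low=18, fraction=0.5)
        expected = [r.interval for r in regions
                    if r.count_high >= 10 and r.count_low >= 9]
        assert out == expected

    def test_thresholds_beyond_line_sizes_give_empty(self):
        assert roh_signatures([self.region(5, 5)], 4, 4, thresholds=(5, 5)) == []


class TestPlantedTractRecovery:
    def test_shared_hard_sweep_creates_consensus_signature(self):
        """A strongly selected allele carried on few founder haplotypes and
        favored in both lines should leave a long homozygous tract in most
        animals of both lines; whenever it nearly fixes in both lines, the
        ROH signature scan recovers an interval overlapping the locus."""
        loci = (SelectedLocus("1", 10_000_000, 1.5, "HIGH", 1, 1 / 30),
                SelectedLocus("1", 10_000_000, 1.5, "LOW", 1, 1 / 30))
        recovered = swept = 0
        for seed in range(4):
            cfg = SimConfig(seed=seed, selected_loci=loci,
                            generations_sampled=(0, 11), line_sample_sizes={})
            res = simulate_experiment(cfg)
            fh = res.truth.trajectories[(0, "HIGH")][-1]
            fl = res.truth.trajectories[(1, "LOW")][-1]
            if min(fh, fl) < 0.9:
                continue
            swept += 1
            ct, g = res.cohorts, res.genotypes
            segs = call_roh_all(g, samples=ct.samples("HIGH", 11)
                                + ct.samples("LOW", 11) + ct.samples("BASE", 0))
            line_of = dict(zip(ct.table["sample_id"], ct.table["line"]))
            cons = consensus_roh(segs, g.markers, 2, line_of)
            sig = merge_intervals(roh_signatures(cons, 100, 100, 0.5))
            recovered += contains_point(sig, "1", res.truth.loci[0].pos_bp)
        assert swept >= 2
        assert recovered == swept
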