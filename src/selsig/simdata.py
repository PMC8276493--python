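"""Forward-in-time simulator of a divergent selection experiment.

The generator emulates the data-generating process the scanning modules
assume: a panmictic base population built as mosaics of a limited founder
haplotype pool (which creates LD that decays with distance), from which
two lines (HIGH / LOW) are bred forward as discrete Wright-Fisher
generations with multiplicative viability selection at configured loci
and recombination under the Haldane model.  Cohorts are drawn without
replacement from generation 0 (base) and from the configured later
generations of each line — a single continuous simulation sampled twice,
mirroring a selection experiment genotyped at two time points.

A separate fixture generator fabricates an annotated variant table with
transcription-unit effect classes and planted line-fixed INDELs for the
prioritisation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .funcvar import (AnnotatedVariant, EFFECT_CLASSES, FUNCTIONAL_CLASSES,
                      fixed_divergent, is_functional)
from .genio import CohortTable, GenotypeMatrix, MarkerMap

HIGH, LOW, BASE = "HIGH", "LOW", "BASE"


@dataclass(frozen=True)
class SelectedLocus:
    """A locus under viability selection in one line.

    ``favored_allele`` (0 = ref, 1 = alt) has fitness weights
    (1, 1+s, 1+2s) by its count in the genotype, applied only in
    ``favored_line``; the locus is neutral in the other line.
    ``init_freq`` pins the founder frequency of the *alt* allele
    (None = drawn from the prior like any other SNP).
    """

    chrom: str
    pos_bp: int
    s: float
    favored_line: str
    favored_allele: int = 1
    init_freq: float | None = 0.5

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.favored_line not in (HIGH, LOW):
            raise ValueError("favored_line must be HIGH or LOW")
        if self.favored_allele not in (0, 1):
            raise ValueError("favored_allele must be 0 or 1")


def divergent_locus(chrom: str, pos_bp: int, s: float,
                    init_freq: float = 0.5) -> list[SelectedLocus]:
    """One locus selected in opposite directions in the two lines.

    The alt allele is favored in HIGH and the ref allele in LOW — the
    configuration of a divergent selection experiment acting on a single
    causal site.
    """
    return [SelectedLocus(chrom, pos_bp, s, HIGH, 1, init_freq),
            SelectedLocus(chrom, pos_bp, s, LOW, 0, init_freq)]


@dataclass(frozen=True)
class SimConfig:
    """Desk-scale defaults: 2 chromosomes x 2,000 SNPs, 100 diploids per
    line, generations 0/11/13 sampled — a scaled-down analogue of a
    two-line divergent selection experiment genotyped on a SNP array."""

    n_chrom: int = 2
    chrom_len_bp: int = 20_000_000
    snps_per_chrom: int = 2_000
    n_founder_haplotypes: int = 30
    pop_size_per_line: int = 100
    base_pop_size: int = 100
    generations_sampled: tuple[int, ...] = (0, 11, 13)
    selected_loci: tuple[SelectedLocus, ...] = ()
    recomb_rate_cM_per_Mb: float = 1.0
    allele_freq_prior: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    base_sample_size: int = 96
    #: per sampled generation > 0: (n HIGH, n LOW); missing = whole line
    line_sample_sizes: dict = field(default_factory=lambda: {13: (46, 49)})

    def __post_init__(self):
        if self.snps_per_chrom < 2:
            raise ValueError("snps_per_chrom must be >= 2")
        if self.pop_size_per_line < 2 or self.base_pop_size < 2:
            raise ValueError("population sizes must be >= 2")
        gens = tuple(self.generations_sampled)
        if not gens or gens[0] != 0 or list(gens) != sorted(gens):
            raise ValueError("generations_sampled must be ascending and start at 0")
        if self.snps_per_chrom > self.chrom_len_bp:
            raise ValueError("more SNPs than distinct positions")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least 2 founder haplotypes")

    @property
    def n_generations(self) -> int:
        return max(self.generations_sampled)

    def chrom_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]


@dataclass
class SimTruth:
    """Ground truth of a run: the configured loci (with positions snapped
    to the nearest simulated SNP) and the realised favored-allele
    frequency trajectory of every locus in every line, generation by
    generation (index 0 = base)."""

    loci: list[SelectedLocus]
    trajectories: dict[tuple[int, str], np.ndarray]


# ---------------------------------------------------------------------------
# recombination machinery
# ---------------------------------------------------------------------------

@dataclass
class _ChromInfo:
    name: str
    sl: slice            # columns of this chromosome in the full matrix
    pos: np.ndarray      # local positions, bp
    length_bp: int
    morgans: float


@dataclass
class BasePool:
    """Generation-0 population: diploid founder-mosaic haplotypes."""

    haps: np.ndarray             # (n_ind, 2, n_snps) int8 alt-allele indicators
    markers: MarkerMap
    chrom_info: list[_ChromInfo]
    founder_freqs: np.ndarray
    selected_idx: list[int]      # marker column of each configured locus

    @property
    def n_ind(self) -> int:
        return self.haps.shape[0]


def _recombined_gamete(h0: np.ndarray, h1: np.ndarray,
                       chrom_info: list[_ChromInfo], rng) -> np.ndarray:
    """One gamete from a diploid (h0, h1): per chromosome, crossover count
    ~ Poisson(genetic length in Morgans), crossover positions uniform
    (Haldane, no interference), starting phase random."""
    out = np.empty_like(h0)
    for ci in chrom_info:
        k = rng.poisson(ci.morgans)
        phase0 = int(rng.integers(2))
        if k == 0:
            out[ci.sl] = (h0 if phase0 == 0 else h1)[ci.sl]
            continue
        cuts = rng.integers(1, ci.length_bp, size=k)
        idx = np.searchsorted(ci.pos, cuts, side="right")
        toggles = np.zeros(len(ci.pos), dtype=np.int64)
        np.add.at(toggles, idx[idx < len(ci.pos)], 1)
        phase = (phase0 + np.cumsum(toggles)) % 2
        seg0, seg1 = h0[ci.sl], h1[ci.sl]
        out[ci.sl] = np.where(phase == 0, seg0, seg1)
    return out


def _founder_mosaic(founders: np.ndarray, chrom_info: list[_ChromInfo], rng) -> np.ndarray:
    """One haplotype copied segment-wise from random founders, with
    segment breaks from the same Haldane crossover process."""
    n_f, L = founders.shape
    out = np.empty(L, dtype=np.int8)
    for ci in chrom_info:
        k = rng.poisson(ci.morgans)
        bounds = np.sort(rng.integers(1, ci.length_bp, size=k)) if k else np.empty(0)
        seg_of_snp = np.searchsorted(bounds, ci.pos, side="left")
        donors = rng.integers(n_f, size=k + 1)
        out[ci.sl] = founders[donors[seg_of_snp], np.arange(ci.sl.start, ci.sl.stop)]
    return out


# ---------------------------------------------------------------------------
# base population
# ---------------------------------------------------------------------------

def simulate_base(config: SimConfig, rng: np.random.Generator | None = None) -> BasePool:
    """Build founder haplotypes and a generation-0 population.

    SNP positions are uniform draws, deduplicated and sorted; founder
    alt-allele frequencies come from the Beta prior conditioned on the
    site being polymorphic among founders.  Each generation-0 haplotype
    is a founder mosaic, which yields LD decaying with distance.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    chrom_info: list[_ChromInfo] = []
    ids, chroms, pos_all = [], [], []
    offset = 0
    for name in config.chrom_names():
        pos = np.array([], dtype=np.int64)
        while len(pos) < config.snps_per_chrom:
            draw = rng.integers(1, config.chrom_len_bp + 1,
                                size=2 * config.snps_per_chrom)
            pos = np.unique(np.concatenate([pos, draw]))
        pos = np.sort(rng.choice(pos, size=config.snps_per_chrom, replace=False))
        morgans = config.chrom_len_bp / 1e6 * config.recomb_rate_cM_per_Mb / 100.0
        sl = slice(offset, offset + len(pos))
        chrom_info.append(_ChromInfo(name, sl, pos, config.chrom_len_bp, morgans))
        ids.extend(f"snp_{name}_{p}" for p in pos)
        chroms.extend([name] * len(pos))
        pos_all.append(pos)
        offset += len(pos)
    L = offset
    pos_all = np.concatenate(pos_all)
    markers = MarkerMap(ids, chroms, pos_all,
                        ["A"] * L, ["G"] * L, sort=False)

    n_f = config.n_founder_haplotypes
    a, b = config.allele_freq_prior
    freqs = rng.beta(a, b, size=L)
    founders = (rng.random((n_f, L)) < freqs).astype(np.int8)
    # condition on polymorphism among founders
    for _ in range(200):
        mono = np.flatnonzero(founders.sum(axis=0) % n_f == 0)
        if not len(mono):
            break
        freqs[mono] = rng.beta(a, b, size=len(mono))
        founders[:, mono] = (rng.random((n_f, len(mono))) < freqs[mono]).astype(np.int8)
    mono = np.flatnonzero(founders.sum(axis=0) % n_f == 0)
    if len(mono):  # force polymorphism on stubborn columns
        founders[rng.integers(n_f, size=len(mono)), mono] ^= 1

    # pin configured loci to their nearest SNP and initial frequency
    selected_idx: list[int] = []
    for locus in config.selected_loci:
        ci = next(c for c in chrom_info if c.name == locus.chrom)
        local = int(np.argmin(np.abs(ci.pos - locus.pos_bp)))
        col = ci.sl.start + local
        selected_idx.append(col)
        if locus.init_freq is not None:
            k = int(round(locus.init_freq * n_f))
            k = min(max(k, 1), n_f - 1)
            column = np.zeros(n_f, dtype=np.int8)
            column[rng.permutation(n_f)[:k]] = 1
            founders[:, col] = column

    haps = np.empty((config.base_pop_size, 2, L), dtype=np.int8)
    for i in range(config.base_pop_size):
        for h in range(2):
            haps[i, h] = _founder_mosaic(founders, chrom_info, rng)
    founder_freqs = founders.mean(axis=0)
    return BasePool(haps, markers, chrom_info, founder_freqs, selected_idx)


def sample_genotypes(haps: np.ndarray, markers: MarkerMap, prefix: str,
                     n: int, rng) -> GenotypeMatrix:
    """Draw ``n`` diploids without replacement and emit their dosages."""
    n = min(n, haps.shape[0])
    pick = np.sort(rng.permutation(haps.shape[0])[:n])
    dosage = haps[pick].sum(axis=1, dtype=np.int8)
    ids = [f"{prefix}_{i:04d}" for i in pick]
    return GenotypeMatrix(dosage, ids, markers)


# ---------------------------------------------------------------------------
# Wright-Fisher line evolution
# ---------------------------------------------------------------------------

def evolve_line(pool: BasePool, config: SimConfig, line: str,
                n_generations: int | None = None,
                rng: np.random.Generator | None = None,
                sample_generations: dict[int, int] | None = None,
                ) -> tuple[dict[int, GenotypeMatrix], SimTruth]:
    """Breed one line forward from the base pool for ``n_generations``
    discrete Wright-Fisher generations of constant size.

    Parent pairs are multinomial draws with probability proportional to
    fitness w = prod over this line's selected loci of (1, 1+s, 1+2s) by
    favored-allele count; loci favoring the other line are neutral here.
    Fixation of all fitness variation is allowed.  Returns genotype
    samples at the requested generations plus the realised trajectories
    of every configured locus (favored-allele frequency in this line).
    """
    if rng is None:
        offset = 1 if line == HIGH else 2
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed).spawn(3)[offset])
    if n_generations is None:
        n_generations = config.n_generations
    if sample_generations is None:
        sample_generations = {}
        for g in config.generations_sampled:
            if 0 < g <= n_generations:
                sizes = config.line_sample_sizes.get(g)
                if sizes is None:
                    sample_generations[g] = config.pop_size_per_line
                else:
                    sample_generations[g] = sizes[0] if line == HIGH else sizes[1]

    N = config.pop_size_per_line
    own = [(col, loc.s, loc.favored_allele)
           for col, loc in zip(pool.selected_idx, config.selected_loci)
           if loc.favored_line == line]

    traj = {i: [_favored_freq(pool.haps, col, loc.favored_allele)]
            for i, (col, loc) in enumerate(zip(pool.selected_idx, config.selected_loci))}

    pop = pool.haps
    samples: dict[int, GenotypeMatrix] = {}
    for gen in range(1, n_generations + 1):
        if own:
            w = np.ones(pop.shape[0])
            for col, s, fav in own:
                g = pop[:, :, col].sum(axis=1)
                if fav == 0:
                    g = 2 - g
                w *= 1.0 + s * g
            p = w / w.sum()
        else:
            p = None
        parents = rng.choice(pop.shape[0], size=(N, 2), p=p)
        child = np.empty((N, 2, pop.shape[2]), dtype=np.int8)
        for i in range(N):
            for k in range(2):
                par = parents[i, k]
                child[i, k] = _recombined_gamete(pop[par, 0], pop[par, 1],
                                                 pool.chrom_info, rng)
        pop = child
        for i, (col, loc) in enumerate(zip(pool.selected_idx, config.selected_loci)):
            traj[i].append(_favored_freq(pop, col, loc.favored_allele))
        if gen in sample_generations:
            samples[gen] = sample_genotypes(pop, pool.markers, f"{line}_g{gen}",
                                            sample_generations[gen], rng)

    loci = [replace(loc, pos_bp=int(pool.markers.pos_bp[col]))
            for loc, col in zip(config.selected_loci, pool.selected_idx)]
    truth = SimTruth(loci, {(i, line): np.array(t) for i, t in traj.items()})
    return samples, truth


def _favored_freq(pop: np.ndarray, col: int, favored_allele: int) -> float:
    f_alt = float(pop[:, :, col].mean())
    return f_alt if favored_allele == 1 else 1.0 - f_alt


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    genotypes: GenotypeMatrix    # all cohorts stacked
    cohorts: CohortTable
    truth: SimTruth
    config: SimConfig


def simulate_experiment(config: SimConfig) -> SimResult:
    """Base population plus both lines, sampled at the configured
    generations, merged into one genotype matrix with a cohort table."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    pool = simulate_base(config, np.random.default_rng(ss[0]))
    base_sample = sample_genotypes(pool.haps, pool.markers, "BASE_g0",
                                   min(config.base_sample_size, pool.n_ind),
                                   np.random.default_rng(ss[3]))
    high_samples, truth_h = evolve_line(pool, config, HIGH,
                                        rng=np.random.default_rng(ss[1]))
    low_samples, truth_l = evolve_line(pool, config, LOW,
                                       rng=np.random.default_rng(ss[2]))

    mats = [(BASE, 0, base_sample)]
    mats += [(HIGH, g, m) for g, m in sorted(high_samples.items())]
    mats += [(LOW, g, m) for g, m in sorted(low_samples.items())]
    values = np.vstack([m.values for _, _, m in mats])
    ids, records = [], []
    for line, gen, m in mats:
        ids.extend(m.sample_ids)
        records.extend((s, line, gen) for s in m.sample_ids)
    genotypes = GenotypeMatrix(values, ids, pool.markers)
    cohorts = CohortTable.from_records(records)
    truth = SimTruth(truth_h.loci, {**truth_h.trajectories, **truth_l.trajectories})
    return SimResult(genotypes, cohorts, truth, config)


# ---------------------------------------------------------------------------
# annotated-variant fixture
# ---------------------------------------------------------------------------

_EFFECT_WEIGHTS = {
    "intergenic": 0.50, "intron": 0.33, "upstream": 0.045, "downstream": 0.043,
    "3'UTR": 0.018, "5'UTR": 0.004, "synonymous": 0.02, "missense": 0.015,
    "frameshift": 0.006, "inframe": 0.003, "splicing": 0.006,
    "ncRNA exon": 0.008, "stop gained": 0.001, "start lost": 0.001,
}

_HOM_DISJOINT = [((0, 0), (1, 1)), ((1, 1), (0, 0)),
                 ((1, 1), (2, 2)), ((2, 2), (1, 1))]


def simulate_annotated_variants(n_genes: int = 40, n_variants: int = 300,
                                n_planted_fixed_divergent: int = 10,
                                seed: int = 0, chrom: str = "1",
                                chrom_len_bp: int = 20_000_000,
                                ):
    """Fabricate an annotated variant table with planted signal.

    Returns ``(variants, genes, truth)``: a list of
    :class:`~selsig.funcvar.AnnotatedVariant`, a gene interval table
    (chrom, start_bp, end_bp, gene_id; inclusive coordinates), and the
    positions of the ``n_planted_fixed_divergent`` planted variants —
    INDELs in transcription units whose two line genotypes are disjoint
    homozygotes.  Every non-planted record is guaranteed to fail at
    least one of the three filter criteria.  Deterministic given seed.
    """
    if n_planted_fixed_divergent > n_variants:
        raise ValueError("cannot plant more variants than n_variants")
    rng = np.random.default_rng(seed)
    import pandas as pd

    # evenly spaced non-overlapping genes with jittered lengths
    pitch = chrom_len_bp // (n_genes + 1)
    starts = (np.arange(n_genes) + 1) * pitch
    lengths = rng.integers(5_000, min(30_000, pitch - 1), size=n_genes)
    genes = pd.DataFrame({"chrom": chrom, "start_bp": starts,
                          "end_bp": starts + lengths,
                          "gene_id": [f"GENE{i:04d}" for i in range(n_genes)]})

    classes = list(_EFFECT_WEIGHTS)
    probs = np.array(list(_EFFECT_WEIGHTS.values()))
    probs /= probs.sum()
    genic = {"intron", "3'UTR", "5'UTR", "synonymous", "missense", "frameshift",
             "inframe", "splicing", "ncRNA exon", "stop gained", "start lost"}
    gt_pool = [(0, 0), (0, 1), (1, 1), (1, 2), (2, 2), (0, 2)]

    used_pos: set[int] = set()

    def fresh_pos(lo: int, hi: int) -> int:
        while True:
            p = int(rng.integers(lo, hi + 1))
            if p not in used_pos:
                used_pos.add(p)
                return p

    variants: list[AnnotatedVariant] = []
    truth: list[tuple[str, int]] = []
    planted_flags = np.zeros(n_variants, dtype=bool)
    planted_flags[rng.permutation(n_variants)[:n_planted_fixed_divergent]] = True

    for i in range(n_variants):
        if planted_flags[i]:
            gi = int(rng.integers(n_genes))
            pos = fresh_pos(int(genes.start_bp[gi]), int(genes.end_bp[gi]))
            eff = str(rng.choice(sorted(FUNCTIONAL_CLASSES & genic)))
            gt_low, gt_high = _HOM_DISJOINT[int(rng.integers(len(_HOM_DISJOINT)))]
            v = AnnotatedVariant(chrom=chrom, pos_bp=pos, ref="A",
                                 alt_alleles=["AT"], vtype="INDEL",
                                 effects=[(genes.gene_id[gi], eff)],
                                 genotype_low=gt_low, genotype_high=gt_high)
            truth.append((chrom, pos))
        else:
            eff = str(rng.choice(classes, p=probs))
            if eff in genic:
                gi = int(rng.integers(n_genes))
                pos = fresh_pos(int(genes.start_bp[gi]), int(genes.end_bp[gi]))
                gene = genes.gene_id[gi]
            else:
                gi = int(rng.integers(n_genes))
                pos = fresh_pos(1, chrom_len_bp)
                gene = genes.gene_id[gi]
            if eff in ("frameshift", "inframe"):
                vtype, ref, alt = "INDEL", "A", "AT"
            elif eff in ("missense", "synonymous", "stop gained", "start lost"):
                vtype, ref, alt = "SNV", "A", "G"
            else:
                vtype = "INDEL" if rng.random() < 0.15 else "SNV"
                ref, alt = ("A", "AT") if vtype == "INDEL" else ("A", "G")
            gt_low = gt_pool[int(rng.integers(len(gt_pool)))]
            gt_high = gt_pool[int(rng.integers(len(gt_pool)))]
            v = AnnotatedVariant(chrom=chrom, pos_bp=pos, ref=ref,
                                 alt_alleles=[alt], vtype=vtype,
                                 effects=[(gene, eff)],
                                 genotype_low=gt_low, genotype_high=gt_high)
            # a decoy must fail at least one criterion of the planted filter
            if v.vtype == "INDEL" and is_functional(v.effects) and fixed_divergent(v):
                v = replace(v, genotype_low=(0, 1))
        variants.append(v)

    variants.sort(key=lambda v: (v.chrom, v.pos_bp))
    truth.sort()
    return variants, genes, truth
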