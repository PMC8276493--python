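"""Integration and cross-generation validation of selection signatures.

Putative signatures come from three independent scanners (consensus ROH,
windowed weighted FST with the MAF drift rule, varLD three-comparison
logic) run on the generation-11 cohorts against the base population.
Each method's putative intervals are validated by rerunning that same
method's full pipeline on the base + generation-13 cohorts — thresholds
recomputed on the generation-13 distribution — and keeping the intervals
that overlap (>= 1 bp) a generation-13 interval of the same method.
Validation never mixes methods.  Validated ("true") signatures are then
merged and joined against a gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import fst as fst_mod
from . import roh as roh_mod
from . import varld as varld_mod
from .genio import CohortTable, GenotypeMatrix
from .intervals import Interval, merge_intervals, overlaps_any, write_bed

log = logging.getLogger(__name__)

METHODS = ("ROH", "FST", "VARLD")
PUTATIVE, TRUE = "PUTATIVE", "TRUE"


@dataclass
class SignatureSet:
    method: str
    intervals: list[Interval]
    analysis_generation: int
    status: str = PUTATIVE

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.status not in (PUTATIVE, TRUE):
            raise ValueError("status must be PUTATIVE or TRUE")
        self.intervals = merge_intervals(self.intervals)


def validate(putative: SignatureSet, revalidation: SignatureSet) -> SignatureSet:
    """Keep putative intervals re-detected by the same method.

    A putative (generation-11) interval is TRUE iff it overlaps >= 1 bp
    some interval of the revalidation (generation-13) set; surviving
    intervals retain their generation-11 coordinates.
    """
    if putative.method != revalidation.method:
        raise ValueError(f"method mismatch: {putative.method} vs {revalidation.method}")
    kept = [iv for iv in putative.intervals
            if overlaps_any(iv, revalidation.intervals)]
    return SignatureSet(putative.method, kept, putative.analysis_generation, TRUE)


# ---------------------------------------------------------------------------
# scanning pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanParams:
    """Every tunable of the three scanners, with the conventional
    defaults: 99.9th-percentile relevance, 500/250-kb FST windows of at
    least 10 SNPs, 50-SNP varLD windows, consensus ROH seen in >= 2
    animals and required in >= 50% of each line."""

    roh: roh_mod.ROHParams = field(default_factory=roh_mod.ROHParams)
    roh_min_count: int = 2
    roh_fraction: float = 0.5
    roh_thresholds: tuple[int, int] | None = None
    fst_window_kb: float = 500.0
    fst_step_kb: float = 250.0
    fst_min_snps: int = 10
    fst_percentile: float = 0.999
    maf_epsilon: float = 0.01
    varld_window_snps: int = 50
    varld_percentile: float = 0.999


def scan_signatures(g: GenotypeMatrix, cohorts: CohortTable, generation: int,
                    params: ScanParams = ScanParams()) -> dict[str, SignatureSet]:
    """Run all three scanners on one analysis generation vs the base
    population and return per-method putative signature sets."""
    base = cohorts.samples("BASE", 0)
    high = cohorts.samples("HIGH", generation)
    low = cohorts.samples("LOW", generation)
    if not base or not high or not low:
        raise ValueError(f"missing cohort for generation {generation}")

    # ROH: consensus over all three cohorts, line thresholds on HIGH/LOW
    segments = roh_mod.call_roh_all(g, params.roh, samples=base + high + low)
    line_of = dict(zip(cohorts.table["sample_id"], cohorts.table["line"]))
    consensus = roh_mod.consensus_roh(segments, g.markers, params.roh_min_count, line_of)
    roh_iv = roh_mod.roh_signatures(consensus, len(high), len(low),
                                    params.roh_fraction, params.roh_thresholds)

    fst_windows = fst_mod.windowed_fst(g, high, low, base_samples=base,
                                       window_kb=params.fst_window_kb,
                                       step_kb=params.fst_step_kb,
                                       min_snps=params.fst_min_snps,
                                       epsilon=params.maf_epsilon)
    fst_iv = (fst_mod.fst_signatures(fst_windows, params.fst_percentile)
              if fst_windows else [])

    scored = {}
    for label, (s1, s2) in {
        varld_mod.BASE_HIGH: (base, high),
        varld_mod.BASE_LOW: (base, low),
        varld_mod.HIGH_LOW: (high, low),
    }.items():
        ws = varld_mod.varld_scores(g, s1, s2, params.varld_window_snps)
        scored[label] = varld_mod.standardize_scores(ws)
    if all(scored.values()):
        varld_iv, _ = varld_mod.varld_signatures(scored, params.varld_percentile)
    else:
        varld_iv = []

    return {
        "ROH": SignatureSet("ROH", roh_iv, generation),
        "FST": SignatureSet("FST", fst_iv, generation),
        "VARLD": SignatureSet("VARLD", varld_iv, generation),
    }


def validate_scan(g: GenotypeMatrix, cohorts: CohortTable,
                  putative_generation: int = 11, validation_generation: int = 13,
                  params: ScanParams = ScanParams()
                  ) -> tuple[dict[str, SignatureSet], dict[str, SignatureSet]]:
    """Full two-generation analysis: scan the putative generation, rerun
    the identical pipeline on the validation generation, and intersect
    per method.  Returns (putative sets, true sets)."""
    putative = scan_signatures(g, cohorts, putative_generation, params)
    # fractional ROH thresholds recompute from the (smaller) gen-13 cohorts
    revalidation = scan_signatures(g, cohorts, validation_generation, params)
    true_sets = {m: validate(putative[m], revalidation[m]) for m in METHODS}
    return putative, true_sets


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class SignatureReport:
    per_method: dict[str, SignatureSet]
    union: list[Interval]
    genes: pd.DataFrame          # gene_id, chrom, start_bp, end_bp

    def counts(self) -> dict[str, int]:
        out = {m: len(s.intervals) for m, s in self.per_method.items()}
        out["union"] = len(self.union)
        out["genes"] = len(self.genes)
        return out

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for m, s in self.per_method.items():
            write_bed(s.intervals, outdir / f"signatures_{m.lower()}.bed")
        write_bed(self.union, outdir / "signatures_union.bed")
        self.genes.to_csv(outdir / "signature_genes.tsv", sep="\t", index=False)
        pd.Series(self.counts()).rename("count").to_csv(
            outdir / "signature_counts.tsv", sep="\t")


def merge_and_report(sets: Mapping[str, SignatureSet],
                     gene_annotation: pd.DataFrame | None = None) -> SignatureReport:
    """Merge validated sets into a union and overlay the gene annotation.

    ``gene_annotation`` needs columns gene_id, chrom, start_bp, end_bp
    (1-based inclusive); genes overlapping any TRUE interval by >= 1 bp
    are listed.  An empty/absent annotation yields a report without the
    gene overlay (with a warning).
    """
    union = merge_intervals(iv for s in sets.values() for iv in s.intervals)
    cols = ["gene_id", "chrom", "start_bp", "end_bp"]
    if gene_annotation is None or gene_annotation.empty:
        log.warning("no gene annotation supplied; report lacks the gene overlay")
        genes = pd.DataFrame(columns=cols)
    else:
        hits = [overlaps_any((str(r.chrom), int(r.start_bp), int(r.end_bp)), union)
                for r in gene_annotation.itertuples()]
        genes = gene_annotation.loc[hits, :].reset_index(drop=True)
        genes = genes[[c for c in cols if c in genes.columns]]
    return SignatureReport(dict(sets), union, genes)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open, name column = gene id)
    or GFF3 (gene features only, ID/gene_id attribute)."""
    path = str(path)
    rows = []
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("ID", attrs.get("gene_id", f"{f[0]}:{f[3]}"))
                rows.append((gid.removeprefix("gene:"), f[0], int(f[3]), int(f[4])))
    else:
        with open(path) as fh:
            for i, line in enumerate(fh):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                gid = f[3] if len(f) > 3 else f"gene_{i}"
                rows.append((gid, f[0], int(f[1]) + 1, int(f[2])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
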