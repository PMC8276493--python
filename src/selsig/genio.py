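"""Genotype I/O, cohort metadata, quality control and allele statistics.

Genotypes are held as an individuals x SNPs matrix of alt-allele dosages
(0, 1, 2) with ``MISSING`` (-1) for no-calls, tied to a :class:`MarkerMap`
describing the SNPs.  Positions are 1-based inclusive throughout the
library (the VCF convention); interval *outputs* written as BED use the
0-based half-open convention and are converted at the writer boundary.

Supported on-disk formats are VCF v4.2 (GT field only) and the PLINK
PED/MAP text dialect.  Cohort membership (line x generation) travels in a
three-column TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Missing-genotype code used in :class:`GenotypeMatrix` values.
MISSING: int = -1

LINES = ("BASE", "HIGH", "LOW")


class GenotypeLoadError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class EmptyResultError(ValueError):
    """Raised when an operation would return an empty genotype matrix."""


# ---------------------------------------------------------------------------
# marker map
# ---------------------------------------------------------------------------

class MarkerMap:
    """Per-SNP metadata: identifier, chromosome, 1-based position, alleles.

    Markers are stored sorted by (chrom, pos_bp) with chromosome names
    ordered lexicographically and positions numerically.  Duplicate
    (chrom, pos_bp) pairs and identical ref/alt alleles are rejected.
    """

    __slots__ = ("snp_id", "chrom", "pos_bp", "ref_allele", "alt_allele")

    def __init__(self, snp_id, chrom, pos_bp, ref_allele, alt_allele, *, sort=True):
        snp_id = np.asarray(snp_id, dtype=object)
        chrom = np.asarray(chrom, dtype=object)
        pos_bp = np.asarray(pos_bp, dtype=np.int64)
        ref_allele = np.asarray(ref_allele, dtype=object)
        alt_allele = np.asarray(alt_allele, dtype=object)
        n = len(snp_id)
        if not (len(chrom) == len(pos_bp) == len(ref_allele) == len(alt_allele) == n):
            raise ValueError("marker fields have unequal lengths")
        if sort and n:
            order = np.lexsort((pos_bp, chrom.astype(str)))
            snp_id, chrom, pos_bp = snp_id[order], chrom[order], pos_bp[order]
            ref_allele, alt_allele = ref_allele[order], alt_allele[order]
        self.snp_id = snp_id
        self.chrom = chrom
        self.pos_bp = pos_bp
        self.ref_allele = ref_allele
        self.alt_allele = alt_allele
        self.validate()

    def validate(self) -> None:
        if np.any(self.pos_bp < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        for r, a in zip(self.ref_allele, self.alt_allele):
            if not r or not a:
                raise ValueError("empty allele string")
            if r == a:
                raise ValueError(f"ref and alt alleles identical ({r!r})")
        for chrom, sl in self.chrom_slices().items():
            pos = self.pos_bp[sl]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"duplicate or unsorted position on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.snp_id)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous column slice per chromosome, in sorted order."""
        out: dict[str, slice] = {}
        if not len(self):
            return out
        chroms = self.chrom.astype(str)
        change = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(self)]))
        for s, e in zip(starts, ends):
            out[str(chroms[s])] = slice(int(s), int(e))
        return out

    def subset(self, index) -> "MarkerMap":
        return MarkerMap(self.snp_id[index], self.chrom[index], self.pos_bp[index],
                         self.ref_allele[index], self.alt_allele[index], sort=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerMap):
            return NotImplemented
        return all(np.array_equal(getattr(self, f), getattr(other, f))
                   for f in self.__slots__)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_id, "chrom": self.chrom,
                             "pos_bp": self.pos_bp, "ref_allele": self.ref_allele,
                             "alt_allele": self.alt_allele})


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

class GenotypeMatrix:
    """Individuals x SNPs matrix of alt-allele dosages in {0, 1, 2, MISSING}."""

    def __init__(self, values, sample_ids: Sequence[str], markers: MarkerMap):
        values = np.asarray(values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (samples x SNPs)")
        if values.shape[0] != len(sample_ids):
            raise ValueError("row count does not match number of samples")
        if values.shape[1] != len(markers):
            raise ValueError("column count does not match number of markers")
        bad = ~np.isin(values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype entries outside {{0,1,2,MISSING}}")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids")
        self.values = values
        self.sample_ids = list(sample_ids)
        self.markers = markers

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(self.values[idx], [self.sample_ids[i] for i in idx],
                              self.markers)

    def subset_snps(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.values[:, mask], self.sample_ids,
                              self.markers.subset(mask))

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing genotypes per sample."""
        if self.n_snps == 0:
            return np.ones(self.n_samples)
        return (self.values != MISSING).mean(axis=1)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.markers == other.markers
                and np.array_equal(self.values, other.values))


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Sample -> (line, generation) assignment.

    ``line`` is one of BASE / HIGH / LOW; ``generation`` a non-negative
    integer (0 denotes the base population).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "line", "generation"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"cohort table needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in cohort table")
        bad = set(self.table["line"]) - set(LINES)
        if bad:
            raise ValueError(f"unknown line labels {sorted(bad)}")
        if (self.table["generation"].astype(int) < 0).any():
            raise ValueError("negative generation")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "CohortTable":
        return cls(pd.DataFrame(records, columns=["sample_id", "line", "generation"]))

    @classmethod
    def read_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "line": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples(self, line: str | None = None, generation: int | None = None) -> list[str]:
        t = self.table
        if line is not None:
            t = t[t["line"] == line]
        if generation is not None:
            t = t[t["generation"].astype(int) == generation]
        return list(t["sample_id"])

    def covers(self, g: GenotypeMatrix) -> bool:
        return set(g.sample_ids) <= set(self.table["sample_id"])


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCParams:
    """Array quality-control thresholds.

    Defaults mirror common SNP-array practice for livestock panels:
    individuals must have a call rate of at least 97%, SNPs a minor allele
    frequency of at least 0.05 and at most 5% missing genotypes.
    """

    min_sample_call_rate: float = 0.97
    min_maf: float = 0.05
    max_snp_missing: float = 0.05

    def __post_init__(self):
        for name in ("min_sample_call_rate", "min_maf", "max_snp_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_samples_in: int
    n_snps_in: int
    samples_dropped_call_rate: list[str] = field(default_factory=list)
    snps_dropped_maf: list[str] = field(default_factory=list)
    snps_dropped_missing: list[str] = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - len(self.samples_dropped_call_rate)

    @property
    def n_snps_out(self) -> int:
        dropped = set(self.snps_dropped_maf) | set(self.snps_dropped_missing)
        return self.n_snps_in - len(dropped)

    def to_frame(self) -> pd.DataFrame:
        rows = ([("sample", s, "call_rate") for s in self.samples_dropped_call_rate]
                + [("snp", s, "maf") for s in self.snps_dropped_maf]
                + [("snp", s, "missingness") for s in self.snps_dropped_missing])
        return pd.DataFrame(rows, columns=["kind", "id", "criterion"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def allele_freq(g: GenotypeMatrix, samples: Sequence[str] | None = None) -> np.ndarray:
    """Alt-allele frequency per SNP over the given sample subset.

    Computed as sum(dosage) / (2 * non-missing count); SNPs with no
    non-missing genotype in the subset are returned as NaN, never as 0.
    """
    if samples is not None:
        if len(list(samples)) == 0:
            raise ValueError("empty sample subset")
        g = g.subset_samples(samples)
    if g.n_samples == 0:
        raise ValueError("empty sample subset")
    v = g.values
    called = v != MISSING
    n = called.sum(axis=0)
    dose = np.where(called, v, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, dose / (2.0 * n), np.nan)


def observed_het(g: GenotypeMatrix, samples: Sequence[str] | None = None) -> np.ndarray:
    """Observed heterozygote fraction per SNP (dosage == 1 among called)."""
    if samples is not None:
        g = g.subset_samples(samples)
    v = g.values
    called = v != MISSING
    n = called.sum(axis=0)
    het = (v == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, het / n, np.nan)


def qc_filter(g: GenotypeMatrix, params: QCParams = QCParams()) -> tuple[GenotypeMatrix, QCReport]:
    """Drop low-call-rate samples, then low-MAF / high-missingness SNPs.

    Sample filtering happens first; SNP statistics are then computed on
    the retained samples only, so the operation is idempotent on its own
    output.  MAF uses the minor allele defined per SNP across retained
    samples.
    """
    if g.n_samples == 0 or g.n_snps == 0:
        raise EmptyResultError("cannot QC-filter an empty genotype matrix")
    report = QCReport(n_samples_in=g.n_samples, n_snps_in=g.n_snps)

    cr = g.call_rate()
    keep_samples = cr >= params.min_sample_call_rate
    report.samples_dropped_call_rate = [s for s, k in zip(g.sample_ids, keep_samples) if not k]
    if not keep_samples.any():
        raise EmptyResultError("all samples removed by call-rate filter")
    g = g.subset_samples([s for s, k in zip(g.sample_ids, keep_samples) if k])

    p = allele_freq(g)
    maf = np.fmin(p, 1.0 - p)          # NaN-freq SNPs handled below
    miss = (g.values == MISSING).mean(axis=0)
    fail_maf = ~(maf >= params.min_maf)          # True for NaN too
    fail_miss = miss > params.max_snp_missing
    report.snps_dropped_maf = list(g.markers.snp_id[fail_maf])
    report.snps_dropped_missing = list(g.markers.snp_id[fail_miss])
    keep_snps = ~(fail_maf | fail_miss)
    g = g.subset_snps(keep_snps)
    log.info("QC: kept %d samples, %d SNPs (dropped %d samples, %d SNPs)",
             g.n_samples, g.n_snps, len(report.samples_dropped_call_rate),
             report.n_snps_in - g.n_snps)
    return g, report


# ---------------------------------------------------------------------------
# VCF read/write
# ---------------------------------------------------------------------------

def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as e:  # htslib errors are opaque
        raise GenotypeLoadError(f"{path}: cannot open as VCF: {e}") from e
    samples = list(vcf.samples)
    ids, chroms, pos, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    try:
        for var in vcf:
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            ids.append(var.ID or f"{var.CHROM}_{var.POS}")
            chroms.append(var.CHROM)
            pos.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            gt = np.asarray(var.gt_types, dtype=np.int8)
            gt[gt == 3] = MISSING        # gts012: 3 == unknown / half-missing
            rows.append(gt)
    except Exception as e:
        raise GenotypeLoadError(
            f"{path}: malformed VCF record after line "
            f"{len(ids) + n_multi}: {e}") from e
    if n_multi:
        log.info("%s: skipped %d non-biallelic site(s)", path, n_multi)
    if rows:
        values = np.stack(rows, axis=1)
    else:
        values = np.zeros((len(samples), 0), dtype=np.int8)
    markers = MarkerMap(ids, chroms, pos or [], refs, alts, sort=False)
    order = np.lexsort((markers.pos_bp, markers.chrom.astype(str)))
    return GenotypeMatrix(values[:, order], samples, markers.subset(order))


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    m = g.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=selsig\n")
        for chrom, sl in m.chrom_slices().items():
            length = int(m.pos_bp[sl].max()) + 1 if sl.stop > sl.start else 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if g.n_samples:
            cols += ["FORMAT"] + g.sample_ids
        fh.write("\t".join(cols) + "\n")
        for j in range(g.n_snps):
            rec = [str(m.chrom[j]), str(m.pos_bp[j]), str(m.snp_id[j]),
                   str(m.ref_allele[j]), str(m.alt_allele[j]), ".", ".", "."]
            if g.n_samples:
                rec.append("GT")
                rec.extend(GT[int(d)] for d in g.values[:, j])
            fh.write("\t".join(rec) + "\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP text read/write
# ---------------------------------------------------------------------------

def _plink_paths(path: Path) -> tuple[Path, Path]:
    """`path` is a prefix, or either of the two component files."""
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in (".ped", ".map") else p
    return stem.with_suffix(".ped"), stem.with_suffix(".map")


def _read_plink(path: Path) -> GenotypeMatrix:
    ped_path, map_path = _plink_paths(path)
    ids, chroms, pos, refs, alts = [], [], [], [], []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise GenotypeLoadError(f"{map_path}:{ln}: expected 4 fields, got {len(fields)}")
            chroms.append(fields[0])
            ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError:
                raise GenotypeLoadError(f"{map_path}:{ln}: bad position {fields[3]!r}") from None
            # allele columns are a selsig extension of the MAP dialect; a
            # 4-column file falls back to A/B placeholder alleles
            refs.append(fields[4] if len(fields) > 4 else "A")
            alts.append(fields[5] if len(fields) > 5 else "B")
    n_snp = len(ids)
    sample_ids, rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snp:
                raise GenotypeLoadError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snp} fields, got {len(fields)}")
            sample_ids.append(fields[1])
            row = np.empty(n_snp, dtype=np.int8)
            for j in range(n_snp):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                    continue
                dose = 0
                for a in (a1, a2):
                    if a == alts[j]:
                        dose += 1
                    elif a != refs[j]:
                        raise GenotypeLoadError(
                            f"{ped_path}:{ln}: allele {a!r} not in {{{refs[j]},{alts[j]}}} "
                            f"for SNP {ids[j]}")
                row[j] = dose
            rows.append(row)
    values = np.stack(rows) if rows else np.zeros((0, n_snp), dtype=np.int8)
    markers = MarkerMap(ids, chroms, pos or [], refs, alts, sort=False)
    order = np.lexsort((markers.pos_bp, markers.chrom.astype(str)))
    return GenotypeMatrix(values[:, order], sample_ids, markers.subset(order))


def _write_plink(g: GenotypeMatrix, path: Path) -> None:
    ped_path, map_path = _plink_paths(path)
    m = g.markers
    with open(map_path, "w") as fh:
        for j in range(len(m)):
            fh.write(f"{m.chrom[j]}\t{m.snp_id[j]}\t0\t{m.pos_bp[j]}"
                     f"\t{m.ref_allele[j]}\t{m.alt_allele[j]}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                d = int(g.values[i, j])
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [str(m.alt_allele[j]) if k < d else str(m.ref_allele[j])
                               for k in range(2)][::-1]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "VCF") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or PLINK PED/MAP text.

    For PLINK input, ``path`` may be the file-set prefix or either
    component file.  Non-biallelic VCF sites are skipped (counted in the
    log); half-missing genotypes become MISSING.  Markers come back
    sorted by (chrom, pos_bp).
    """
    fmt = format.upper()
    if fmt == "VCF":
        return _read_vcf(Path(path))
    if fmt in ("PLINK_TEXT", "PLINK"):
        return _read_plink(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str = "VCF") -> None:
    """Write a genotype matrix; round-trips through :func:`read_genotypes`."""
    fmt = format.upper()
    if fmt == "VCF":
        _write_vcf(g, Path(path))
    elif fmt in ("PLINK_TEXT", "PLINK"):
        _write_plink(g, Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")
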