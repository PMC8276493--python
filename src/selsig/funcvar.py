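"""Functional-mutation prioritisation inside validated signatures.

Works on effect-annotated variants carrying one pooled consensus genotype
per line (the way pooled whole-genome sequencing of each line is usually
summarised).  Alleles are coded 0 = reference, 1 = alternative, 2 = a
novel allele absent from the reference assembly.

A variant counts as a *transcription-unit functional mutation* when any
of its effects is a UTR, missense, frameshift or splice-site change; a
*fixed-divergent* variant is homozygous in both lines with no shared
allele (1/1 vs 0/0, or 1/1 vs a novel 2/2).  The intersection of the two
filters with the INDEL type is the shortlist of line-diagnostic
functional INDELs; genes carrying any functional mutation inside a true
signature are the candidate genes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace  # noqa: F401  (replace used by callers)
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import Interval, contains_point

log = logging.getLogger(__name__)

#: The 14 recognised effect classes.
EFFECT_CLASSES = frozenset({
    "upstream", "downstream", "intergenic", "3'UTR", "5'UTR", "intron",
    "splicing", "synonymous", "missense", "frameshift", "inframe",
    "ncRNA exon", "stop gained", "start lost",
})

#: Classes that place a variant in the transcription unit of a gene.
FUNCTIONAL_CLASSES = frozenset({"3'UTR", "5'UTR", "missense", "frameshift", "splicing"})

#: Optionally treated as functional too (off by default).
EXTENDED_FUNCTIONAL_CLASSES = frozenset({"stop gained", "start lost", "inframe"})

_CLASS_ALIASES = {
    "3ʹutr": "3'UTR", "3utr": "3'UTR", "3'utr": "3'UTR",
    "3_prime_utr_variant": "3'UTR", "three_prime_utr": "3'UTR",
    "5ʹutr": "5'UTR", "5utr": "5'UTR", "5'utr": "5'UTR",
    "5_prime_utr_variant": "5'UTR", "five_prime_utr": "5'UTR",
    "frameshift_variant": "frameshift", "missense_variant": "missense",
    "synonymous_variant": "synonymous", "intron_variant": "intron",
    "splice": "splicing", "splice_site": "splicing",
    "splice_acceptor_variant": "splicing", "splice_donor_variant": "splicing",
    "upstream_gene_variant": "upstream", "downstream_gene_variant": "downstream",
    "intergenic_variant": "intergenic", "stop_gained": "stop gained",
    "start_lost": "start lost", "inframe_insertion": "inframe",
    "inframe_deletion": "inframe", "ncrna exon": "ncRNA exon",
    "ncrna_exonic": "ncRNA exon",
}


class UnknownEffectError(ValueError):
    """Raised when an annotation uses an effect class outside the vocabulary."""


def normalize_effect_class(name: str) -> str:
    """Map an annotator's effect string onto the 14-class vocabulary."""
    key = name.strip()
    if key in EFFECT_CLASSES:
        return key
    low = key.lower().replace("ʹ", "'")
    if low in EFFECT_CLASSES:
        return low
    for cls in EFFECT_CLASSES:
        if low == cls.lower():
            return cls
    if low in _CLASS_ALIASES:
        return _CLASS_ALIASES[low]
    raise UnknownEffectError(f"unknown effect class {name!r}")


Genotype = tuple[int, int] | None


@dataclass(frozen=True)
class AnnotatedVariant:
    """An effect-annotated variant with pooled per-line genotypes."""

    chrom: str
    pos_bp: int
    ref: str
    alt_alleles: list[str] = field(default_factory=lambda: ["N"])
    vtype: str = "SNV"                     # SNV | INDEL
    effects: list[tuple[str, str]] = field(default_factory=list)   # (gene_id, class)
    genotype_low: Genotype = None          # unordered allele pair, 0/1/2 coding
    genotype_high: Genotype = None

    def __post_init__(self):
        if self.vtype not in ("SNV", "INDEL"):
            raise ValueError(f"vtype must be SNV or INDEL, got {self.vtype!r}")
        for _, cls in self.effects:
            if cls not in EFFECT_CLASSES:
                raise UnknownEffectError(f"unknown effect class {cls!r}")


@dataclass
class CandidateGene:
    gene_id: str
    functional_variant_count: int
    effect_classes: set[str]
    in_signature: list[Interval]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def is_functional(effects: Iterable[tuple[str, str]],
                  include_extended: bool = False) -> bool:
    """True when any effect hits the transcription unit: UTRs, missense,
    frameshift or splicing (optionally stop-gained / start-lost /
    inframe)."""
    allowed = FUNCTIONAL_CLASSES | (EXTENDED_FUNCTIONAL_CLASSES if include_extended
                                    else frozenset())
    return any(cls in allowed for _, cls in effects)


def fixed_divergent(v: AnnotatedVariant) -> bool:
    """Both line genotypes homozygous with disjoint allele sets.

    Covers 1/1 vs 0/0 as well as 1/1 vs a novel 2/2.  Symmetric in line
    order; False (with a warning) when a line genotype is missing.
    """
    if v.genotype_low is None or v.genotype_high is None:
        log.warning("variant %s:%d lacks a line genotype; treated as not "
                    "fixed-divergent", v.chrom, v.pos_bp)
        return False
    lo, hi = set(v.genotype_low), set(v.genotype_high)
    return len(lo) == 1 and len(hi) == 1 and lo.isdisjoint(hi)


def fixed_divergent_functional_indels(variants: Iterable[AnnotatedVariant],
                                      include_extended: bool = False,
                                      ) -> list[AnnotatedVariant]:
    """The headline shortlist: INDELs in transcription units fixed for
    disjoint homozygous genotypes between the lines."""
    return [v for v in variants
            if v.vtype == "INDEL"
            and is_functional(v.effects, include_extended)
            and fixed_divergent(v)]


def tabulate_effects(variants: Iterable[AnnotatedVariant]) -> tuple[Counter, int]:
    """Count effects per class over (gene, class) occurrences.

    A variant annotated on two genes contributes two effects, so the
    total can exceed the variant count.  Returns (counter, total).
    """
    counts: Counter = Counter()
    for v in variants:
        for _, cls in v.effects:
            if cls not in EFFECT_CLASSES:
                raise UnknownEffectError(f"unknown effect class {cls!r}")
            counts[cls] += 1
    return counts, sum(counts.values())


def candidate_genes(variants: Iterable[AnnotatedVariant],
                    true_signatures: Sequence[Interval],
                    include_extended: bool = False) -> list[CandidateGene]:
    """Genes with >= 1 functional mutation inside a true signature."""
    per_gene: dict[str, CandidateGene] = {}
    for v in variants:
        if not is_functional(v.effects, include_extended):
            continue
        if not contains_point(true_signatures, v.chrom, v.pos_bp):
            continue
        hit = [iv for iv in true_signatures
               if iv[0] == v.chrom and iv[1] <= v.pos_bp <= iv[2]]
        for gene, cls in v.effects:
            if cls not in (FUNCTIONAL_CLASSES |
                           (EXTENDED_FUNCTIONAL_CLASSES if include_extended else frozenset())):
                continue
            cg = per_gene.setdefault(gene, CandidateGene(gene, 0, set(), []))
            cg.functional_variant_count += 1
            cg.effect_classes.add(cls)
            for iv in hit:
                if iv not in cg.in_signature:
                    cg.in_signature.append(iv)
    return sorted(per_gene.values(), key=lambda c: c.gene_id)


# ---------------------------------------------------------------------------
# GO keyword-dictionary pathway percentages
# ---------------------------------------------------------------------------

def go_pathway_percentages(go_descriptions: Sequence[str],
                           dictionary: Mapping[str, Sequence[str]],
                           multi_assign: bool = False) -> dict[str, float]:
    """Share of GO descriptions per biological pathway, by keyword match.

    Each description is matched case-insensitively against the keyword
    lists; unmatched descriptions fall into "Other Processes".  With
    first-match assignment (the default; dictionary order decides ties)
    percentages X_i / N * 100 sum to 100.  With ``multi_assign`` a
    description can count toward several pathways and the sum may exceed
    100.
    """
    n = len(go_descriptions)
    if n == 0:
        raise ValueError("no GO descriptions supplied (N = 0)")
    counts = {p: 0 for p in dictionary}
    counts["Other Processes"] = 0
    for desc in go_descriptions:
        d = desc.lower()
        matched = False
        for pathway, keywords in dictionary.items():
            if any(k.lower() in d for k in keywords):
                counts[pathway] += 1
                matched = True
                if not multi_assign:
                    break
        if not matched:
            counts["Other Processes"] += 1
    return {p: 100.0 * c / n for p, c in counts.items()}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_gt(text: str) -> Genotype:
    t = text.strip().replace("|", "/")
    if t in (".", "./.", ""):
        return None
    a, b = t.split("/")
    return (int(a), int(b))


def _format_gt(gt: Genotype) -> str:
    return "./." if gt is None else f"{gt[0]}/{gt[1]}"


def read_variant_table(path) -> list[AnnotatedVariant]:
    """Read an annotated variant TSV.

    Columns (case-insensitive): chrom, pos_bp, low, high, gene, region
    (an effect class), mutation (e.g. "3-bp deletion", "SNV"); an
    optional ``effects`` column ("gene:class;gene:class") overrides
    gene/region for multi-effect variants.  This mirrors how pooled-line
    diagnostic variants are customarily tabulated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    colmap = {"ocu": "chrom", "bp": "pos_bp"}
    df = df.rename(columns=colmap)
    out = []
    for _, row in df.iterrows():
        if "effects" in df.columns and isinstance(row.get("effects"), str) and row["effects"]:
            effects = [(g.strip(), normalize_effect_class(c))
                       for g, c in (pair.split(":", 1)
                                    for pair in row["effects"].split(";"))]
        else:
            effects = [(str(row["gene"]), normalize_effect_class(str(row["region"])))]
        mutation = str(row.get("mutation", "SNV"))
        vtype = ("INDEL" if ("insertion" in mutation.lower()
                             or "deletion" in mutation.lower()
                             or mutation.upper() == "INDEL") else "SNV")
        ref = str(row["ref"]) if "ref" in df.columns else "N"
        alt = str(row["alt"]) if "alt" in df.columns else "N"
        out.append(AnnotatedVariant(
            chrom=str(row["chrom"]), pos_bp=int(row["pos_bp"]), ref=ref,
            alt_alleles=[alt], vtype=vtype, effects=effects,
            genotype_low=_parse_gt(str(row["low"])),
            genotype_high=_parse_gt(str(row["high"]))))
    return out


def write_variant_table(variants: Iterable[AnnotatedVariant], path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "chrom": v.chrom, "pos_bp": v.pos_bp, "ref": v.ref,
            "alt": ",".join(v.alt_alleles), "low": _format_gt(v.genotype_low),
            "high": _format_gt(v.genotype_high),
            "gene": v.effects[0][0] if v.effects else ".",
            "region": v.effects[0][1] if v.effects else ".",
            "mutation": v.vtype,
            "effects": ";".join(f"{g}:{c}" for g, c in v.effects),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_reference_fixed_indels() -> list[AnnotatedVariant]:
    """The ten published line-diagnostic functional INDELs from the rabbit
    divergent selection experiment on environmental variance of litter
    size, shipped as package data."""
    with resources.as_file(resources.files("selsig.data")
                           / "divergent_fixed_indels.tsv") as p:
        return read_variant_table(p)
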