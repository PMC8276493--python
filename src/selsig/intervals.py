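"""Small genomic-interval helpers shared by the scanning modules.

Intervals are (chrom, start_bp, end_bp) tuples, 1-based inclusive on both
ends (marker coordinates).  BED conversion (0-based half-open) happens
only in :func:`write_bed` / :func:`read_bed`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[str, int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: sort and fuse any that touch or overlap."""
    out: list[Interval] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2] + 1:
            c, ps, pe = out[-1]
            out[-1] = (c, ps, max(pe, e))
        else:
            out.append((chrom, s, e))
    return out


def overlaps(a: Interval, b: Interval) -> bool:
    """At least 1 bp shared (inclusive coordinates)."""
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


def overlaps_any(a: Interval, others: Sequence[Interval]) -> bool:
    return any(overlaps(a, b) for b in others)


def intersect(set_a: Sequence[Interval], set_b: Sequence[Interval]) -> list[Interval]:
    """Pairwise intersections (>= 1 bp) of two interval sets, merged."""
    hits = []
    for a in set_a:
        for b in set_b:
            if overlaps(a, b):
                hits.append((a[0], max(a[1], b[1]), min(a[2], b[2])))
    return merge_intervals(hits)


def contains_point(intervals: Sequence[Interval], chrom: str, pos: int) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in intervals)


def write_bed(intervals: Iterable[Interval], path, names: Iterable[str] | None = None) -> None:
    """Write intervals as BED (0-based half-open)."""
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(intervals):
            name = f"\t{names[i]}" if names else ""
            fh.write(f"{chrom}\t{s - 1}\t{e}{name}\n")


def read_bed(path) -> list[Interval]:
    """Read the first three BED columns back to inclusive coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out
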