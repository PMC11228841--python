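"""Adapter trimming, alignment, uniqueness/mismatch filtering, mappability.

The uniqueness filter is the analytical core of organellar XR-seq
preprocessing: reads that place equally well at several genomic locations
(NUMT/NUPT copies, inverted-repeat copies) cannot be attributed to a
compartment and are removed.  Two alignment paths feed the same
:class:`AlignedFragment` representation:

* :func:`align_exact` — an internal exact-match aligner that enumerates
  *all* perfect full-length placements of each read on both strands of all
  genomes (origin-spanning placements included on circular genomes) and
  defines uniqueness combinatorially: unique iff exactly one placement.
  This is the intent of a MAPQ ≥ 30 cutoff, made exact and testable.
* :func:`import_sam` — SAM/BAM import (pysam), where uniqueness is decided
  by the aligner-reported MAPQ against a threshold (default 30) and
  mismatches come from the NM tag (recomputed from the reference when
  absent).

Mappability is reported as the fraction of positions covered in the
unfiltered alignment that remain covered after filtering, per region
category — the cost of the uniqueness filter, not of sampling depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Genome, revcomp
from .simulate import FastqRead

__all__ = [
    "AlignedFragment",
    "TrimReport",
    "FilterReport",
    "MappabilityReport",
    "trim_adapter",
    "align_exact",
    "import_sam",
    "filter_fragments",
    "apply_halving_weights",
    "compute_mappability",
    "fragment_sequence",
    "write_bed",
]


@dataclass
class AlignedFragment:
    """One read placement on the (edited) reference.

    ``start``/``end`` are 0-based half-open; on circular genomes ``end``
    may exceed the genome length for origin-spanning placements (positions
    are taken modulo length).  ``uniqueness`` is one of ``unique``,
    ``multi``, ``unmapped``; unmapped fragments carry no coordinates.
    ``weight`` is the counting weight (0.5 inside halve-count intervals).
    """

    read_id: str
    chrom: str | None
    start: int
    end: int
    strand: str
    length: int
    uniqueness: str
    mismatches: int = 0
    mapq: int | None = None
    weight: float = 1.0

    @property
    def midpoint(self) -> int:
        return self.start + self.length // 2


@dataclass
class TrimReport:
    total: int = 0
    trimmed: int = 0
    discarded_untrimmed: int = 0
    discarded_empty: int = 0


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(
    reads: list[FastqRead],
    adapter: str,
    min_overlap: int = 3,
    max_error_rate: float = 0.0,
) -> tuple[list[FastqRead], TrimReport]:
    """Trim a 3′ adapter; discard reads in which no adapter is found.

    The adapter may occur in full anywhere in the read, or as a prefix of
    the adapter overlapping the read's 3′ end by at least ``min_overlap``
    bases.  Up to ``floor(max_error_rate × overlap)`` mismatches are
    allowed.  The leftmost acceptable hit wins; the read is truncated at
    the hit.  Untrimmed reads and reads empty after trimming are discarded,
    with counts reported.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    report = TrimReport(total=len(reads))
    kept: list[FastqRead] = []
    la = len(adapter)
    for read in reads:
        n = len(read.seq)
        hit = None
        for j in range(0, n - min_overlap + 1):
            ov = min(la, n - j)
            errors = _mismatches(read.seq[j : j + ov], adapter[:ov])
            if errors <= int(max_error_rate * ov):
                hit = j
                break
        if hit is None:
            report.discarded_untrimmed += 1
            continue
        if hit == 0:
            report.discarded_empty += 1
            continue
        report.trimmed += 1
        kept.append(FastqRead(read.id, read.seq[:hit], read.qual[:hit]))
    return kept, report


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    """All occurrence start positions of ``needle`` with start < limit."""
    out = []
    i = haystack.find(needle)
    while i != -1 and i < limit:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def align_exact(
    reads: list[FastqRead], genomes: list[Genome]
) -> list[AlignedFragment]:
    """Enumerate all perfect full-length placements; classify uniqueness.

    Both strands of every genome are searched; circular genomes are
    extended by (read length − 1) bases so origin-spanning placements are
    found once.  A read is ``unique`` iff it has exactly one placement
    across all genomes and strands, ``multi`` if more, ``unmapped`` if
    none.  Multi reads report their first placement (sorted by genome,
    position, strand) so that unfiltered coverage can still be computed.
    """
    if not reads:
        return []
    max_len = max(len(r.seq) for r in reads)
    search: list[tuple[str, int, str, bool]] = []
    for g in genomes:
        ext = g.seq + g.seq[: max_len - 1] if g.is_circular else g.seq
        search.append((g.id, len(g.seq), ext, g.is_circular))

    cache: dict[str, list[tuple[str, int, str]]] = {}
    out: list[AlignedFragment] = []
    for read in reads:
        seq = read.seq
        placements = cache.get(seq)
        if placements is None:
            placements = []
            rc = revcomp(seq)
            for gid, glen, ext, _circ in search:
                for strand, query in (("+", seq), ("-", rc)):
                    for pos in _find_all(ext, query, glen):
                        placements.append((gid, pos, strand))
            placements = sorted(set(placements))
            cache[seq] = placements
        L = len(seq)
        if not placements:
            out.append(
                AlignedFragment(read.id, None, -1, -1, "+", L, "unmapped")
            )
        else:
            uniq = "unique" if len(placements) == 1 else "multi"
            gid, pos, strand = placements[0]
            out.append(
                AlignedFragment(read.id, gid, pos, pos + L, strand, L, uniq)
            )
    return out


def import_sam(
    path, genomes: list[Genome], mapq_min: int = 30
) -> list[AlignedFragment]:
    """Import SAM/BAM records as aligned fragments.

    Uniqueness is ``unique`` iff MAPQ ≥ ``mapq_min`` (the conventional
    cutoff that removes reads mapping equally well to several locations).
    Mismatch counts come from the NM tag, or are recomputed against the
    reference when the tag is absent.
    """
    import pysam

    by_id = {g.id: g for g in genomes}
    out: list[AlignedFragment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.append(
                    AlignedFragment(
                        rec.query_name, None, -1, -1, "+",
                        rec.query_length or 0, "unmapped",
                    )
                )
                continue
            chrom = rec.reference_name
            if chrom not in by_id:
                raise ValueError(f"reference {chrom!r} absent from genome set")
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            else:
                g = by_id[chrom]
                ref = g.fetch(rec.reference_start, rec.query_length)
                nm = _mismatches(rec.query_sequence.upper(), ref)
            uniq = "unique" if rec.mapping_quality >= mapq_min else "multi"
            out.append(
                AlignedFragment(
                    read_id=rec.query_name,
                    chrom=chrom,
                    start=rec.reference_start,
                    end=rec.reference_start + rec.query_length,
                    strand="-" if rec.is_reverse else "+",
                    length=rec.query_length,
                    uniqueness=uniq,
                    mismatches=nm,
                    mapq=rec.mapping_quality,
                )
            )
    return out


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    removed_multimapping: int = 0
    removed_unmapped: int = 0
    removed_mismatch: int = 0


def filter_fragments(
    fragments: list[AlignedFragment], max_mismatches: int = 0
) -> tuple[list[AlignedFragment], FilterReport]:
    """Keep uniquely mapping fragments with at most ``max_mismatches``."""
    report = FilterReport(total=len(fragments))
    kept = []
    for f in fragments:
        if f.uniqueness == "unmapped":
            report.removed_unmapped += 1
        elif f.uniqueness == "multi":
            report.removed_multimapping += 1
        elif f.mismatches > max_mismatches:
            report.removed_mismatch += 1
        else:
            kept.append(f)
    report.kept = len(kept)
    return kept, report


def apply_halving_weights(
    fragments: list[AlignedFragment], genomes: list[Genome]
) -> list[AlignedFragment]:
    """Down-weight to 0.5 any fragment overlapping a halve-count interval.

    Implements uniform 1/2 counting for reads in the retained copy of a
    collapsed duplication (e.g. a plastid inverted repeat).
    """
    halved = {g.id: g.halved_intervals for g in genomes}
    glen = {g.id: len(g.seq) for g in genomes}
    out = []
    for f in fragments:
        w = f.weight
        for s, e in halved.get(f.chrom, ()):
            n = glen[f.chrom]
            # fragment occupies [start, end) with possible wrap mod n
            fs, fe = f.start, f.end
            overlaps = max(fs, s) < min(fe, e)
            if fe > n:  # origin-spanning: also test the wrapped part
                overlaps = overlaps or max(0, s) < min(fe - n, e)
            if overlaps:
                w = f.weight * 0.5
                break
        out.append(replace(f, weight=w))
    return out


def _coverage_mask(fragments, glen: int) -> np.ndarray:
    mask = np.zeros(glen, dtype=bool)
    for f in fragments:
        if f.end <= glen:
            mask[f.start : f.end] = True
        else:  # circular wrap
            mask[f.start :] = True
            mask[: f.end - glen] = True
    return mask


@dataclass
class MappabilityReport:
    """Fraction of unfiltered-covered positions retained after filtering.

    ``fractions`` maps region category → fraction in [0, 1] (NaN where the
    category had no unfiltered coverage); ``overall`` aggregates over all
    positions (position-weighted).
    """

    genome_id: str
    fractions: dict[str, float]
    overall: float

    def to_frame(self):
        import pandas as pd

        rows = [
            {"genome": self.genome_id, "category": c, "fraction_retained": v}
            for c, v in self.fractions.items()
        ]
        rows.append(
            {
                "genome": self.genome_id,
                "category": "total",
                "fraction_retained": self.overall,
            }
        )
        return pd.DataFrame(rows)


def compute_mappability(
    fragments_unfiltered: list[AlignedFragment],
    fragments_filtered: list[AlignedFragment],
    genome: Genome,
    feature_set=None,
) -> MappabilityReport:
    """Position-level retained fraction after uniqueness filtering.

    A position counts as covered when any fragment overlaps it.  Positions
    never covered in the unfiltered set are excluded from numerator and
    denominator, so the report measures mappability rather than depth.
    """
    glen = len(genome.seq)
    unf = _coverage_mask(
        [f for f in fragments_unfiltered if f.chrom == genome.id], glen
    )
    flt = _coverage_mask(
        [f for f in fragments_filtered if f.chrom == genome.id], glen
    )
    if feature_set is not None:
        cats = feature_set.category_array(genome.id, glen)
        names = feature_set.CATEGORIES
    else:
        cats = np.zeros(glen, dtype=np.int8)
        names = ("intergenic",)
    fractions = {}
    for code, name in enumerate(names):
        denom = int((unf & (cats == code)).sum())
        if denom == 0:
            fractions[name] = float("nan")
        else:
            fractions[name] = int((flt & unf & (cats == code)).sum()) / denom
    total_denom = int(unf.sum())
    overall = (
        float("nan") if total_denom == 0 else int((flt & unf).sum()) / total_denom
    )
    return MappabilityReport(genome.id, fractions, overall)


def fragment_sequence(genome: Genome, fragment: AlignedFragment) -> str:
    """Fragment-oriented sequence (reverse-complemented for − placements)."""
    seq = genome.fetch(fragment.start, fragment.length)
    return revcomp(seq) if fragment.strand == "-" else seq


def write_bed(fragments: list[AlignedFragment], path) -> None:
    """Write mapped fragments as BED6 (score = weight × 1000)."""
    with open(path, "w") as fh:
        for f in fragments:
            if f.chrom is None:
                continue
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.read_id}"
                f"\t{int(round(f.weight * 1000))}\t{f.strand}\n"
            )
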