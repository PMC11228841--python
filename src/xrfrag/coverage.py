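"""RPKM coverage by genome and region, and strand-resolved comparisons.

Coverage is summarized as RPKM (reads per kilobase of target per million
mapped reads) with halving weights applied, so a collapsed duplication
does not double-count.  Reads are assigned to region categories by their
midpoint, which makes per-category counts a partition of per-genome
counts.  Template-vs-coding strand comparisons are normalized by the
di-pyrimidine content available to damage on each strand within the
category, since an excess of substrate alone would inflate one strand's
read count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import CATEGORIES, GENIC_CATEGORIES, FeatureSet
from .genome import Genome

__all__ = [
    "CoverageTable",
    "StrandReport",
    "rpkm",
    "assign_region",
    "coverage_table",
    "coverage_ratio",
    "strand_normalized_coverage",
    "per_position_coverage",
]


def rpkm(
    weighted_reads_in_target: float,
    target_length_nt: int,
    total_mapped_weighted_reads: float,
) -> float:
    """Reads per kilobase of target per million mapped reads."""
    if target_length_nt <= 0:
        raise ValueError("target length must be positive")
    if total_mapped_weighted_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return (
        weighted_reads_in_target
        / (target_length_nt / 1000.0)
        / (total_mapped_weighted_reads / 1e6)
    )


def assign_region(fragment, feature_set: FeatureSet, genome_length: int) -> str:
    """Region category of a fragment by its midpoint.

    Midpoints of origin-spanning fragments wrap modulo the genome length;
    unannotated positions are intergenic.  Overlapping annotations resolve
    by fixed priority (tRNA > rRNA > CDS > intron).
    """
    mid = fragment.midpoint % genome_length
    cats = feature_set.category_array(fragment.chrom, genome_length)
    return CATEGORIES[cats[mid]]


@dataclass
class CoverageTable:
    """RPKM per genome and per (genome, category), plus org/nuc ratios."""

    genome_rpkm: dict[str, float]
    genome_reads: dict[str, float]
    category_rpkm: dict[tuple[str, str], float]
    category_reads: dict[tuple[str, str], float]
    total_mapped: float
    org_nuc_ratio: dict[str, float] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for gid, v in self.genome_rpkm.items():
            rows.append(
                {
                    "genome": gid,
                    "category": "total",
                    "weighted_reads": self.genome_reads[gid],
                    "rpkm": v,
                    "org_nuc_ratio": self.org_nuc_ratio.get(gid, float("nan")),
                }
            )
        for (gid, cat), v in self.category_rpkm.items():
            rows.append(
                {
                    "genome": gid,
                    "category": cat,
                    "weighted_reads": self.category_reads[(gid, cat)],
                    "rpkm": v,
                    "org_nuc_ratio": float("nan"),
                }
            )
        return pd.DataFrame(rows)


def coverage_table(
    fragments,
    genomes: list[Genome],
    feature_set: FeatureSet | None = None,
) -> CoverageTable:
    """Weighted RPKM per genome and per region category.

    The RPKM denominator ("total mapped reads") is the weighted sum of
    all supplied fragments across all genomes, so compartments within one
    library are directly comparable.  Category lengths are full
    edited-reference lengths; mappability is reported separately.
    """
    by_id = {g.id: g for g in genomes}
    total = float(sum(f.weight for f in fragments if f.chrom in by_id))
    if total <= 0:
        raise ValueError("no mapped fragments")
    genome_reads = {g.id: 0.0 for g in genomes}
    category_reads = {
        (g.id, cat): 0.0 for g in genomes for cat in CATEGORIES
    }
    for f in fragments:
        g = by_id.get(f.chrom)
        if g is None:
            continue
        genome_reads[g.id] += f.weight
        if feature_set is not None:
            cat = assign_region(f, feature_set, len(g.seq))
            category_reads[(g.id, cat)] += f.weight
    genome_rpkm = {
        gid: rpkm(n, len(by_id[gid].seq), total) for gid, n in genome_reads.items()
    }
    category_rpkm = {}
    if feature_set is not None:
        for g in genomes:
            lengths = feature_set.category_lengths(g.id, len(g.seq))
            for cat in CATEGORIES:
                if lengths[cat] > 0:
                    category_rpkm[(g.id, cat)] = rpkm(
                        category_reads[(g.id, cat)], lengths[cat], total
                    )
    table = CoverageTable(
        genome_rpkm=genome_rpkm,
        genome_reads=genome_reads,
        category_rpkm=category_rpkm,
        category_reads={k: v for k, v in category_reads.items()},
        total_mapped=total,
    )
    nuclear_ids = [g.id for g in genomes if g.compartment == "nuclear"]
    if nuclear_ids:
        for g in genomes:
            if g.compartment != "nuclear":
                try:
                    table.org_nuc_ratio[g.id] = coverage_ratio(
                        table, g.id, nuclear_ids, by_id
                    )
                except ValueError:
                    pass
    return table


def coverage_ratio(
    table: CoverageTable,
    organellar_id: str,
    nuclear_ids: list[str],
    genomes_by_id: dict[str, Genome] | None = None,
) -> float:
    """Organellar / nuclear RPKM ratio.

    Nuclear RPKM pools reads and lengths over all nuclear chromosomes so
    the ratio is a single scalar per organellar genome.
    """
    nuc_reads = sum(table.genome_reads[g] for g in nuclear_ids)
    if genomes_by_id is not None:
        nuc_len = sum(len(genomes_by_id[g].seq) for g in nuclear_ids)
        nuc_rpkm = rpkm(nuc_reads, nuc_len, table.total_mapped)
    else:
        if len(nuclear_ids) != 1:
            raise ValueError("need genome lengths to pool several nuclear ids")
        nuc_rpkm = table.genome_rpkm[nuclear_ids[0]]
    if nuc_rpkm <= 0:
        raise ValueError("nuclear RPKM is zero")
    return table.genome_rpkm[organellar_id] / nuc_rpkm


@dataclass
class StrandReport:
    """Template vs coding strand coverage, normalized by substrate.

    ``rows`` maps (genome, category) → dict with weighted template/coding
    read counts, template/coding di-pyrimidine counts, and the normalized
    ratio (template rate over coding rate); the ratio is NaN when either
    substrate count is zero.
    """

    rows: dict[tuple[str, str], dict]

    def ratio(self, genome_id: str, category: str) -> float:
        return self.rows[(genome_id, category)]["normalized_ratio"]

    def to_frame(self):
        import pandas as pd

        out = []
        for (gid, cat), row in self.rows.items():
            out.append({"genome": gid, "category": cat, **row})
        return pd.DataFrame(out)


def strand_normalized_coverage(
    fragments,
    feature_set: FeatureSet,
    genome: Genome,
    dipyr_set: tuple[str, ...] = ("TT",),
) -> StrandReport:
    """Template/coding strand read counts normalized by di-pyrimidines.

    A fragment is template-strand when its mapped strand is opposite the
    feature strand at its midpoint (the template is the strand read by
    the polymerase, complementary to the transcript).  Counts are divided
    by the number of di-pyrimidines available on the corresponding strand
    within the category, and the report's ratio is (template rate) /
    (coding rate).  Genic categories only.
    """
    glen = len(genome.seq)
    cats = feature_set.category_array(genome.id, glen)
    strands = feature_set.strand_array(genome.id, glen)

    rows: dict[tuple[str, str], dict] = {}
    for cat in GENIC_CATEGORIES:
        code = CATEGORIES.index(cat)
        template_reads = coding_reads = 0.0
        for f in fragments:
            if f.chrom != genome.id:
                continue
            mid = f.midpoint % glen
            if cats[mid] != code or strands[mid] == 0:
                continue
            feat_strand = "+" if strands[mid] > 0 else "-"
            if f.strand != feat_strand:
                template_reads += f.weight
            else:
                coding_reads += f.weight
        # substrate on coding vs template strand, summed over features:
        # + features: coding substrate = forward occurrences, template =
        # reverse; − features: the reverse.  Split the category's windows
        # by feature strand.
        mask_plus = (cats == code) & (strands > 0)
        mask_minus = (cats == code) & (strands < 0)
        cod_sub = tmp_sub = 0
        for d in dipyr_set:
            fwd, rev = _masked_dinuc_counts(genome, d)
            cod_sub += _sum_windows(fwd, mask_plus) + _sum_windows(rev, mask_minus)
            tmp_sub += _sum_windows(rev, mask_plus) + _sum_windows(fwd, mask_minus)
        if tmp_sub > 0 and cod_sub > 0:
            ratio = (template_reads / tmp_sub) / (coding_reads / cod_sub) \
                if coding_reads > 0 else float("inf") if template_reads > 0 \
                else float("nan")
        else:
            ratio = float("nan")
        rows[(genome.id, cat)] = {
            "template_count": template_reads,
            "coding_count": coding_reads,
            "template_dipyr": tmp_sub,
            "coding_dipyr": cod_sub,
            "normalized_ratio": ratio,
        }
    return StrandReport(rows)


def _masked_dinuc_counts(genome: Genome, dinuc: str):
    """Boolean window arrays: forward-strand and reverse-strand matches."""
    from .genome import _window_arrays, revcomp

    first, second = _window_arrays(genome)
    rc = revcomp(dinuc)
    n_code = ord("N")
    valid = (first != n_code) & (second != n_code)
    fwd = (first == ord(dinuc[0])) & (second == ord(dinuc[1])) & valid
    rev = (first == ord(rc[0])) & (second == ord(rc[1])) & valid
    return fwd, rev


def _sum_windows(window_hits: np.ndarray, position_mask: np.ndarray) -> int:
    """Count hit windows lying fully inside the masked positions.

    The both-ends-inside rule keeps substrate counts symmetric under
    strand complementation, so normalized ratios are flip-invariant.
    """
    n = len(position_mask)
    if len(window_hits) == n:  # circular: window i pairs i with (i+1) mod n
        pair_ok = position_mask & np.roll(position_mask, -1)
    else:
        pair_ok = position_mask[:-1] & position_mask[1:]
    return int((window_hits & pair_ok).sum())


def per_position_coverage(fragments, genome: Genome) -> np.ndarray:
    """Weighted per-position coverage depth (wrapping on circular genomes)."""
    glen = len(genome.seq)
    cov = np.zeros(glen, dtype=float)
    for f in fragments:
        if f.chrom != genome.id:
            continue
        if f.end <= glen:
            cov[f.start : f.end] += f.weight
        else:
            cov[f.start :] += f.weight
            cov[: f.end - glen] += f.weight
    return cov
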