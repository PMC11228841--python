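"""Reference genomes for organellar excision-fragment analysis.

A :class:`Genome` couples a DNA sequence with its topology (organellar
genomes are circular) and its cellular compartment (nuclear, mitochondrial
or plastid).  Two kinds of user-declared reference edits are supported,
mirroring common preprocessing of organellar references before
uniqueness-based read filtering:

* ``remove_interval`` — physically delete a span (e.g. the second copy of a
  plastid inverted repeat, or a large NUMT from a nuclear chromosome) while
  retaining an invertible coordinate map between the original and the
  edited sequence;
* ``halve_count_interval`` — leave the sequence untouched but mark a span
  (the retained inverted-repeat copy) whose reads should carry weight 1/2
  in all downstream counting, since they collapse two original copies onto
  one.

The module also computes genome-wide dinucleotide statistics.  The
forward-strand TT frequency of an organellar genome is the null expectation
against which positional TT enrichment in excision fragments is judged.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Genome",
    "AppliedEdit",
    "CoordinateMap",
    "DinucStats",
    "load_genomes",
    "apply_reference_edits",
    "dinucleotide_frequency",
    "dinucleotide_frequency_table",
    "region_dinuc_counts",
    "revcomp",
    "DINUCLEOTIDES",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: All 16 dinucleotides over {A, C, G, T}, lexicographic.
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

VALID_TOPOLOGIES = ("circular", "linear")
VALID_COMPARTMENTS = ("nuclear", "mito", "plastid")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A, C, G, T, N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AppliedEdit:
    """A declared reference edit on 1-based inclusive original coordinates.

    ``kind`` is ``"remove_interval"`` or ``"halve_count_interval"``;
    ``start``/``end`` follow the 1-based inclusive convention used when
    citing genome positions (converted to 0-based half-open internally).
    """

    kind: str
    start: int
    end: int
    reason: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("remove_interval", "halve_count_interval"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid 1-based inclusive interval [{self.start}, {self.end}]"
            )

    @property
    def interval0(self) -> tuple[int, int]:
        """The edit interval as 0-based half-open ``(start, end)``."""
        return self.start - 1, self.end


class CoordinateMap:
    """Invertible position map between an original and an edited sequence.

    Built from non-overlapping removed intervals (0-based half-open on the
    original coordinate system).  Positions inside removed intervals have
    no image; all other positions round-trip exactly.
    """

    def __init__(self, removed: list[tuple[int, int]], original_length: int):
        removed = sorted(removed)
        for (s1, e1), (s2, e2) in zip(removed, removed[1:]):
            if s2 < e1:
                raise ValueError("removed intervals overlap")
        self.removed = removed
        self.original_length = original_length
        # cumulative removed length before each interval start
        self._starts = [s for s, _ in removed]
        self._cum = []
        total = 0
        for s, e in removed:
            self._cum.append(total)
            total += e - s
        self.removed_total = total

    def old_to_new(self, pos: int) -> int | None:
        """Map an original position to the edited sequence (None if removed)."""
        i = bisect.bisect_right(self._starts, pos) - 1
        if i >= 0:
            s, e = self.removed[i]
            if pos < e:
                return None
            return pos - (self._cum[i] + (e - s))
        return pos

    def new_to_old(self, pos: int) -> int:
        """Map an edited-sequence position back to the original."""
        if pos < 0 or pos >= self.original_length - self.removed_total:
            raise IndexError(f"position {pos} outside edited sequence")
        shift = 0
        for s, e in self.removed:
            if pos + shift >= s:
                shift += e - s
            else:
                break
        return pos + shift


@dataclass
class Genome:
    """A reference sequence with topology, compartment and edit history.

    ``halved_intervals`` are 0-based half-open spans *on the current
    (edited) coordinate system* whose overlapping reads count 1/2.
    """

    id: str
    seq: str
    topology: str = "linear"
    compartment: str = "nuclear"
    edits: list[AppliedEdit] = field(default_factory=list)
    coord_map: CoordinateMap | None = None
    halved_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        if self.topology not in VALID_TOPOLOGIES:
            raise ValueError(f"genome {self.id!r}: bad topology {self.topology!r}")
        if self.compartment not in VALID_COMPARTMENTS:
            raise ValueError(
                f"genome {self.id!r}: bad compartment {self.compartment!r}"
            )
        self.seq = self.seq.upper()
        bad = set(self.seq) - set("ACGTN")
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"genome {self.id!r}: invalid character {self.seq[pos]!r} "
                f"at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, length: int) -> str:
        """Extract ``length`` bases from 0-based ``start``, wrapping if circular."""
        n = len(self.seq)
        if self.is_circular:
            start %= n
            if start + length <= n:
                return self.seq[start : start + length]
            if length > n:
                raise ValueError("fetch longer than circular genome")
            return self.seq[start:] + self.seq[: start + length - n]
        if start < 0 or start + length > n:
            raise IndexError(
                f"[{start}, {start + length}) outside linear genome {self.id!r}"
            )
        return self.seq[start : start + length]


def load_genomes(
    fasta_paths,
    topology_map: dict[str, str],
    compartment_map: dict[str, str],
) -> list[Genome]:
    """Load genomes from FASTA files, assigning topology and compartment.

    Every record id must appear in both maps; duplicate ids across files
    are rejected.  Sequences are uppercased and validated over {A,C,G,T,N}.
    """
    from Bio import SeqIO

    if isinstance(fasta_paths, (str, bytes)) or hasattr(fasta_paths, "__fspath__"):
        fasta_paths = [fasta_paths]
    genomes: list[Genome] = []
    seen: set[str] = set()
    for path in fasta_paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if rec.id not in topology_map:
                raise ValueError(f"no topology assigned for {rec.id!r}")
            if rec.id not in compartment_map:
                raise ValueError(f"no compartment assigned for {rec.id!r}")
            genomes.append(
                Genome(
                    id=rec.id,
                    seq=str(rec.seq),
                    topology=topology_map[rec.id],
                    compartment=compartment_map[rec.id],
                )
            )
    if not genomes:
        raise ValueError("no records found in FASTA input")
    return genomes


def apply_reference_edits(genome: Genome, edits: list[AppliedEdit]) -> Genome:
    """Apply declared edits, returning a new genome with a coordinate map.

    ``remove_interval`` edits delete their spans and shift downstream
    coordinates; the old→new map is retained and invertible for all
    unremoved positions.  ``halve_count_interval`` edits leave the sequence
    unchanged and record (on edited coordinates) the spans whose reads are
    later down-weighted by 1/2.
    """
    n = len(genome.seq)
    intervals = []
    for e in edits:
        s, t = e.interval0
        if t > n:
            raise ValueError(f"edit [{e.start}, {e.end}] outside genome of length {n}")
        intervals.append((s, t, e))
    intervals.sort()
    for (s1, e1, _), (s2, e2, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("edits overlap")

    removed = [(s, t) for s, t, e in intervals if e.kind == "remove_interval"]
    cmap = CoordinateMap(removed, n)
    pieces, prev = [], 0
    for s, t in removed:
        pieces.append(genome.seq[prev:s])
        prev = t
    pieces.append(genome.seq[prev:])
    new_seq = "".join(pieces)
    if not new_seq:
        raise ValueError("edits remove the entire genome")

    halved = []
    for s, t, e in intervals:
        if e.kind != "halve_count_interval":
            continue
        ns, nt = cmap.old_to_new(s), cmap.old_to_new(t - 1)
        if ns is None or nt is None:
            raise ValueError("halve_count_interval overlaps a removed interval")
        halved.append((ns, nt + 1))

    return replace(
        genome,
        seq=new_seq,
        edits=list(genome.edits) + [e for _, _, e in intervals],
        coord_map=cmap,
        halved_intervals=list(genome.halved_intervals) + halved,
    )


def _window_arrays(genome: Genome):
    """First/second base arrays for all overlapping dinucleotide windows.

    Linear genomes yield L−1 windows; circular genomes add the single
    wraparound window (last base, first base) for L windows in total.
    """
    arr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)
    if genome.is_circular:
        first = arr
        second = np.roll(arr, -1)
    else:
        first = arr[:-1]
        second = arr[1:]
    return first, second


def dinucleotide_frequency(genome: Genome, dinuc: str) -> float:
    """Frequency of ``dinuc`` among overlapping forward-strand windows.

    The denominator is L−1 for linear genomes and L for circular genomes
    (the origin-spanning window is included).  Windows containing N are
    excluded from numerator and denominator alike.
    """
    if len(genome.seq) < 2:
        raise ValueError("genome shorter than 2 nt")
    dinuc = dinuc.upper()
    if len(dinuc) != 2 or any(c not in "ACGT" for c in dinuc):
        raise ValueError(f"invalid dinucleotide {dinuc!r}")
    first, second = _window_arrays(genome)
    n_code = ord("N")
    valid = (first != n_code) & (second != n_code)
    denom = int(valid.sum())
    if denom == 0:
        raise ValueError("no valid dinucleotide windows (all contain N)")
    hits = (first == ord(dinuc[0])) & (second == ord(dinuc[1])) & valid
    return int(hits.sum()) / denom


def dinucleotide_frequency_table(genome: Genome) -> dict[str, float]:
    """Frequencies of all 16 forward-strand dinucleotides (they sum to 1)."""
    return {d: dinucleotide_frequency(genome, d) for d in DINUCLEOTIDES}


def region_dinuc_counts(genome: Genome, feature_set, dinuc: str) -> dict:
    """Per-category, per-strand counts of a dinucleotide.

    For each region category the + strand count is the number of windows
    matching ``dinuc`` on the forward strand, and the − strand count the
    number matching its reverse complement (i.e. occurrences of ``dinuc``
    read on the minus strand).  A window is assigned to the category of
    its first base, so per-category counts partition the genome-wide
    count exactly.  Returns ``{category: (plus_count, minus_count)}``.
    """
    dinuc = dinuc.upper()
    rc = revcomp(dinuc)
    cats = feature_set.category_array(genome.id, len(genome.seq))
    first, second = _window_arrays(genome)
    cat_first = cats if genome.is_circular else cats[:-1]
    n_code = ord("N")
    valid = (first != n_code) & (second != n_code)
    plus = (first == ord(dinuc[0])) & (second == ord(dinuc[1])) & valid
    minus = (first == ord(rc[0])) & (second == ord(rc[1])) & valid
    out = {}
    for code, name in enumerate(feature_set.CATEGORIES):
        mask = cat_first == code
        out[name] = (int((plus & mask).sum()), int((minus & mask).sum()))
    return out


@dataclass
class DinucStats:
    """Genome-wide dinucleotide statistics (forward-strand frequencies plus
    per-region per-strand counts for one dinucleotide of interest)."""

    genome_id: str
    frequencies: dict[str, float]
    region_counts: dict[str, tuple[int, int]] | None = None

    @classmethod
    def from_genome(cls, genome: Genome, feature_set=None, dinuc: str = "TT"):
        freqs = dinucleotide_frequency_table(genome)
        region = (
            region_dinuc_counts(genome, feature_set, dinuc)
            if feature_set is not None
            else None
        )
        return cls(genome.id, freqs, region)

    def to_frame(self):
        import pandas as pd

        rows = [
            {"genome": self.genome_id, "dinucleotide": d, "frequency": f}
            for d, f in self.frequencies.items()
        ]
        return pd.DataFrame(rows)
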