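"""Synthetic damage-anchored fragment libraries with ground truth.

The generator emulates the statistical structure of UV-damage
excision-fragment (XR-seq) libraries from small organellar genomes:

* random genomes of configurable AT content and topology (organellar
  genomes are AT-rich and circular);
* nuclear sequence carrying planted organellar duplications (NUMT/NUPT
  analogues) at configurable divergence, the source of multimapping reads;
* fragment libraries in which every read contains a TT dimer at a fixed
  distance from its 3′ end, under one of two generative mechanisms:

  - ``fixed_incision``: incisions at varying distances upstream of the
    dimer release fragments of several lengths, each keeping the dimer at
    the same offset from the 3′ end;
  - ``five_prime_trim``: a primary fragment of one length is shortened
    from the 5′ end in fixed steps, which produces the identical 3′-anchored
    geometry by degradation instead of incision.

Both mechanisms predict that TT peak positions in length classes coincide
when reads are right (3′) aligned — the key recoverable signature.

Reads are emitted in fragment orientation (5′→3′ of the excised strand)
with a literal 3′ sequencing adapter appended, and every read's true
origin (genome, strand, interval, dimer position) is logged for
downstream recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .genome import Genome, revcomp

__all__ = [
    "DamageModel",
    "FragmentTruth",
    "FastqRead",
    "DEFAULT_ADAPTER",
    "make_random_genome",
    "plant_duplication",
    "simulate_fragments",
    "write_fastq",
    "read_fastq",
    "write_fasta",
    "write_truth",
    "read_truth",
]

#: Illumina TruSeq 3′ adapter prefix, the default ligated suffix.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass(frozen=True)
class DamageModel:
    """Generative model for damage-anchored fragments.

    ``dimer_offset_3p`` places the dimer's 3′ base among the last
    ``dimer_offset_3p`` bases of the fragment: the TT pair occupies
    1-based read positions (L − offset, L − offset + 1).  With the default
    primary length 26 and offset 19 the pair sits at positions 7–8, and
    5′-shortening by 2 nt moves it to 5–6, 3–4, 1–2 in the 24-, 22-,
    20-nt classes — i.e. the same right-aligned position throughout.
    """

    mechanism: str = "fixed_incision"
    primary_length: int = 26
    trim_step: int = 2
    trim_max_steps: int = 0
    dimer_offset_3p: int = 19
    length_weights: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("fixed_incision", "five_prime_trim"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.primary_length < self.dimer_offset_3p + 2:
            raise ValueError("primary_length must be >= dimer_offset_3p + 2")
        if self.trim_max_steps < 0 or self.trim_step < 0:
            raise ValueError("trim parameters must be nonnegative")
        weights = self.length_weights
        if weights is None:
            if self.mechanism == "fixed_incision":
                lengths = [self.primary_length]
            else:
                lengths = [
                    self.primary_length - k * self.trim_step
                    for k in range(self.trim_max_steps + 1)
                ]
            weights = {L: 1.0 / len(lengths) for L in lengths}
            object.__setattr__(self, "length_weights", weights)
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ValueError("length_weights must sum to 1")
        for L in weights:
            if L < self.dimer_offset_3p + 1:
                raise ValueError(
                    f"length {L} cannot hold a dimer at 3' offset "
                    f"{self.dimer_offset_3p}"
                )

    def dimer_position(self, length: int) -> int:
        """1-based read position of the dimer's 5′ base in a fragment."""
        return length - self.dimer_offset_3p


class FastqRead(NamedTuple):
    """One sequencing read (constant Phred quality unless stated)."""

    id: str
    seq: str
    qual: str

    @classmethod
    def make(cls, read_id: str, seq: str, qual_char: str = "I") -> "FastqRead":
        return cls(read_id, seq, qual_char * len(seq))


@dataclass(frozen=True)
class FragmentTruth:
    """Ground truth for one simulated fragment.

    ``start`` is the 0-based forward-strand position of the fragment's
    leftmost base; on circular genomes ``start + length`` may exceed the
    genome length, denoting an origin-spanning fragment.  ``dimer_pos`` is
    the 1-based read position of the TT pair's first base.
    """

    read_id: str
    genome_id: str
    strand: str
    start: int
    length: int
    dimer_pos: int


def make_random_genome(
    length: int,
    at_fraction: float,
    topology: str,
    seed: int,
    genome_id: str = "synthetic",
    compartment: str = "mito",
) -> Genome:
    """I.i.d. random genome with P(A)=P(T)=at_fraction/2."""
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must be in [0, 1]")
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = np.random.default_rng(seed)
    p_at = at_fraction / 2.0
    p_gc = (1.0 - at_fraction) / 2.0
    bases = rng.choice(np.array(list("ATCG")), size=length, p=[p_at, p_at, p_gc, p_gc])
    return Genome(
        id=genome_id, seq="".join(bases), topology=topology, compartment=compartment
    )


@dataclass(frozen=True)
class PlantedDuplication:
    """Truth record for one planted organellar insertion."""

    donor_id: str
    donor_start: int
    donor_end: int
    insertion_site: int
    inserted_start: int
    inserted_end: int
    n_substitutions: int


def plant_duplication(
    nuclear_genome: Genome,
    donor_genome: Genome,
    donor_interval: tuple[int, int],
    insertion_site: int,
    divergence_rate: float,
    seed: int,
) -> tuple[Genome, PlantedDuplication]:
    """Insert a (possibly diverged) copy of a donor segment into a genome.

    Emulates a NUMT/NUPT: a nuclear copy of organellar sequence whose reads
    multimap unless divergence makes placements distinguishable.  Intervals
    are 0-based half-open.  Returns the modified genome and a truth record.
    """
    s, e = donor_interval
    if not (0 <= s < e <= len(donor_genome.seq)):
        raise ValueError(f"donor interval [{s}, {e}) out of bounds")
    if not 0.0 <= divergence_rate <= 0.25:
        raise ValueError("divergence_rate must be in [0, 0.25]")
    if not 0 <= insertion_site <= len(nuclear_genome.seq):
        raise ValueError("insertion site out of bounds")
    rng = np.random.default_rng(seed)
    segment = list(donor_genome.seq[s:e])
    n_subs = 0
    if divergence_rate > 0:
        hits = rng.random(len(segment)) < divergence_rate
        for i in np.nonzero(hits)[0]:
            alternatives = [b for b in "ACGT" if b != segment[i]]
            segment[i] = alternatives[rng.integers(3)]
            n_subs += 1
    inserted = "".join(segment)
    new_seq = (
        nuclear_genome.seq[:insertion_site] + inserted + nuclear_genome.seq[insertion_site:]
    )
    truth = PlantedDuplication(
        donor_id=donor_genome.id,
        donor_start=s,
        donor_end=e,
        insertion_site=insertion_site,
        inserted_start=insertion_site,
        inserted_end=insertion_site + len(inserted),
        n_substitutions=n_subs,
    )
    from dataclasses import replace

    return replace(nuclear_genome, seq=new_seq), truth


def _dimer_sites(genome: Genome) -> tuple[np.ndarray, np.ndarray]:
    """0-based positions of TT (plus strand) and AA (minus-strand TT)."""
    arr = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)
    if genome.is_circular:
        first, second = arr, np.roll(arr, -1)
    else:
        first, second = arr[:-1], arr[1:]
    t, a = ord("T"), ord("A")
    plus = np.nonzero((first == t) & (second == t))[0]
    minus = np.nonzero((first == a) & (second == a))[0]
    return plus, minus


def simulate_fragments(
    genome: Genome,
    damage_model: DamageModel,
    n_reads: int,
    seed: int,
    adapter: str = DEFAULT_ADAPTER,
    read_prefix: str = "frag",
    max_resamples: int = 1000,
) -> tuple[list[FastqRead], list[FragmentTruth]]:
    """Simulate a damage-anchored fragment library with ground truth.

    Each read picks a strand uniformly, then a TT site uniformly on that
    strand, draws a length from the damage model, and lays the fragment
    out so the dimer's 3′ base sits ``dimer_offset_3p`` bases from the
    fragment's 3′ end.  Fragments that would run off a linear genome are
    resampled (the count is tracked on the returned list as
    ``simulate_fragments.last_resamples``).  Emitted reads are
    fragment + adapter at constant quality.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    plus_sites, minus_sites = _dimer_sites(genome)
    if len(plus_sites) == 0 or len(minus_sites) == 0:
        raise ValueError("genome lacks a TT site on one or both strands")
    rng = np.random.default_rng(seed)
    lengths = np.array(sorted(damage_model.length_weights))
    probs = np.array([damage_model.length_weights[L] for L in lengths])
    glen = len(genome.seq)

    reads: list[FastqRead] = []
    truths: list[FragmentTruth] = []
    resamples = 0
    for i in range(n_reads):
        for _attempt in range(max_resamples):
            strand = "+" if rng.random() < 0.5 else "-"
            L = int(rng.choice(lengths, p=probs))
            i0 = damage_model.dimer_position(L) - 1  # 0-based read index
            if strand == "+":
                site = int(plus_sites[rng.integers(len(plus_sites))])
                start = site - i0
            else:
                site = int(minus_sites[rng.integers(len(minus_sites))])
                start = site + i0 + 2 - L
            if genome.is_circular:
                start %= glen
            elif start < 0 or start + L > glen:
                resamples += 1
                continue
            frag = genome.fetch(start, L)
            if strand == "-":
                frag = revcomp(frag)
            dimer_pos = damage_model.dimer_position(L)
            assert frag[dimer_pos - 1 : dimer_pos + 1] == "TT"
            rid = f"{read_prefix}_{i}"
            reads.append(FastqRead.make(rid, frag + adapter))
            truths.append(
                FragmentTruth(
                    read_id=rid,
                    genome_id=genome.id,
                    strand=strand,
                    start=start,
                    length=L,
                    dimer_pos=dimer_pos,
                )
            )
            break
        else:
            raise RuntimeError("could not place a fragment within resample budget")
    simulate_fragments.last_resamples = resamples
    return reads, truths


# --------------------------------------------------------------------- I/O


def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path) -> list[FastqRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(FastqRead(rec.id, str(rec.seq), qual))
    return out


def write_fasta(genomes: list[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


_TRUTH_COLUMNS = ["read_id", "genome_id", "strand", "start", "length", "dimer_pos"]


def write_truth(truth_list: list[FragmentTruth], path) -> None:
    """Write ground-truth records as TSV (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truth_list:
            fh.write(
                f"{t.read_id}\t{t.genome_id}\t{t.strand}\t{t.start}"
                f"\t{t.length}\t{t.dimer_pos}\n"
            )


def read_truth(path) -> list[FragmentTruth]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "genome_id": str})
    return [
        FragmentTruth(
            read_id=row.read_id,
            genome_id=row.genome_id,
            strand=row.strand,
            start=int(row.start),
            length=int(row.length),
            dimer_pos=int(row.dimer_pos),
        )
        for row in df.itertuples()
    ]
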