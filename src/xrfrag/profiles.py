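"""Length spectra and anchored positional nucleotide/di-pyrimidine profiles.

Excision fragments released after UV damage show characteristic length
distributions (discrete peaks at regular intervals) and a non-random
placement of TT di-pyrimidines within reads of a given length.  The TT
frequency at read position p (the pair occupying positions p, p+1 on the
read's 5′→3′ axis) is compared against a genome-wide null p0 — the
forward-strand TT frequency of the source genome — with an approximate
95% confidence band of two standard errors,

    ci_half_width = 2 · sqrt(p0 · (1 − p0) / n),

n being the number of reads in the length class.  Observed frequencies
above p0 + ci_half_width are called enriched.

Profiles of different length classes can be reported on a shared
right-aligned (3′-anchored) axis: when fragments of several lengths share
a fixed dimer-to-3′-end geometry, their TT peaks coincide on that axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import DINUCLEOTIDES

__all__ = [
    "LengthSpectrum",
    "DinucProfile",
    "NucProfile",
    "EnrichmentCall",
    "ci_half_width",
    "length_spectrum",
    "spectrum_correlation",
    "positional_dinuc_profile",
    "positional_nuc_profile",
    "call_enrichment",
]

PYRIMIDINE_DINUCS = ("TT", "TC", "CT", "CC")


def ci_half_width(p0: float, n: float) -> float:
    """Half-width of the ≈95% null band: two standard errors of p0 at n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    return 2.0 * math.sqrt(p0 * (1.0 - p0) / n)


@dataclass
class LengthSpectrum:
    """Weighted read-length histogram for one compartment."""

    compartment: str
    counts: dict[int, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def frequencies(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            return {}
        return {L: c / t for L, c in sorted(self.counts.items())}

    def to_frame(self):
        import pandas as pd

        freqs = self.frequencies
        return pd.DataFrame(
            [
                {
                    "compartment": self.compartment,
                    "length": L,
                    "count": self.counts[L],
                    "frequency": freqs.get(L, 0.0),
                }
                for L in sorted(self.counts)
            ]
        )


def length_spectrum(
    fragments,
    compartment_of_chrom: dict[str, str],
    min_len: int | None = None,
    max_len: int | None = None,
) -> dict[str, LengthSpectrum]:
    """Per-compartment weighted length spectra from filtered fragments.

    With ``min_len``/``max_len`` the spectra carry explicit zero-count
    bins over the whole range, so spectra of different samples share a
    common axis for correlation.
    """
    spectra: dict[str, LengthSpectrum] = {}
    for comp in set(compartment_of_chrom.values()):
        spectra[comp] = LengthSpectrum(comp)
    if min_len is not None and max_len is not None:
        for spec in spectra.values():
            for L in range(min_len, max_len + 1):
                spec.counts[L] = 0.0
    for f in fragments:
        comp = compartment_of_chrom.get(f.chrom)
        if comp is None:
            continue
        spec = spectra.setdefault(comp, LengthSpectrum(comp))
        spec.counts[f.length] = spec.counts.get(f.length, 0.0) + f.weight
    return spectra


def spectrum_correlation(
    spec_a: LengthSpectrum, spec_b: LengthSpectrum
) -> tuple[float, float]:
    """Pearson R (and p-value) between two spectra over the bin union.

    Bins absent from one spectrum contribute frequency 0.  Fewer than
    three union bins leave the correlation undefined.
    """
    from scipy import stats

    fa, fb = spec_a.frequencies, spec_b.frequencies
    bins = sorted(set(fa) | set(fb))
    if len(bins) < 3:
        raise ValueError("need at least 3 length bins to correlate")
    xa = np.array([fa.get(L, 0.0) for L in bins])
    xb = np.array([fb.get(L, 0.0) for L in bins])
    r = stats.pearsonr(xa, xb)
    return float(r.statistic), float(r.pvalue)


@dataclass
class DinucProfile:
    """Positional dinucleotide frequencies for one read-length class.

    ``freqs[p][d]`` is the weighted frequency of dinucleotide ``d`` at
    1-based pair position p ∈ 1..L−1 on the read's 5′→3′ axis.  With a
    genome null ``null_p0`` the two-standard-error band half-width is
    stored for enrichment calls.  ``flagged_low_n`` marks classes below
    the minimum read count considered profile-worthy.
    """

    length: int
    anchor: str
    freqs: dict[int, dict[str, float]]
    n_reads: float
    null_p0: float | None = None
    ci: float | None = None
    flagged_low_n: bool = False

    def frequency(self, position: int, dinuc: str = "TT") -> float:
        return self.freqs[position].get(dinuc, 0.0)

    def argmax_position(self, dinuc: str = "TT") -> int:
        """1-based pair position with the highest frequency of ``dinuc``."""
        return max(self.freqs, key=lambda p: (self.freqs[p].get(dinuc, 0.0), -p))

    def offset_from_3p(self, position: int) -> int:
        """Distance from the pair's 3′ base to the read's 3′ end.

        Equal across length classes when profiles are right aligned: the
        pair at position p covers (p, p+1), so the offset is L − p.
        """
        return self.length - position

    def shared_axis_position(self, position: int, length_max: int) -> int:
        """Position on a shared axis across length classes.

        For a 3′ (right-aligned) anchor the axis is that of the longest
        class, offset by length_max − L; a 5′ anchor leaves positions as
        they are.
        """
        if self.anchor == "three_prime":
            return position + (length_max - self.length)
        return position

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in sorted(self.freqs):
            for d, v in self.freqs[p].items():
                rows.append(
                    {
                        "length": self.length,
                        "anchor": self.anchor,
                        "position": p,
                        "dinucleotide": d,
                        "frequency": v,
                    }
                )
        return pd.DataFrame(rows)


def positional_dinuc_profile(
    fragments,
    sequences: list[str],
    length: int,
    anchor: str = "five_prime",
    null_p0: float | None = None,
    min_reads: int = 100,
) -> DinucProfile:
    """Weighted per-position dinucleotide frequencies for one length class.

    ``sequences`` are fragment-oriented (already reverse-complemented for
    − strand placements) and parallel to ``fragments``.  All fragments
    must have the stated length.  Frequencies at each pair position sum
    to 1 over the 16 dinucleotides.
    """
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"invalid anchor {anchor!r}")
    if len(fragments) != len(sequences):
        raise ValueError("fragments and sequences must be parallel")
    if not fragments:
        raise ValueError("no fragments supplied")
    counts = {p: {d: 0.0 for d in DINUCLEOTIDES} for p in range(1, length)}
    total_w = 0.0
    for f, seq in zip(fragments, sequences):
        if f.length != length or len(seq) != length:
            raise ValueError(
                f"fragment {f.read_id!r} has length {f.length}, expected {length}"
            )
        total_w += f.weight
        for p in range(1, length):
            d = seq[p - 1 : p + 1]
            if d in counts[p]:
                counts[p][d] += f.weight
    freqs = {
        p: {d: c / total_w for d, c in by_d.items()} for p, by_d in counts.items()
    }
    ci = ci_half_width(null_p0, total_w) if null_p0 is not None else None
    return DinucProfile(
        length=length,
        anchor=anchor,
        freqs=freqs,
        n_reads=total_w,
        null_p0=null_p0,
        ci=ci,
        flagged_low_n=total_w < min_reads,
    )


@dataclass
class NucProfile:
    """Per-position mononucleotide frequencies for one length class."""

    length: int
    anchor: str
    freqs: dict[int, dict[str, float]]
    n_reads: float

    def frequency(self, position: int, base: str) -> float:
        return self.freqs[position].get(base, 0.0)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in sorted(self.freqs):
            for b, v in self.freqs[p].items():
                rows.append(
                    {
                        "length": self.length,
                        "anchor": self.anchor,
                        "position": p,
                        "base": b,
                        "frequency": v,
                    }
                )
        return pd.DataFrame(rows)


def positional_nuc_profile(
    fragments, sequences: list[str], length: int, anchor: str = "five_prime"
) -> NucProfile:
    """Weighted per-position A/C/G/T frequencies (positions 1..L)."""
    if anchor not in ("five_prime", "three_prime"):
        raise ValueError(f"invalid anchor {anchor!r}")
    if not fragments:
        raise ValueError("no fragments supplied")
    counts = {p: {b: 0.0 for b in "ACGT"} for p in range(1, length + 1)}
    total_w = 0.0
    for f, seq in zip(fragments, sequences):
        if f.length != length or len(seq) != length:
            raise ValueError(
                f"fragment {f.read_id!r} has length {f.length}, expected {length}"
            )
        total_w += f.weight
        for p in range(1, length + 1):
            b = seq[p - 1]
            if b in counts[p]:
                counts[p][b] += f.weight
    freqs = {
        p: {b: c / total_w for b, c in by_b.items()} for p, by_b in counts.items()
    }
    return NucProfile(length=length, anchor=anchor, freqs=freqs, n_reads=total_w)


@dataclass(frozen=True)
class EnrichmentCall:
    """Significance of one (position, dinucleotide) against the null band."""

    length: int
    position: int
    dinucleotide: str
    observed: float
    null_p0: float
    significant: bool


def call_enrichment(
    profile: DinucProfile, dinucs: tuple[str, ...] = ("TT",)
) -> list[EnrichmentCall]:
    """Call positions whose observed frequency exceeds p0 + 2·SE."""
    if profile.null_p0 is None or profile.ci is None:
        raise ValueError("profile lacks a null expectation")
    if profile.n_reads <= 0:
        raise ValueError("profile has no reads")
    calls = []
    threshold = profile.null_p0 + profile.ci
    for p in sorted(profile.freqs):
        for d in dinucs:
            obs = profile.freqs[p].get(d, 0.0)
            calls.append(
                EnrichmentCall(
                    length=profile.length,
                    position=p,
                    dinucleotide=d,
                    observed=obs,
                    null_p0=profile.null_p0,
                    significant=obs > threshold,
                )
            )
    return calls
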