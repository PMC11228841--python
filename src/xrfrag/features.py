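"""Typed, stranded genomic intervals defining region categories.

Every genomic position resolves to exactly one of five categories —
intergenic, intron, CDS, rRNA, tRNA — with overlaps broken by a fixed
priority (tRNA > rRNA > CDS > intron > intergenic; the smallest, most
specific feature wins).  Intergenic space is the complement of all
features and never needs to be annotated explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Feature", "FeatureSet", "CATEGORIES", "GENIC_CATEGORIES"]

CATEGORIES = ("intergenic", "intron", "CDS", "rRNA", "tRNA")
GENIC_CATEGORIES = ("intron", "CDS", "rRNA", "tRNA")
# paint order: later paints overwrite earlier ones, so the last has priority
_PAINT_ORDER = ("intron", "CDS", "rRNA", "tRNA")


@dataclass(frozen=True)
class Feature:
    """One stranded interval (0-based half-open) of a region category."""

    chrom: str
    start: int
    end: int
    strand: str
    category: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.category not in GENIC_CATEGORIES:
            raise ValueError(f"invalid category {self.category!r}")


class FeatureSet:
    """A collection of features with position-level category resolution."""

    CATEGORIES = CATEGORIES

    def __init__(self, features: list[Feature] | None = None):
        self.features = list(features or [])
        self._cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def for_chrom(self, chrom: str) -> list[Feature]:
        return [f for f in self.features if f.chrom == chrom]

    def _arrays(self, chrom: str, length: int):
        key = (chrom, length)
        if key not in self._cache:
            cats = np.zeros(length, dtype=np.int8)  # 0 == intergenic
            strands = np.zeros(length, dtype=np.int8)  # 0 none, +1, -1
            for cat in _PAINT_ORDER:
                code = CATEGORIES.index(cat)
                for f in self.features:
                    if f.chrom != chrom or f.category != cat:
                        continue
                    if f.end > length:
                        raise ValueError(
                            f"feature [{f.start}, {f.end}) outside {chrom!r} "
                            f"of length {length}"
                        )
                    cats[f.start : f.end] = code
                    strands[f.start : f.end] = 1 if f.strand == "+" else -1
            self._cache[key] = (cats, strands)
        return self._cache[key]

    def category_array(self, chrom: str, length: int) -> np.ndarray:
        """Per-position category codes (index into ``CATEGORIES``)."""
        return self._arrays(chrom, length)[0]

    def strand_array(self, chrom: str, length: int) -> np.ndarray:
        """Per-position feature strand (+1/−1; 0 for intergenic)."""
        return self._arrays(chrom, length)[1]

    def category_of(self, chrom: str, pos: int, length: int) -> str:
        return CATEGORIES[self.category_array(chrom, length)[pos]]

    def category_lengths(self, chrom: str, length: int) -> dict[str, int]:
        """Total bases per category on one chromosome (a partition)."""
        cats = self.category_array(chrom, length)
        return {
            name: int((cats == code).sum()) for code, name in enumerate(CATEGORIES)
        }

    # ------------------------------------------------------------------ I/O

    #: default mapping GFF3 feature type → category
    DEFAULT_TYPE_MAP = {
        "CDS": "CDS",
        "intron": "intron",
        "rRNA": "rRNA",
        "tRNA": "tRNA",
    }

    @classmethod
    def from_gff(cls, path, type_map: dict[str, str] | None = None) -> "FeatureSet":
        """Read features from GFF3, keeping only mapped feature types."""
        import gffutils

        type_map = dict(type_map or cls.DEFAULT_TYPE_MAP)
        try:
            db = gffutils.create_db(
                str(path),
                dbfn=":memory:",
                force=True,
                keep_order=True,
                merge_strategy="create_unique",
            )
        except gffutils.exceptions.EmptyInputError:
            return cls()
        feats = []
        for rec in db.all_features():
            if rec.featuretype not in type_map:
                continue
            strand = rec.strand if rec.strand in "+-" else "+"
            feats.append(
                Feature(
                    chrom=rec.seqid,
                    start=rec.start - 1,  # GFF3 is 1-based inclusive
                    end=rec.end,
                    strand=strand,
                    category=type_map[rec.featuretype],
                )
            )
        return cls(feats)

    def to_gff(self, path) -> None:
        """Write features as GFF3 (category as the feature type)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, f in enumerate(self.features):
                attrs = f"ID={f.category}_{i}"
                fh.write(
                    f"{f.chrom}\txrfrag\t{f.category}\t{f.start + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t.\t{attrs}\n"
                )
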