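"""Adapter trimming, the exact aligner, filtering, and mappability."""

import numpy as np
import pytest

from xrfrag import (
    AlignedFragment,
    FastqRead,
    Feature,
    FeatureSet,
    align_exact,
    apply_halving_weights,
    compute_mappability,
    filter_fragments,
    import_sam,
    make_random_genome,
    plant_duplication,
    simulate_fragments,
    trim_adapter,
)
from xrfrag.genome import AppliedEdit, Genome, apply_reference_edits, revcomp
from xrfrag.simulate import DamageModel

ADAPTER = "AGATCGGAAGAGC"


def naive_placements(read_seq, genomes):
    """Independent oracle: O(L·n) sliding-window scan for perfect matches."""
    out = set()
    L = len(read_seq)
    for g in genomes:
        ext = g.seq + (g.seq[: L - 1] if g.is_circular else "")
        for strand, q in (("+", read_seq), ("-", revcomp(read_seq))):
            for i in range(len(g.seq)):
                if ext[i : i + L] == q:
                    out.add((g.id, i, strand))
    return out


class TestTrimAdapter:
    def test_full_adapter_exact(self):
        read = FastqRead.make("r1", "ACGTACGT" + ADAPTER)
        (kept,), report = trim_adapter([read], ADAPTER)
        assert kept.seq == "ACGTACGT"
        assert report.trimmed == 1

    def test_untrimmed_read_discarded(self):
        read = FastqRead.make("r1", "ACGTACGTACGTACGT")
        kept, report = trim_adapter([read], ADAPTER)
        assert kept == []
        assert report.discarded_untrimmed == 1

    def test_partial_adapter_suffix(self):
        # brute-force oracle: the leftmost suffix overlap >= min_overlap
        frag = "ACGTACCGTT"
        read = FastqRead.make("r1", frag + ADAPTER[:5])
        (kept,), _ = trim_adapter([read], ADAPTER, min_overlap=3)
        candidates = [
            j
            for j in range(len(read.seq))
            if len(read.seq) - j >= 3
            and read.seq[j:] == ADAPTER[: len(read.seq) - j]
        ]
        assert kept.seq == read.seq[: candidates[0]]
        assert kept.seq == frag

    def test_adapter_at_start_gives_empty_discard(self):
        read = FastqRead.make("r1", ADAPTER + "ACGT")
        kept, report = trim_adapter([read], ADAPTER)
        assert kept == []
        assert report.discarded_empty == 1

    def test_error_tolerance(self):
        mutated = "AGATCGGTAGAGC"  # one mismatch vs adapter
        read = FastqRead.make("r1", "TTTTGGGG" + mutated)
        kept, _ = trim_adapter([read], ADAPTER, max_error_rate=0.0)
        assert kept == []
        (kept,), _ = trim_adapter([read], ADAPTER, max_error_rate=0.1)
        assert kept.seq == "TTTTGGGG"


class TestAlignExact:
    def test_read_from_single_copy_region_unique(self, mito_genome):
        frag = mito_genome.seq[100:126]
        (result,) = align_exact([FastqRead.make("r", frag)], [mito_genome])
        assert result.uniqueness == "unique"
        assert (result.start, result.end, result.strand) == (100, 126, "+")

    def test_absent_read_unmapped(self, mito_genome):
        (result,) = align_exact(
            [FastqRead.make("r", "ACGT" * 10)], [mito_genome]
        )
        assert result.uniqueness == "unmapped"

    def test_planted_exact_numt_reads_multimap(self):
        mito = make_random_genome(3000, 0.7, "circular", seed=20, genome_id="mt")
        nuc = make_random_genome(
            6000, 0.5, "linear", seed=21, genome_id="nuc", compartment="nuclear"
        )
        planted, _ = plant_duplication(nuc, mito, (500, 1500), 2000, 0.0, seed=22)
        inside = FastqRead.make("in", mito.seq[700:726])
        overlap = FastqRead.make("edge", mito.seq[490:516])  # 10 nt unique flank
        frags = align_exact([inside, overlap], [mito, planted])
        assert frags[0].uniqueness == "multi"
        assert frags[1].uniqueness == "unique"

    def test_matches_naive_scan(self, rng):
        from conftest import random_dna

        genomes = [
            Genome(
                f"g{i}",
                random_dna(rng, int(rng.integers(200, 1500))),
                topology="circular" if i % 2 else "linear",
            )
            for i in range(4)
        ]
        reads = []
        for k in range(30):
            g = genomes[int(rng.integers(len(genomes)))]
            start = int(rng.integers(0, len(g.seq) - 20))
            seq = g.seq[start : start + 20]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(FastqRead.make(f"r{k}", seq))
        results = align_exact(reads, genomes)
        for read, frag in zip(reads, results):
            oracle = naive_placements(read.seq, genomes)
            if frag.uniqueness == "unmapped":
                assert oracle == set()
            elif frag.uniqueness == "unique":
                assert oracle == {(frag.chrom, frag.start, frag.strand)}
            else:
                assert len(oracle) > 1

    def test_origin_spanning_placement_found_once(self):
        g = make_random_genome(500, 0.6, "circular", seed=30)
        wrap = g.seq[-10:] + g.seq[:10]
        (frag,) = align_exact([FastqRead.make("w", wrap)], [g])
        assert frag.uniqueness in ("unique", "multi")
        if frag.uniqueness == "unique":
            assert frag.start == 490 and frag.end == 510


class TestFilterFragments:
    @pytest.mark.parametrize(
        "uniqueness,mismatches,kept,cause",
        [
            ("unique", 0, True, None),
            ("multi", 0, False, "removed_multimapping"),
            ("unique", 1, False, "removed_mismatch"),
            ("unmapped", 0, False, "removed_unmapped"),
        ],
    )
    def test_filter_semantics(self, uniqueness, mismatches, kept, cause):
        f = AlignedFragment("r", "g", 0, 26, "+", 26, uniqueness, mismatches)
        result, report = filter_fragments([f])
        assert (len(result) == 1) is kept
        if cause:
            assert getattr(report, cause) == 1

    def test_filtering_idempotent(self):
        frags = [
            AlignedFragment("a", "g", 0, 26, "+", 26, "unique", 0),
            AlignedFragment("b", "g", 5, 31, "+", 26, "multi", 0),
            AlignedFragment("c", "g", 9, 35, "-", 26, "unique", 2),
        ]
        once, _ = filter_fragments(frags)
        twice, _ = filter_fragments(once)
        assert twice == once


class TestHalvingWeights:
    def test_overlapping_reads_halved(self):
        g = Genome("g", "ACGT" * 50)
        edited = apply_reference_edits(
            g, [AppliedEdit("halve_count_interval", 1, 100)]
        )
        inside = AlignedFragment("a", "g", 10, 36, "+", 26, "unique")
        outside = AlignedFragment("b", "g", 150, 176, "+", 26, "unique")
        straddle = AlignedFragment("c", "g", 90, 116, "+", 26, "unique")
        out = apply_halving_weights([inside, outside, straddle], [edited])
        assert [f.weight for f in out] == [0.5, 1.0, 0.5]


class TestImportSam:
    def _write_sam(self, path, glen, rows):
        lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:mt\tLN:{glen}"]
        lines += rows
        path.write_text("\n".join(lines) + "\n")

    def test_mapq_and_nm_mapping(self, tmp_path, mito_genome):
        seq = mito_genome.seq[50:76]
        sam = tmp_path / "a.sam"
        self._write_sam(
            sam,
            len(mito_genome.seq),
            [
                f"good\t0\tmt\t51\t42\t26M\t*\t0\t0\t{seq}\t*\tNM:i:0",
                f"lowq\t0\tmt\t51\t3\t26M\t*\t0\t0\t{seq}\t*\tNM:i:0",
                f"mm\t0\tmt\t51\t42\t26M\t*\t0\t0\t{seq}\t*\tNM:i:2",
            ],
        )
        g = mito_genome
        from dataclasses import replace

        frags = import_sam(sam, [replace(g, id="mt")])
        by_id = {f.read_id: f for f in frags}
        assert by_id["good"].uniqueness == "unique"
        assert by_id["good"].mismatches == 0
        assert by_id["lowq"].uniqueness == "multi"
        assert by_id["mm"].mismatches == 2  # retained; removed by the filter

    def test_nm_recomputed_when_absent(self, tmp_path, mito_genome):
        from dataclasses import replace

        g = replace(mito_genome, id="mt")
        seq = list(g.seq[50:76])
        seq[5] = "A" if seq[5] != "A" else "C"
        sam = tmp_path / "b.sam"
        self._write_sam(
            sam,
            len(g.seq),
            [f"r\t0\tmt\t51\t42\t26M\t*\t0\t0\t{''.join(seq)}\t*"],
        )
        (frag,) = import_sam(sam, [g])
        assert frag.mismatches == 1

    def test_unknown_reference_rejected(self, tmp_path, mito_genome):
        sam = tmp_path / "c.sam"
        self._write_sam(
            sam, 100, ["r\t0\tmt\t1\t42\t10M\t*\t0\t0\tACGTACGTAC\t*\tNM:i:0"]
        )
        with pytest.raises(ValueError, match="absent"):
            import_sam(sam, [mito_genome])  # genome set has id 'mito', not 'mt'


def saturating_reads(genome, length=26, step=1):
    reads = []
    limit = len(genome.seq) if genome.is_circular else len(genome.seq) - length + 1
    for i in range(0, limit, step):
        reads.append(FastqRead.make(f"p{i}", genome.fetch(i, length)))
    return reads


class TestMappability:
    def test_no_duplication_all_retained(self):
        mito = make_random_genome(2000, 0.7, "circular", seed=40, genome_id="mt")
        reads = saturating_reads(mito)
        unfiltered = align_exact(reads, [mito])
        filtered, _ = filter_fragments(unfiltered)
        report = compute_mappability(unfiltered, filtered, mito)
        assert report.overall == pytest.approx(1.0)

    def test_exact_duplicate_drops_fraction(self):
        mito = make_random_genome(4000, 0.7, "circular", seed=41, genome_id="mt")
        nuc = make_random_genome(
            8000, 0.5, "linear", seed=42, genome_id="nuc", compartment="nuclear"
        )
        planted, _ = plant_duplication(nuc, mito, (1000, 1400), 3000, 0.0, seed=43)
        reads = saturating_reads(mito)
        unfiltered = align_exact(reads, [mito, planted])
        filtered, _ = filter_fragments(unfiltered)
        report = compute_mappability(unfiltered, filtered, mito)
        # 400 of 4000 nt duplicated; read-length edge effects stay small
        assert report.overall == pytest.approx(0.9, abs=0.02)

    def test_category_without_coverage_is_nan(self):
        mito = make_random_genome(2000, 0.7, "circular", seed=44, genome_id="mt")
        fs = FeatureSet([Feature("mt", 100, 200, "+", "tRNA")])
        frag = AlignedFragment("r", "mt", 500, 526, "+", 26, "unique")
        report = compute_mappability([frag], [frag], mito, fs)
        assert np.isnan(report.fractions["tRNA"])
        assert report.fractions["intergenic"] == pytest.approx(1.0)

    def test_origin_spanning_coverage_wraps(self):
        g = make_random_genome(300, 0.6, "circular", seed=45)
        frag = AlignedFragment("r", g.id, 290, 316, "+", 26, "unique")
        from xrfrag import per_position_coverage

        cov = per_position_coverage([frag], g)
        assert cov.sum() == 26
        assert cov[295] == 1 and cov[5] == 1
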