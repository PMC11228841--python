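"""RPKM, region assignment, strand-resolved and halved coverage."""

import math

import numpy as np
import pytest

from xrfrag import (
    AlignedFragment,
    AppliedEdit,
    DamageModel,
    Feature,
    FeatureSet,
    Genome,
    align_exact,
    apply_halving_weights,
    apply_reference_edits,
    assign_region,
    coverage_ratio,
    coverage_table,
    filter_fragments,
    make_random_genome,
    per_position_coverage,
    rpkm,
    simulate_fragments,
    strand_normalized_coverage,
    trim_adapter,
)
from xrfrag.genome import revcomp
from xrfrag.simulate import DEFAULT_ADAPTER, FastqRead


def _frag(read_id, chrom, start, length=26, strand="+", weight=1.0):
    return AlignedFragment(read_id, chrom, start, start + length, strand,
                           length, "unique", weight=weight)


class TestRpkm:
    def test_definitional(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)

    def test_doubling_total_halves(self):
        assert rpkm(10, 1000, 2_000_000) == pytest.approx(
            rpkm(10, 1000, 1_000_000) / 2
        )

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestAssignRegion:
    def test_midpoint_rules(self, mito_genome, mito_features):
        glen = len(mito_genome.seq)
        inside = _frag("a", "mito", 1000)  # midpoint 1013, CDS [500,2000)
        assert assign_region(inside, mito_features, glen) == "CDS"
        # straddles the CDS/intergenic boundary at 2000 with midpoint inside
        straddle = _frag("b", "mito", 1980)  # midpoint 1993
        assert assign_region(straddle, mito_features, glen) == "CDS"
        outside = _frag("c", "mito", 2005)  # midpoint 2018, intergenic gap
        assert assign_region(outside, mito_features, glen) == "intergenic"

    def test_priority_enumeration(self):
        # all pairwise overlap configurations resolve by the priority table
        priority = ["intron", "CDS", "rRNA", "tRNA"]
        for low_i, low in enumerate(priority):
            for high in priority[low_i + 1 :]:
                fs = FeatureSet(
                    [
                        Feature("c", 0, 60, "+", low),
                        Feature("c", 20, 40, "+", high),
                    ]
                )
                frag = _frag("r", "c", 17)  # midpoint 30 in the overlap
                assert assign_region(frag, fs, 100) == high

    def test_wrapped_midpoint(self, mito_genome, mito_features):
        glen = len(mito_genome.seq)
        frag = _frag("w", "mito", glen - 5)  # midpoint wraps to 8
        assert assign_region(frag, mito_features, glen) == "intergenic"


class TestCoverageTable:
    def test_category_counts_partition_genome_counts(
        self, mito_genome, mito_features, rng
    ):
        glen = len(mito_genome.seq)
        frags = [
            _frag(f"r{i}", "mito", int(rng.integers(0, glen)),
                  weight=float(rng.choice([0.5, 1.0])))
            for i in range(500)
        ]
        table = coverage_table(frags, [mito_genome], mito_features)
        per_cat = sum(
            table.category_reads[("mito", cat)]
            for cat in mito_features.CATEGORIES
        )
        assert per_cat == pytest.approx(table.genome_reads["mito"])

    def test_uniform_library_equal_category_rpkm(self, mito_genome, mito_features):
        glen = len(mito_genome.seq)
        # one read starting at every position: perfectly uniform coverage
        frags = [_frag(f"r{i}", "mito", i) for i in range(glen)]
        table = coverage_table(frags, [mito_genome], mito_features)
        values = [
            table.category_rpkm[("mito", cat)]
            for cat in mito_features.CATEGORIES
        ]
        for v in values:
            assert v == pytest.approx(values[0], rel=0.01)

    def test_rpkm_invariant_under_downsampling(self, mito_genome, rng):
        glen = len(mito_genome.seq)
        frags = [_frag(f"r{i}", "mito", int(rng.integers(0, glen)))
                 for i in range(2000)]
        full = coverage_table(frags, [mito_genome]).genome_rpkm["mito"]
        for seed in range(20):
            sub_rng = np.random.default_rng(seed)
            sub = [f for f in frags if sub_rng.random() < 0.5]
            down = coverage_table(sub, [mito_genome]).genome_rpkm["mito"]
            # whole-genome RPKM is exactly depth-independent by construction
            assert down == pytest.approx(full)


class TestCoverageRatio:
    def test_simple_ratios(self):
        mito = Genome("mt", "ACGT" * 250, topology="circular", compartment="mito")
        nuc = Genome("nc", "ACGT" * 250, compartment="nuclear")
        frags = [_frag(f"m{i}", "mt", i) for i in range(20)] + [
            _frag(f"n{i}", "nc", i) for i in range(10)
        ]
        table = coverage_table(frags, [mito, nuc])
        assert table.org_nuc_ratio["mt"] == pytest.approx(2.0)
        frags = [_frag("m", "mt", 0), _frag("n", "nc", 0)]
        table = coverage_table(frags, [mito, nuc])
        assert table.org_nuc_ratio["mt"] == pytest.approx(1.0)

    def test_planted_read_excess_recovered(self, rng):
        mito = make_random_genome(3000, 0.7, "circular", seed=50, genome_id="mt")
        nuc = make_random_genome(
            3000, 0.5, "linear", seed=51, genome_id="nc", compartment="nuclear"
        )
        n_org, n_nuc = 2000, 200
        frags = [
            _frag(f"m{i}", "mt", int(rng.integers(0, 3000)))
            for i in range(n_org)
        ] + [
            _frag(f"n{i}", "nc", int(rng.integers(0, 2970)))
            for i in range(n_nuc)
        ]
        table = coverage_table(frags, [mito, nuc])
        assert table.org_nuc_ratio["mt"] == pytest.approx(10.0, rel=1e-6)


class TestStrandNormalizedCoverage:
    def test_template_definition(self, mito_genome, mito_features):
        # feature on + covering [500, 2000): a − fragment is template
        frag = _frag("r", "mito", 1000, strand="-")
        report = strand_normalized_coverage([frag], mito_features, mito_genome)
        row = report.rows[("mito", "CDS")]
        assert row["template_count"] == 1.0 and row["coding_count"] == 0.0

    def test_template_only_planting_gives_large_ratio(
        self, mito_genome, mito_features
    ):
        rng = np.random.default_rng(60)
        frags = []
        for i in range(300):
            start = int(rng.integers(500, 1974))
            frags.append(_frag(f"r{i}", "mito", start, strand="-"))
        report = strand_normalized_coverage(frags, mito_features, mito_genome)
        assert report.ratio("mito", "CDS") == math.inf

    def test_symmetric_planting_ratio_near_one(self):
        # a TT-symmetric region: substrate equal on both strands
        core = "TTAA" * 200
        g = Genome("g", core, topology="linear", compartment="mito")
        fs = FeatureSet([Feature("g", 0, len(core), "+", "CDS")])
        frags = [
            _frag(f"p{i}", "g", i * 7 % 700, strand="+") for i in range(100)
        ] + [
            _frag(f"m{i}", "g", i * 7 % 700, strand="-") for i in range(100)
        ]
        report = strand_normalized_coverage(frags, fs, g)
        assert report.ratio("g", "CDS") == pytest.approx(1.0)

    def test_complement_flip_leaves_ratios_unchanged(
        self, mito_genome, mito_features, rng
    ):
        # odd fragment length: the midpoint rule is exactly mirror-symmetric
        # (even lengths can flip assignment for reads straddling a boundary)
        glen = len(mito_genome.seq)
        frags = []
        for i in range(400):
            start = int(rng.integers(0, glen - 25))
            strand = "+" if rng.random() < 0.6 else "-"
            frags.append(_frag(f"r{i}", "mito", start, length=25, strand=strand))
        fwd = strand_normalized_coverage(frags, mito_features, mito_genome)

        flipped_genome = Genome(
            "mito", revcomp(mito_genome.seq), topology=mito_genome.topology,
            compartment="mito",
        )
        flipped_features = FeatureSet(
            [
                Feature("mito", glen - f.end, glen - f.start,
                        "-" if f.strand == "+" else "+", f.category)
                for f in mito_features
            ]
        )
        flipped_frags = [
            AlignedFragment(
                f.read_id, "mito", glen - f.end, glen - f.start,
                "-" if f.strand == "+" else "+", f.length, "unique",
                weight=f.weight,
            )
            for f in frags
        ]
        assert all(
            glen - 1 - f.midpoint == ff.midpoint
            for f, ff in zip(frags, flipped_frags)
        )
        rev = strand_normalized_coverage(
            flipped_frags, flipped_features, flipped_genome
        )
        for cat in ("CDS", "tRNA", "rRNA", "intron"):
            a, b = fwd.ratio("mito", cat), rev.ratio("mito", cat)
            if math.isnan(a):
                assert math.isnan(b)
            else:
                assert a == pytest.approx(b)

    def test_zero_substrate_is_nan(self):
        g = Genome("g", "GGGG" * 100, compartment="mito")
        fs = FeatureSet([Feature("g", 0, 400, "+", "CDS")])
        frag = _frag("r", "g", 10, strand="+")
        report = strand_normalized_coverage([frag], fs, g)
        assert math.isnan(report.ratio("g", "CDS"))


class TestInvertedRepeatHalving:
    def test_halved_coverage_matches_single_copy(self):
        """Collapsing an inverted repeat and halving its read counts gives
        the retained copy the same weighted depth as single-copy sequence."""
        rng = np.random.default_rng(70)
        single = make_random_genome(6000, 0.6, "linear", seed=71,
                                    genome_id="pt", compartment="plastid").seq
        repeat = single[1000:2500]
        original = Genome(
            "pt", single + revcomp(repeat), topology="circular",
            compartment="plastid",
        )
        # uniform sampling over the *original* two-copy genome
        reads = []
        glen = len(original.seq)
        for i in range(0, glen, 2):
            reads.append(FastqRead.make(f"u{i}", original.fetch(i, 26)))
        edited = apply_reference_edits(
            original,
            [
                AppliedEdit("halve_count_interval", 1001, 2500),
                AppliedEdit("remove_interval", 6001, 7500),
            ],
        )
        aligned = align_exact(reads, [edited])
        kept, _ = filter_fragments(aligned)
        kept = apply_halving_weights(kept, [edited])
        cov = per_position_coverage(kept, edited)
        inside = cov[1050:2400].mean()
        outside = np.concatenate([cov[100:900], cov[2600:5800]]).mean()
        assert inside / outside == pytest.approx(1.0, abs=0.1)
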