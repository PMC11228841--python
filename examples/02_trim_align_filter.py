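"""Preprocess a library: adapter trimming, exact alignment, filtering.

Reads that place equally well at several genomic locations are removed
(the uniqueness filter); the counts surviving each stage are printed.
"""

from xrfrag import (
    DEFAULT_ADAPTER,
    DamageModel,
    align_exact,
    filter_fragments,
    make_random_genome,
    simulate_fragments,
    trim_adapter,
)

genome = make_random_genome(8000, 0.7, "circular", seed=1, genome_id="mt")
model = DamageModel(primary_length=26, dimer_offset_3p=19)
reads, _ = simulate_fragments(genome, model, 2000, seed=3)

trimmed, trim_report = trim_adapter(reads, DEFAULT_ADAPTER)
aligned = align_exact(trimmed, [genome])
kept, filter_report = filter_fragments(aligned)

print(f"input reads:        {trim_report.total}")
print(f"adapter trimmed:    {trim_report.trimmed} "
      f"(discarded untrimmed: {trim_report.discarded_untrimmed})")
print(f"uniquely mapped:    {filter_report.kept}")
print(f"removed multi:      {filter_report.removed_multimapping}")
print(f"removed mismatched: {filter_report.removed_mismatch}")
# On this single-genome fixture every fragment maps back uniquely; planted
# duplications (see 05_numt_mappability.py) create multimappers.
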