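"""Positional TT enrichment against the genome-wide null.

For each read-length class the per-position TT frequency is compared to
the genome's forward-strand TT frequency (null line) with a 2-standard-
error band.  With the dimer planted 19 nt from the 3′ end, the TT peak
sits at positions 7–8 in 26-nt reads and shifts to 5–6, 3–4, 1–2 in the
24-, 22-, 20-nt classes — the same position once right (3′) aligned.
"""

from xrfrag import (
    DEFAULT_ADAPTER,
    DamageModel,
    align_exact,
    call_enrichment,
    dinucleotide_frequency,
    filter_fragments,
    fragment_sequence,
    make_random_genome,
    positional_dinuc_profile,
    simulate_fragments,
    trim_adapter,
)

genome = make_random_genome(8000, 0.7, "circular", seed=1, genome_id="mt")
model = DamageModel(
    mechanism="five_prime_trim", primary_length=26, trim_step=2,
    trim_max_steps=3, dimer_offset_3p=19,
)
reads, _ = simulate_fragments(genome, model, 10_000, seed=4)
trimmed, _ = trim_adapter(reads, DEFAULT_ADAPTER)
kept, _ = filter_fragments(align_exact(trimmed, [genome]))

p0 = dinucleotide_frequency(genome, "TT")
print(f"genome TT null frequency p0 = {p0:.4f}")
for L in (26, 24, 22, 20):
    sub = [f for f in kept if f.length == L]
    seqs = [fragment_sequence(genome, f) for f in sub]
    profile = positional_dinuc_profile(sub, seqs, L, anchor="three_prime",
                                       null_p0=p0)
    peak = profile.argmax_position("TT")
    n_sig = sum(c.significant for c in call_enrichment(profile))
    print(f"  {L}-nt reads (n={len(sub)}): TT peak at positions "
          f"{peak}-{peak + 1}, 3' offset {profile.offset_from_3p(peak)}, "
          f"CI half-width {profile.ci:.4f}, {n_sig} enriched positions")
# Identical 3' offsets across classes reproduce the right-aligned peak
# signature expected from a fixed dimer-to-3'-end geometry.
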