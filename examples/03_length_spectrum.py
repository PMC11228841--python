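"""Read-length spectra and replicate correlation.

A 5′-trimming damage model with equal weights over {26, 24, 22, 20} nt
should yield four peaks of 0.25 each; two replicate libraries of the
same condition should correlate near-perfectly (Pearson R).
"""

from xrfrag import (
    DEFAULT_ADAPTER,
    DamageModel,
    align_exact,
    filter_fragments,
    length_spectrum,
    make_random_genome,
    simulate_fragments,
    spectrum_correlation,
    trim_adapter,
)

genome = make_random_genome(8000, 0.7, "circular", seed=1, genome_id="mt")
model = DamageModel(
    mechanism="five_prime_trim", primary_length=26, trim_step=2,
    trim_max_steps=3, dimer_offset_3p=19,
)


def spectrum(seed):
    reads, _ = simulate_fragments(genome, model, 10_000, seed=seed)
    trimmed, _ = trim_adapter(reads, DEFAULT_ADAPTER)
    kept, _ = filter_fragments(align_exact(trimmed, [genome]))
    return length_spectrum(kept, {"mt": "mito"}, min_len=15, max_len=32)["mito"]


a, b = spectrum(11), spectrum(12)
print("length  frequency (replicate A)")
for L, f in a.frequencies.items():
    if f > 0:
        print(f"  {L} nt   {f:.4f}")
r, p = spectrum_correlation(a, b)
print(f"replicate Pearson R = {r:.4f} (p = {p:.2e})")
# The four ~0.25 peaks recover the planted length weights; R near 1 shows
# the spectrum is a stable property of the condition, not of one library.
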