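"""Simulate a damage-anchored fragment library with ground truth.

Builds a small AT-rich circular mitochondrial genome, plants UV-damage
fragments whose TT dimer sits 19 nt from each fragment's 3′ end, and
prints the first few reads with their true origins.
"""

from xrfrag import DamageModel, make_random_genome, simulate_fragments

genome = make_random_genome(8000, 0.7, "circular", seed=1, genome_id="mt")
model = DamageModel(
    mechanism="five_prime_trim",
    primary_length=26,
    trim_step=2,
    trim_max_steps=3,
    dimer_offset_3p=19,
)
reads, truth = simulate_fragments(genome, model, 1000, seed=2)

print(f"genome: {genome.id}, {len(genome.seq)} nt, "
      f"{genome.topology}, AT {((genome.seq.count('A') + genome.seq.count('T')) / len(genome.seq)):.2f}")
print(f"simulated {len(reads)} reads; emitted lengths and dimer positions:")
for t in truth[:4]:
    print(f"  {t.read_id}: {t.length} nt on {t.strand} strand at {t.start}, "
          f"TT pair at read positions {t.dimer_pos}-{t.dimer_pos + 1}")
# Each length class keeps the dimer at the same distance from the 3' end:
# trimming 2 nt off the 5' end moves the pair from positions 7-8 to 5-6.
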