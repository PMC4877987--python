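"""Fragment-based ANI and species delineation.

A genome is cut into 1,020 bp fragments; each aligns to its best match in
the other genome, fragments above 60 % identity are kept, and ANI is
their mean identity. ANI < 94 % (with in-silico DDH < 70 % when
available) separates species.
"""

from covbin import ani, classify_species, mutate_sequence, simulate_genome

genome = simulate_genome("ref", 40_000, 0.55, seed=1)

# a close relative: 5 % per-base substitutions
relative = mutate_sequence(genome, 0.05, seed=2)
res = ani([genome], [relative])
print(f"ANI(ref, 5%-mutant)  = {res.ani:.1f} %  "
      f"({res.n_fragments_ab + res.n_fragments_ba} fragments)")

res_self = ani([genome], [genome])
print(f"ANI(ref, ref)        = {res_self.ani:.1f} %")

# species calls: the mutant pair versus a printed draft-genome pair
for ani_pct, ddh in [(res.ani, None), (79.3, 17.7)]:
    call = classify_species(ani_pct, ddh)
    print(f"ANI {ani_pct:5.1f} %  DDH {ddh if ddh is not None else '—':>5}"
          f"  -> {call.verdict.value}")

# A 5 % substitution rate yields ANI near 95 % (same-species side of the
# 94 % line), while 79.3 % ANI with 17.7 % DDH is an unambiguous
# different-species call.
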