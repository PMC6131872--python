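"""Detect a substoichiometric plastome isomer from spanning read pairs.

Recombination between two small inverted-repeat (IR) copies flips the
intervening segment, interconverting genome arrangements "A" and "B".  A
paired-end library from a mixture of the two isomers is classified by
which arrangement gives each IR-spanning pair a concordant mapping.
"""

from plastoscan.seqsim import simulate_arrangement_spec, simulate_ir_library
from plastoscan.structscan import classify_read_pairs

arr = simulate_arrangement_spec(seed=3)
print(f"reference: {len(arr.genome)} bp, IR copies at {arr.ir1} and {arr.ir2}")

# 97.6% B / 2.4% A — the substoichiometric regime
pairs, truth = simulate_ir_library(
    arr, fraction_B=1.0 - 20 / 834, n_pairs=834, seed=5, span_only=True
)
ev = classify_read_pairs(pairs, arr)
true_a = sum(1 for v in truth.values() if v == "A")
print(f"spanning pairs classified: {ev.total}")
print(f"  support B (major): {ev.supports_B}")
print(f"  support A (minor): {ev.supports_A}  (truth: {true_a})")
print(f"  ambiguous:         {ev.ambiguous}")
print(f"estimated minor-isomer fraction: {100 * ev.minor_fraction:.2f}% "
      f"(simulated at 2.40%)")
print("A minority of spanning pairs consistently supporting the other "
      "arrangement is the signature of a substoichiometric genome isomer.")
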