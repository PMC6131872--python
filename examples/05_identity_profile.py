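"""Pairwise sliding-window identity along a whole-genome alignment.

Computes percent identity between two taxa in 1 kb windows, excluding
gapped columns — the numbers behind the classic grey-scale similarity
strips used to compare plastomes.
"""

import numpy as np

from plastoscan.seqsim import ChimeraSpec, simulate_chimera
from plastoscan.structscan import identity_windows

spec = ChimeraSpec(seed=11, length=30000, segment=(12000, 18000),
                   indel_rate=0.0005)
aln, _ = simulate_chimera(spec)

starts, ends, ident = identity_windows(
    aln, "Cupressus_1", "Juniperus_1", window=1000, step=1000
)
print("window        identity")
for s, e, v in list(zip(starts, ends, ident))[:8]:
    print(f"{s:6d}-{e:6d}  {v:6.2f}%")
print(f"... mean over {len(ident)} windows: {np.nanmean(ident):.2f}%")
print("Windows inside the introgressed segment ({}-{}) show elevated "
      "Cupressus/Juniperus identity because that segment shares their "
      "common history.".format(*spec.segment))
inside = ident[(starts >= 12000) & (ends <= 18000)]
outside = ident[(ends < 12000) | (starts > 18000)]
print(f"inside segment: {np.nanmean(inside):.2f}%   "
      f"outside: {np.nanmean(outside):.2f}%")
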