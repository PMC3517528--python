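"""TSD position-frequency profile and hAT family assignment.

Tallies 200 target site duplications drawn from the Buster-style
nnnTAnnn motif into a position-frequency matrix, calls the dominance
consensus, renders a text logo and assigns the family from the
central dinucleotide.
"""

import numpy as np

from mitekit.tsd import build_pfm, call_consensus, classify_family, text_logo

rng = np.random.default_rng(5)
sites = [
    "".join(str(rng.choice(list("ACGT"))) if c == "n" else c
            for c in "nnnTAnnn")
    for _ in range(200)
]
pfm = build_pfm(sites)
consensus = call_consensus(pfm)
print("sites      :", len(sites))
print("consensus  :", consensus)
print("family call:", classify_family(consensus))
print()
print(text_logo(pfm))
# only the fixed T and A carry ~2 bits; random positions stay near 0
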