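"""Predict the screening PCR product on the reference element.

Locates the MarF/MarR primer pair (2 mismatches allowed, exact 3'
trinucleotide required) on the bundled reference element and reports
the predicted amplicon; the expected product is 455 bp.
"""

import mitekit
from mitekit.pcr import MAR_F, MAR_R, find_primer_sites, predict_amplicons

reference = mitekit.load_synthetic_reference()
for name, primer in (("MarF", MAR_F), ("MarR", MAR_R)):
    for site in find_primer_sites(reference, primer, budget=2, primer_id=name):
        print(f"{name}: {site.interval} {site.orientation} "
              f"({site.mismatches} mismatches)")

for interval, length in predict_amplicons(reference, MAR_F, MAR_R):
    print(f"product: {interval.start}-{interval.end} -> {length} bp")
# one product spanning the primer pair; 455 bp as in the wet-lab screen
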