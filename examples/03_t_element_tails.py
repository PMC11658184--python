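"""Non-templated 3' tails on a mitochondrial t-element.

t-elements are tRNA-like sequences cleaved from mRNA ends; they receive
post-transcriptional 3' additions (often a full CCA) but are never
aminoacylated.  Their references carry no CCA, so any 3' addition appears
as a soft-clipped overhang, collected here into a tail spectrum.
"""

import numpy as np

from trnacharge import map_reads
from trnacharge.align import AlignmentRecord, map_read
from trnacharge.reference import ReferenceSet
from trnacharge.simulate import make_t_element
from trnacharge.tails import classify_tails, tail_spectrum

rng = np.random.default_rng(3)
te = make_t_element("mit-tE-ccmC", rng)
refset = ReferenceSet([te])

# reads with a drawn distribution of 3' additions (counts chosen to echo a
# typical control-library spectrum)
additions = ["CCA"] * 86 + ["CC"] * 35 + ["C"] * 12 + ["CCAA"] * 4
reads = [(f"r{i}", te.seq + add, "I" * (len(te.seq) + len(add)))
         for i, add in enumerate(additions)]
records, _ = map_reads(reads, refset)
calls = classify_tails(records, refset)
spectrum = tail_spectrum(calls, te)
print(spectrum.to_string(index=False))
print()
print("Each row is one non-templated 3' addition (soft-clipped past the")
print("reference terminus) with its read count; 'None' = no addition.")
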