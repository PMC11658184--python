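"""5'-tRF calling from 3'-end positions.

Simulates a gene where 12% of molecules are a 5' fragment ending 20 nt
short of the mature 3' end, plus low-level degradation noise, and shows
the caller reporting one tRF at that breakpoint.
"""

from trnacharge import map_reads, simulate_library
from trnacharge.profiles import trf_table
from trnacharge.simulate import GeneParams, SimulationConfig, random_reference_set

refset = random_reference_set(1, seed=19)
gene = refset.genes[0]
bp = len(gene.seq) - 20  # fragment ends 20 nt short of the 3' terminus

cfg = SimulationConfig(
    seed=19, n_reads_per_gene=3000, treatment="control",
    default_params=GeneParams(theta=0.5, trf_5prime_prob=0.12,
                              trf_5prime_breakpoint=bp))
reads, _ = simulate_library(cfg, refset)
records, _ = map_reads(reads, refset)
calls = trf_table(records, refset)
print(calls.to_string(index=False))
print()
print("distance = nucleotides missing from the annotated 3' end (> 7 required);")
print("fraction = share of the gene's reads ending there (> 5% required);")
print("max_detectable_distance reflects the ~35 nt library size floor.")
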