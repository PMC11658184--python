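"""Sprinzl-anchored modification profiling.

Simulates a library whose tRNAs carry a hard-stop site at position 58 and
a misincorporating site at position 26, then shows how the 5' end
histogram localizes the stop and the misincorporation matrix recovers the
substitution + deletion rate.
"""

from trnacharge import map_reads, simulate_library
from trnacharge.profiles import end_histogram, misincorporation_matrix, profiles_to_frame
from trnacharge.simulate import GeneParams, ModSite, SimulationConfig, random_reference_set

refset = random_reference_set(3, seed=7, genome_cycle=("nuclear",))
cfg = SimulationConfig(
    seed=7, n_reads_per_gene=2000, treatment="control", extra_degradation=0.0,
    size_min=15, terminal_transferase_prob=0.0,
    default_params=GeneParams(
        theta=0.5,
        mod_sites=(ModSite("58", stop_prob=0.3),
                   ModSite("26", del_prob=0.1, sub_prob=0.25))))

reads, _ = simulate_library(cfg, refset)
records, _ = map_reads(reads, refset)

hist = end_histogram(records, refset, "nuclear", "five_prime")
frame = profiles_to_frame(hist)
print("5' start positions, per thousand nuclear-mapped reads:")
print(frame[["1", "59"]].round(1).to_string())
print("  -> mass at 59 = reads truncated by the hard stop at position 58\n")

mat = misincorporation_matrix(records, refset, min_cov=50, level="gene")
print("misincorporation (sub+del fraction of covering reads) at site 26:")
print(mat["26"].round(3).to_string())
print("  -> expected 0.35 (= 0.10 deletions + 0.25 substitutions); a cell")
print("     can fall short when the base at 26 repeats a neighbor, because a")
print("     deletion inside a repeated-base run aligns equally well to the")
print("     neighboring column and is attributed there")
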