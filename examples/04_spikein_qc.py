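"""Spike-in call-rate matrix: modification-calling accuracy from controls.

Simulates the three fiducial controls (unmodified plasmid-like DNA, fully
CpG-methylated phage-like DNA, and an 80-nt oligo hydroxymethylated at
designated CpGs) through near-ideal chemistry and estimates the call-rate
matrix: rows are true states, columns called states, entries row-normalised
percentages over bases with genetic call C at control CpGs.
"""

from sixbct import ChemistryParams, make_spikeins
from sixbct.chemistry import simulate_control_reads
from sixbct.qc import call_rate_matrix, three_column_view
from sixbct.quant import accumulate_calls
from sixbct.readproc import ME2U, trim_pairs
from sixbct.resolve import place_reads, resolve_pairs

params = ChemistryParams(
    p_hmc_protect=0.995, p_mc_protect=0.995, p_mt_copy=0.995,
    p_deaminate=0.995, seq_error=0.001, read_length=100,
    p_partial_fragment=0.0, insert_length_mean=50, insert_length_sd=10)
spikeins = make_spikeins(seed=11)
genome = spikeins.genome()

reads = []
for label, pairs in simulate_control_reads(spikeins, 3000, params, ME2U,
                                           seed=12).items():
    trimmed, _ = trim_pairs(pairs, ME2U)
    placed = [r for r in place_reads(resolve_pairs(trimmed), genome)
              if r.placed]
    print(f"{label:<13} {len(pairs)} pairs -> {len(placed)} placed reads")
    reads += placed

table = accumulate_calls(reads, genome)
matrix = call_rate_matrix(table, spikeins)
print("\ncall-rate matrix (%, rows = true state):")
print(matrix.round(2).to_string())
print("\nthree-column view (ambiguous dropped, rows renormalised):")
print(three_column_view(matrix).round(2).to_string())
print("\nDiagonal entries are the per-state sensitivities; with 0.995")
print("per-module efficiencies they sit in the ~98-99.5% band.")
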