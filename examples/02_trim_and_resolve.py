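"""Validate, trim and resolve read pairs into 6-letter reads.

Simulates a small ideal-chemistry run, trims the ME2U scars (9 nt from each
5' end), cuts the 3' adaptor and the 9-bp Tn5 gap duplication, then decodes
each (original strand, copy strand) pair into one single-end read carrying a
genetic base plus modification state per position.
"""

from sixbct import (
    ChemistryParams,
    SimulationConfig,
    assign_methylation,
    make_genome,
    simulate_run,
    trim_pairs,
)
from sixbct.readproc import ME2U
from sixbct.resolve import place_reads, resolve_pairs

genome = make_genome(seed=5, chromosome_lengths=[40_000], cpg_enrichment=2.0)
landscape = assign_methylation(genome, None, None,
                               {"background": (0.3, 0.1)}, seed=6)
config = SimulationConfig(
    genome=genome, landscape=landscape, target_mark="WG",
    n_fragments=2000, params=ChemistryParams.ideal(read_length=100),
    seed=7)
result = simulate_run(config)

trimmed, counts = trim_pairs(result.pairs, ME2U)
print("trimming:", counts)
reads = resolve_pairs(trimmed)
placed = [r for r in place_reads(reads, genome) if r.placed]
print(f"resolved {len(reads)} reads, {len(placed)} placed uniquely")

r = placed[0]
print(f"\nfirst placed read ({r.chrom}:{r.start} {r.strand}):")
print("  genetic:", r.genetic)
print("  states :", r.states)
print("\nState symbols: U unmodified C, M 5mC, H 5hmC, X ambiguous modC,")
print("'.' a non-cytosine position.  Unmodified Cs were deaminated on the")
print("original strand and read back from the copy strand, so the genetic")
print("sequence is complete even where the raw read shows T.")
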