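# Methods

This note documents the models, parameters and design choices behind
`sixbct`: what the simulator does and does not emulate, how the resolver's
decode table follows from the chemistry, and the numerical conventions used
throughout.

## Coordinates and state encoding

All coordinates are 0-based, half-open, on the top (reference) strand,
matching BED/bedGraph conventions. Per-cytosine modification states are
encoded as integers (−1 non-cytosine, 0 C, 1 5mC, 2 5hmC) in per-chromosome
arrays, one per strand. The two strands of a CpG are drawn and quantified
independently — each sequenced molecule reports exactly one strand, and
strand symmetry of methylation is not assumed.

## Synthetic reference

`make_genome` draws i.i.d. bases at a requested GC fraction and then plants
extra CG dinucleotides to reach a requested CpG enrichment (the i.i.d. GC is
adjusted downward so the realised overall GC stays within ~2 points of the
request). This is the simplest model with controllable CpG density; it makes
no attempt to mimic real mammalian sequence composition, isochores or CpG
islands.

`assign_methylation` draws each CpG cytosine independently from its
annotation class's (p_5mC, p_5hmC). Default class presets follow the
enhancer-state averages measured by 6-base CUT&Tag in mouse embryonic stem
cells — primed (0.13, 0.04), active (0.04, 0.02), poised (0.02, 0.02) — on a
bulk-like background of (0.70, 0.03); histone-mark regions outside annotated
enhancers default to hypomethylated values consistent with the measured
ordering of marks. Non-CpG cytosines are modified at a background rate of
0.002 (5mC) / 0 (5hmC); this feeds the ambiguous-modC channel without
dominating it. The rate is a free parameter of the simulator, not a measured
value.

Because truth is a *binary state per site*, per-site modification fractions
in deep data approach 0 or 1; cell-to-cell heterogeneity (fractional
per-site methylation) is deliberately not modelled. Consequently the
replicate-correlation analogue tests reproducibility of site classification,
not of intermediate methylation levels, and correlations on simulated data
run higher than on real tissue.

Spike-in controls: a 2 kb unmodified plasmid-like record, a 3 kb fully
CpG-methylated phage-like record, and an 80-nt oligo with six planted CpGs
of which four (offsets 10, 34, 58, 70) carry 5hmC on both strands. Truth
tables are exhaustive over every cytosine.

## Chemistry forward model

The simulator reproduces the *sequence consequences* of the library
chemistry; uracil intermediates, hairpin folding and enzyme kinetics are not
physically modelled.

Fragment sampling: start positions fall inside the target mark's intervals
with probability proportional to the mark's fold enrichment (default 20× in
the demos) and uniformly elsewhere; IgG and whole-genome modes are uniform.
Insert lengths are normal (default mean 60, sd 15), clipped to
[20, 2·read_length]. A fragment is partially tagmented / randomly cleaved
with probability `p_partial_fragment` (default 0.3); such fragments are
digested by the exonuclease step unless they escape with `p_exo_escape`
(default 0.05), in which case they surface with at most one valid scar.
Varying `p_exo_escape` reproduces the qualitative effect of different
exonuclease cocktails.

Conversion, in order, per molecule: (1) the copy strand is the exact
complement of the original insert; (2) original 5hmC is glucosylation-
protected with `p_hmc_protect`; (3) MT methylates the copy-strand CpG
cytosine opposite an original 5mCpG with `p_mt_copy` — never opposite 5hmC,
whether or not its protection succeeded, since hemi-hydroxymethylated CpGs
are poor MT substrates; (4) oxidation protects original 5mC and MT-added
copy 5mC independently with `p_mc_protect`; (5) every unprotected C on
either strand deaminates to T with `p_deaminate`; (6) uniform per-base
substitution errors at `seq_error`. The per-module efficiencies of the real
kit are not published; the defaults of 0.995 per step (sequencing error
0.001) were chosen once because they reproduce the observed 98–99.5%
spike-in sensitivity band, and `ChemistryParams.ideal()` gives the loss-free
limit used by the round-trip tests.

Read emission: mate 1 = R1 scar + converted original strand + gap
duplication + 3′ adaptor, truncated/padded to the read length; mate 2
likewise with the R2 scar and the copy strand read from the opposite end.
The 9-bp gap-duplication segment models the Tn5 target-site duplication: it
duplicates the terminal insert bases but is fill-in synthesised with
unmodified nucleotides, so it is emitted fully deaminated and carries no
methylation signal. Placing it on the 3′ side of the insert is what makes
the pipeline's fixed 9-bp 3′ trim recover the exact insert; reads whose
insert exceeds the read span lose their terminal bases instead and are later
discarded by the resolver's inconsistency filter (at default geometry this
costs the longest few percent of inserts). Quality strings are constant
(Q37); no quality-aware step exists in the pipeline.

## Trimming and resolution

Scar validation is an exact 5′ prefix match by default (`max_mismatch = 0`;
N positions in the ME1U prefix match anything): the discard rule is a hard
one and exactness keeps retention statistics interpretable. The 3′ adaptor
is cut at the first exact occurrence of a 12-base seed of the deaminated
mosaic-end sequence, then 9 further bases (the gap duplication) come off
each 3′ end.

The decode table is derived from the chemistry above (see README table).
Two conventions matter:

* a modified C whose 3′ neighbour on the original strand is not G — CpH
  context — is called ambiguous modC (X), as is a modified C in the read's
  final column, where the subtype channel is truncated;
* during per-CpG accumulation, a *terminal* X is not tallied: at an aligned
  CpG it reflects read geometry, not chemistry, and counting it would
  deflate the call-rate diagonal by ~1/insert-length even under perfect
  chemistry. Non-terminal X calls are tallied (and X at reference CpH sites
  is the correct call).

Mates whose trimmed lengths differ by ≤ 3 are reconciled by pairing mate 1's
last L columns against the head of reverse-complemented mate 2 (the overlap
implied by reading the insert from opposite ends); larger differences reject
the pair. Reads with more than 10% inconsistent (N) columns are discarded —
a conservative, configurable threshold. Placement is by unique exact match
of the genetic sequence in either orientation; zero or multiple hits leave
the read unplaced, mirroring a multimapper filter. Externally aligned reads
can be imported from SAM instead (primary alignments only).

## Quantification and QC

Per-site percentages use the subtype denominator n_U + n_M + n_H; ambiguous
modC is excluded from %5mC/%5hmC but reported and included in %modC and in
the classifier's 4-state vectors. Global values are unweighted means over
sites (not call-weighted). Coverage filters default to ≥ 20 for analysis and
≥ 10 for browser export. Region aggregation is an unweighted mean over the
qualifying CpGs inside each interval; empty regions are flagged rather than
silently dropped.

The call-rate matrix row for each control is restricted to control CpG sites
whose truth state matches the row label (relevant for the hmC oligo, which
also contains designed unmodified CpGs), over bases whose genetic call is C.
A fourth "ambiguous" column keeps rows summing to 100; a three-column
renormalised view is also provided.

## Differential testing

Two-group comparison pools counts within each group, optionally tiles sites
into windows (default 100 bp window and step), and tests each unit with a
binomial likelihood-ratio test of the group term (1 df) — the same contrast
a two-group logistic regression fits. Simulation at the test's own null
(totals ≥ 20) puts the type-I error at α = 0.05 within [0.03, 0.07].
q-values are Benjamini–Hochberg; the flag rule uses raw p as published
(p < 0.05, |log2FC| ≥ 0.5, |difference| ≥ 15 points). log2FC is computed as
log2((μ₁+ε)/(μ₂+ε)) with ε = 10⁻³ to guard zeros. No overdispersion
correction is applied; with binary per-site truth the binomial model is the
generating model, but on real data a dispersion term would be warranted.

## Enhancer classifier

Samples are ordered per-CpG vectors (x_ambiguous_modC, x_mC, x_hmC, x_C),
counts normalised per CpG per replicate and averaged across replicates;
labels are 0 active, 1 poised, 2 primed; chromosome 1 is held out for
evaluation. The network — linear projection to d_model = 32, one multi-head
self-attention layer (4 heads, query = key = value) with residual connection
and a 256-unit two-layer feed-forward block, masked mean-pooling, a two-layer
256-unit classifier head, elu activations, dropout 0.2, softmax cross-
entropy — is implemented directly in NumPy with hand-derived gradients
(validated against finite differences in the test suite) and Adam
(lr 10⁻³, batch 32, early stopping on a 10% validation split, patience 10).
Pooling, optimiser, epochs and padding were open choices: masked mean-
pooling keeps the model length-invariant, variable-length samples are padded
to the 95th percentile of training lengths, and there is no positional
encoding by default, so logits are invariant to CpG permutation within a
sample (asserted numerically). Parameter count is 96,067.

The classifier acceptance checks run on synthetic enhancers with
*well-separated* class signatures — active (0.05, 0.35), poised
(0.40, 0.03), primed (0.80, 0.10) at coverage 50, 20–60 CpGs per enhancer —
because at the published real-data class averages, active (0.04, 0.02) and
poised (0.02, 0.02) differ by less than the per-enhancer sampling noise at
desk scale; separability is the property under test, not the real-data AUC.
The whole-genome analogue replaces 70% of CpGs with background-signature
draws, diluting the class signal the way an unenriched library does.

## Problem sizes

Test and acceptance runs use genomes of 12–120 kb, 2,000–33,000 fragments
per library, ~50× mean CpG coverage for recovery checks, ≥ 5,000 qualifying
calls per spike-in control, 2,000 null units for calibration, and 450
synthetic enhancers for classification — sizes at which every asserted
property has ≥ 3-standard-error headroom under its stated tolerance.

## Known limitations

* Binary per-site truth (no cell-mixture heterogeneity), no PCR duplication,
  index hopping or sequencer-specific error profiles.
* Exact-match placement cannot place reads containing N and treats
  palindromic or repeated sequence as multi-mapping; real alignment is
  delegated to SAM import.
* Pairs whose insert exceeds the resolvable read span are discarded rather
  than partially resolved (the real vendor pipeline reconciles overlapping
  mates by alignment).
* The vendor resolution algorithm's proprietary error handling is
  unavailable; the decode table here is derived from the chemistry and
  validated by exhaustive round-trip against this package's own forward
  model.
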