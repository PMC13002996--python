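"""Forward simulation of the 6B-C&T molecular workflow.

The simulator follows the sequence-level consequences of the library
chemistry, from feature-enriched fragment sampling to paired-end FASTQ:

1. Tn5 tagmentation with a hairpin mosaic-end adaptor samples fragments with
   probability proportional to the target mark's fold enrichment inside its
   intervals (uniform for IgG and whole-genome mode).
2. Fully tagmented fragments circularise into exonuclease-resistant dumbbells;
   partially tagmented / randomly cleaved fragments are digested unless they
   escape, in which case they surface without a complete scar pair.
3. After strand separation, each original strand receives a copy strand
   (exact complement).  5hmC on the original is glucosylation-protected; the
   MT step methylates the copy-strand CpG cytosine opposite an original 5mCpG;
   oxidation protects original and copy 5mC; deamination converts every
   unprotected C to T; sequencing error is applied per base.
4. Each mate is emitted as scar + converted strand + 9-bp gap-duplication
   segment (the Tn5 target-site duplication, fill-in synthesised and carrying
   no methylation information) + 3' adaptor, padded or truncated to the read
   length.

Only probabilities in, sequences out: the uracil intermediates and hairpin
folding are not modelled physically, just their sequence consequences.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dna import STATE_5HMC, STATE_5MC, array_to_seq, complement, seq_to_array
from .errors import InvalidParameterError
from .readproc import ME2U, ScarDialect
from .reference import FeatureAnnotation, Genome, MethylLandscape, SpikeInSet

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ChemistryParams:
    """Per-step efficiencies and library geometry of the conversion chemistry.

    All probabilities are per molecule/base in [0, 1].  The defaults are
    near-ideal module efficiencies (the real per-module values are proprietary
    to the kit; 0.995 per step reproduces the observed 98-99.5% spike-in
    sensitivity band).
    """

    p_hmc_protect: float = 0.995   # glucosylation protection of 5hmC
    p_mc_protect: float = 0.995    # oxidative protection of (copy or original) 5mC
    p_mt_copy: float = 0.995       # copy-strand CpG methylation opposite 5mC
    p_deaminate: float = 0.995     # deamination of an unprotected C
    seq_error: float = 0.001       # per-base sequencing substitution rate
    read_length: int = 100
    gap_duplication: int = 9       # Tn5 target-site duplication length
    p_partial_fragment: float = 0.3
    p_exo_escape: float = 0.05
    insert_length_mean: float = 60.0
    insert_length_sd: float = 15.0

    def __post_init__(self) -> None:
        for name in ("p_hmc_protect", "p_mc_protect", "p_mt_copy", "p_deaminate",
                     "seq_error", "p_partial_fragment", "p_exo_escape"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 30:
            raise InvalidParameterError("read_length must be >= 30")
        if self.gap_duplication < 0:
            raise InvalidParameterError("gap_duplication must be >= 0")
        if self.insert_length_mean <= 0 or self.insert_length_sd <= 0:
            raise InvalidParameterError("insert length parameters must be positive")

    @classmethod
    def ideal(cls, **overrides) -> "ChemistryParams":
        """Loss-free chemistry: every protection/conversion succeeds, no errors."""
        base = dict(
            p_hmc_protect=1.0, p_mc_protect=1.0, p_mt_copy=1.0, p_deaminate=1.0,
            seq_error=0.0, p_partial_fragment=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Molecule:
    """One sampled insert; ``strand`` is the original strand that is retained."""

    chrom: str
    start: int
    end: int
    strand: str                      # '+' or '-'
    kind: str = "double-hairpin"     # or 'partial'
    mol_id: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start < 20:
            raise InvalidParameterError("molecule insert must be >= 20 bp")


@dataclass
class ReadPair:
    """A paired-end record; mate1 reports the original strand, mate2 the copy."""

    pair_id: str
    mate1: str
    mate2: str
    qual1: str = ""
    qual2: str = ""
    molecule: Molecule | None = None


def sample_fragments(
    genome: Genome,
    annotation: FeatureAnnotation | None,
    target_mark: str,
    n_fragments: int,
    params: ChemistryParams,
    seed: int,
) -> list[Molecule]:
    """Sample insert molecules, enriched inside the target mark's intervals.

    Fragment start positions fall inside the mark's intervals with probability
    proportional to the mark's fold enrichment and uniformly elsewhere; "IgG"
    and "WG" sample uniformly.  Insert lengths are normal, truncated to
    [20, 2 * read_length].  Fragment class 'partial' is assigned with
    probability ``p_partial_fragment``; strand is uniform.
    """
    if n_fragments <= 0:
        raise InvalidParameterError("n_fragments must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(genome.records)
    lengths = np.array([len(genome.records[c]) for c in chroms], dtype=float)

    uniform = target_mark in ("IgG", "WG") or annotation is None
    if not uniform:
        fold = annotation.enrichment.get(target_mark, 1.0)
        ivs_by_chrom = {c: [] for c in chroms}
        for chrom, s, e in annotation.intervals_for(target_mark):
            ivs_by_chrom[chrom].append((s, e))
        covered = np.array(
            [sum(e - s for s, e in ivs_by_chrom[c]) for c in chroms], dtype=float
        )
        weights = lengths + (fold - 1.0) * covered
    else:
        weights = lengths

    probs = weights / weights.sum()
    chrom_idx = rng.choice(len(chroms), size=n_fragments, p=probs)
    ins = np.clip(
        rng.normal(params.insert_length_mean, params.insert_length_sd, n_fragments),
        20, 2 * params.read_length,
    ).astype(int)
    is_partial = rng.random(n_fragments) < params.p_partial_fragment
    strands = np.where(rng.random(n_fragments) < 0.5, "+", "-")

    molecules: list[Molecule] = []
    for i in range(n_fragments):
        chrom = chroms[chrom_idx[i]]
        L = int(lengths[chrom_idx[i]])
        length = min(int(ins[i]), L)
        if not uniform and ivs_by_chrom[chrom]:
            cov = sum(e - s for s, e in ivs_by_chrom[chrom])
            p_inside = fold * cov / (fold * cov + (L - cov))
            if rng.random() < p_inside:
                spans = np.array([e - s for s, e in ivs_by_chrom[chrom]], float)
                k = rng.choice(len(spans), p=spans / spans.sum())
                s, e = ivs_by_chrom[chrom][k]
                start = int(rng.integers(s, e))
            else:
                # rejection-sample a start outside the intervals
                while True:
                    start = int(rng.integers(0, L))
                    if not any(s <= start < e for s, e in ivs_by_chrom[chrom]):
                        break
        else:
            start = int(rng.integers(0, L))
        start = min(start, L - length)
        molecules.append(
            Molecule(
                chrom=chrom, start=start, end=start + length,
                strand=str(strands[i]),
                kind="partial" if is_partial[i] else "double-hairpin",
                mol_id=f"mol{i}",
            )
        )
    return molecules


# ---------------------------------------------------------------------------
# conversion chemistry


def convert_strand(
    seq: str, states: np.ndarray, params: ChemistryParams, rng: np.random.Generator
) -> tuple[str, str]:
    """Run the conversion chemistry on one original strand and its copy.

    ``seq`` is the original strand 5'->3'; ``states`` the per-position state
    codes along it.  Returns (converted original, converted copy) with the
    copy reported *in the original's orientation* (element-wise complement
    frame), so column i of both outputs refers to the same duplex position.
    """
    n = len(seq)
    o = seq_to_array(seq)
    c = seq_to_array(complement(seq))

    is_c_orig = o == "C"
    next_is_g = np.zeros(n, dtype=bool)
    next_is_g[:-1] = o[1:] == "G"

    # (2) glucosylation protects original 5hmC before the MT/Ox/DA cascade
    prot_hmc = (states == STATE_5HMC) & (rng.random(n) < params.p_hmc_protect)

    # (3) MT methylates the copy CpG cytosine opposite an original 5mCpG
    mt_source = (states == STATE_5MC) & next_is_g & (rng.random(n) < params.p_mt_copy)
    copy_methylated = np.zeros(n, dtype=bool)
    copy_methylated[1:] = mt_source[:-1]

    # (4) oxidation protects original 5mC and MT-added copy 5mC independently
    prot_mc_orig = (states == STATE_5MC) & (rng.random(n) < params.p_mc_protect)
    prot_copy = copy_methylated & (rng.random(n) < params.p_mc_protect)

    # (5) deamination of every unprotected C, both strands
    deam_o = is_c_orig & ~(prot_hmc | prot_mc_orig) & \
        (rng.random(n) < params.p_deaminate)
    o = o.copy()
    o[deam_o] = "T"
    is_c_copy = c == "C"
    deam_c = is_c_copy & ~prot_copy & (rng.random(n) < params.p_deaminate)
    c = c.copy()
    c[deam_c] = "T"

    # (6) per-base sequencing error (uniform substitution to another base)
    for arr in (o, c):
        err = np.nonzero(rng.random(n) < params.seq_error)[0]
        for i in err:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]

    return array_to_seq(o), array_to_seq(c)


def convert_molecule(
    mol: Molecule,
    genome: Genome,
    landscape: MethylLandscape,
    params: ChemistryParams,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Extract the molecule's original strand and run the chemistry on it."""
    ref = genome.records[mol.chrom]
    if not (0 <= mol.start < mol.end <= len(ref)):
        raise InvalidParameterError("molecule outside genome bounds")
    top = ref[mol.start:mol.end]
    if mol.strand == "+":
        seq = top
    else:
        from .dna import revcomp
        seq = revcomp(top)
    states = landscape.states_for_molecule(mol.chrom, mol.start, mol.end, mol.strand)
    return convert_strand(seq, states, params, rng)


def _corrupt_scar(scar: str, rng: np.random.Generator) -> str:
    """A random same-length prefix guaranteed not to match the scar exactly."""
    junk = "".join(_BASES[rng.integers(0, 4, size=len(scar))].tolist())
    i = len(scar) // 2
    wrong = _BASES[_BASES != scar[i]]
    return junk[:i] + str(wrong[rng.integers(0, 3)]) + junk[i + 1:]


def emit_readpair(
    mol: Molecule,
    original_converted: str,
    copy_converted: str,
    dialect: ScarDialect,
    params: ChemistryParams,
    rng: np.random.Generator,
) -> ReadPair:
    """Assemble the paired-end reads for one converted molecule.

    mate1 = R1 scar + converted original strand (5'->3') + gap-duplication
    segment + 3' adaptor; mate2 likewise with the R2 scar and the copy strand
    read from the opposite end (i.e. the reverse of the aligned copy).  The
    gap-duplication segment duplicates the terminal bases of the insert but is
    fill-in synthesised with unmodified nucleotides, so it is emitted fully
    deaminated and carries no methylation signal; the fixed 3' gap trim
    removes it.  Partial fragments surface with at most one valid scar.
    """
    g = params.gap_duplication
    L = params.read_length
    core1 = original_converted
    core2 = copy_converted[::-1]  # copy strand in its own 5'->3' orientation

    scar1 = dialect.instantiate_r1(rng)
    scar2 = dialect.instantiate_r2(rng)
    if mol.kind == "partial":
        mode = int(rng.integers(0, 3))
        if mode in (0, 2):
            scar1 = _corrupt_scar(scar1, rng)
        if mode in (1, 2):
            scar2 = _corrupt_scar(scar2, rng)

    def build(scar: str, core: str) -> str:
        gapdup = core[-g:].replace("C", "T") if g else ""
        read = scar + core + gapdup + dialect.adaptor3p
        while len(read) < L:
            read += dialect.adaptor3p
        return read[:L]

    mate1 = build(scar1, core1)
    mate2 = build(scar2, core2)
    qual = "F" * L
    return ReadPair(pair_id=mol.mol_id, mate1=mate1, mate2=mate2,
                    qual1=qual, qual2=qual, molecule=mol)


# ---------------------------------------------------------------------------
# whole-run driver


@dataclass
class SimulationConfig:
    genome: Genome
    landscape: MethylLandscape
    params: ChemistryParams = field(default_factory=ChemistryParams)
    dialect: ScarDialect = ME2U
    annotation: FeatureAnnotation | None = None
    target_mark: str = "IgG"
    n_fragments: int = 10000
    seed: int = 0
    spikeins: SpikeInSet | None = None
    spikein_fraction: float = 0.0


@dataclass
class SimulationResult:
    pairs: list[ReadPair]
    molecules: list[Molecule]
    n_digested: int
    n_spikein: int


def simulate_run(config: SimulationConfig) -> SimulationResult:
    """Simulate a full run: genomic + spike-in molecules through the chemistry.

    Partial fragments are digested by the exonuclease step unless they escape
    with probability ``p_exo_escape``; escapees are emitted without a complete
    scar pair.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    genome, landscape = config.genome, config.landscape
    n_spike = 0
    if config.spikeins is not None and config.spikein_fraction > 0:
        from .reference import merge_reference
        genome, landscape = merge_reference(genome, landscape, config.spikeins)
        n_spike = int(rng.binomial(config.n_fragments, config.spikein_fraction))

    n_genomic = config.n_fragments - n_spike
    molecules = sample_fragments(
        config.genome, config.annotation, config.target_mark,
        n_genomic, config.params, seed=int(rng.integers(0, 2**31 - 1)),
    )
    if n_spike:
        spike_genome = config.spikeins.genome()
        spike_mols = sample_fragments(
            spike_genome, None, "WG", n_spike, config.params,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i, m in enumerate(spike_mols):
            m.mol_id = f"spk{i}"
        molecules = molecules + spike_mols

    pairs: list[ReadPair] = []
    n_digested = 0
    for mol in molecules:
        if mol.kind == "partial" and rng.random() >= config.params.p_exo_escape:
            n_digested += 1
            continue
        orig, copy = convert_molecule(mol, genome, landscape, config.params, rng)
        pairs.append(emit_readpair(mol, orig, copy, config.dialect,
                                   config.params, rng))
    return SimulationResult(pairs=pairs, molecules=molecules,
                            n_digested=n_digested, n_spikein=n_spike)


def simulate_control_reads(
    spikeins: SpikeInSet,
    n_pairs_per_control: int,
    params: ChemistryParams,
    dialect: ScarDialect = ME2U,
    seed: int = 0,
) -> dict[str, list[ReadPair]]:
    """Simulate reads drawn uniformly from each fiducial control separately."""
    rng = np.random.default_rng(seed)
    genome = spikeins.genome()
    landscape = spikeins.landscape()
    out: dict[str, list[ReadPair]] = {}
    for label, ctrl in spikeins.controls.items():
        sub = Genome({ctrl.name: ctrl.sequence})
        mols = sample_fragments(sub, None, "WG", n_pairs_per_control,
                                params, seed=int(rng.integers(0, 2**31 - 1)))
        pairs = []
        for i, mol in enumerate(mols):
            mol.mol_id = f"{label}:{i}"
            if mol.kind == "partial" and rng.random() >= params.p_exo_escape:
                continue
            orig, copy = convert_molecule(mol, genome, landscape, params, rng)
            pairs.append(emit_readpair(mol, orig, copy, dialect, params, rng))
        out[label] = pairs
    return out


# ---------------------------------------------------------------------------
# FASTQ / truth output


def write_fastq_pair(pairs: Sequence[ReadPair], path1, path2) -> None:
    """Write mates to two FASTQ files (gzip when the name ends with .gz)."""

    def opener(path):
        p = str(path)
        if p.endswith(".gz"):
            # fixed mtime and no embedded filename keep output byte-identical
            return io.TextIOWrapper(
                gzip.GzipFile(filename="", mode="wb", mtime=0,
                              fileobj=open(p, "wb")),
                encoding="ascii")
        return open(p, "w")

    with opener(path1) as f1, opener(path2) as f2:
        for p in pairs:
            com = ""
            if p.molecule is not None:
                m = p.molecule
                com = f" {m.chrom}:{m.start}-{m.end}:{m.strand}:{m.kind}"
            f1.write(f"@{p.pair_id}{com}\n{p.mate1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}{com}\n{p.mate2}\n+\n{p.qual2}\n")


def write_truth_tsv(pairs: Sequence[ReadPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\tkind\n")
        for p in pairs:
            m = p.molecule
            if m is None:
                continue
            fh.write(f"{p.pair_id}\t{m.chrom}\t{m.start}\t{m.end}\t"
                     f"{m.strand}\t{m.kind}\n")
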