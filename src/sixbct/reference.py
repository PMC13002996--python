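"""Synthetic references: genomes, annotations, methylation landscapes, spike-ins.

This module fabricates everything a 6-base CUT&Tag (6B-C&T) experiment needs as
ground truth: a random reference genome with controllable GC and CpG density,
histone-mark feature annotations, enhancer intervals labelled by functional
state (active / poised / primed), a per-cytosine modification landscape
(C / 5mC / 5hmC on each strand independently), and the three fiducial spike-in
controls used to estimate the call-rate matrix: an unmodified plasmid-like
control, a fully CpG-methylated phage-like control, and an 80-nt oligo
hydroxymethylated at designated CpGs.

Default per-class (p_5mC, p_5hmC) presets follow the enhancer-state averages
measured by 6B-C&T in mouse embryonic stem cells: primed enhancers carry the
highest levels of both marks (~13% 5mC, ~4% 5hmC), active ~4%/~2% and poised
~2%/~2%, on a heavily methylated genomic background.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dna import (
    STATE_5HMC,
    STATE_5MC,
    STATE_C,
    STATE_NONE,
    STATE_NAMES,
    cpg_positions_plus,
    seq_to_array,
)
from .errors import InvalidParameterError

MARK_LABELS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "none")
ENHANCER_CLASSES = ("active", "poised", "primed")

#: class -> (p_5mC, p_5hmC) presets; enhancer values follow the measured
#: per-class averages, the background follows bulk mESC CpG methylation.
DEFAULT_PRESETS: dict[str, tuple[float, float]] = {
    "primed": (0.13, 0.04),
    "active": (0.04, 0.02),
    "poised": (0.02, 0.02),
    # histone-mark regions outside annotated enhancers: active marks are
    # strongly hypomethylated relative to bulk, the repressive mark less so
    "H3K4me1": (0.05, 0.02),
    "H3K27ac": (0.04, 0.02),
    "H3K4me3": (0.02, 0.01),
    "H3K27me3": (0.25, 0.02),
    "background": (0.70, 0.03),
}


@dataclass(frozen=True)
class Genome:
    """An ordered mapping of chromosome name to uppercase ACGT sequence."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise InvalidParameterError("genome needs at least one chromosome")
        for name, seq in self.records.items():
            if not seq:
                raise InvalidParameterError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise InvalidParameterError(
                    f"chromosome {name!r} contains non-ACGT characters"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records.items()}

    def cpg_sites(self, chrom: str) -> dict[str, np.ndarray]:
        """Top-strand coordinates of CpG cytosines on each strand."""
        plus = cpg_positions_plus(self.records[chrom])
        return {"+": plus, "-": plus + 1}


@dataclass(frozen=True)
class FeatureAnnotation:
    """Histone-mark intervals plus per-mark fragment-sampling fold enrichment."""

    intervals: list[tuple[str, int, int, str]]
    enrichment: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        by_mark: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for chrom, start, end, mark in self.intervals:
            if not 0 <= start < end:
                raise InvalidParameterError(f"bad interval {(chrom, start, end)}")
            if mark not in MARK_LABELS:
                raise InvalidParameterError(f"unknown mark label {mark!r}")
            by_mark.setdefault((chrom, mark), []).append((start, end))
        for key, ivs in by_mark.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise InvalidParameterError(
                        f"overlapping {key[1]} intervals on {key[0]}"
                    )
        for mark, fold in self.enrichment.items():
            if fold <= 0:
                raise InvalidParameterError(f"enrichment for {mark} must be > 0")

    def intervals_for(self, mark: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, m in self.intervals if m == mark]


@dataclass(frozen=True)
class EnhancerSet:
    """Non-overlapping enhancer intervals labelled active / poised / primed."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, label in self.intervals:
            if label not in ENHANCER_CLASSES:
                raise InvalidParameterError(f"unknown enhancer class {label!r}")
            if not 0 <= start < end:
                raise InvalidParameterError(f"bad interval {(chrom, start, end)}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise InvalidParameterError(f"overlapping enhancers on {chrom}")


@dataclass
class MethylLandscape:
    """Ground-truth modification state of every cytosine on both strands.

    ``plus[chrom][i]`` / ``minus[chrom][i]`` hold an integer state code
    (STATE_C / STATE_5MC / STATE_5HMC) at top-strand coordinate ``i`` when that
    strand carries a cytosine there, and STATE_NONE otherwise.  Both strands of
    a CpG are drawn independently; each sequenced molecule reports one strand.
    """

    plus: dict[str, np.ndarray]
    minus: dict[str, np.ndarray]
    class_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def state(self, chrom: str, pos: int, strand: str) -> int:
        arr = self.plus if strand == "+" else self.minus
        return int(arr[chrom][pos])

    def states_for_molecule(
        self, chrom: str, start: int, end: int, strand: str
    ) -> np.ndarray:
        """States along the original (sequenced) strand, 5'->3'."""
        if strand == "+":
            return self.plus[chrom][start:end].copy()
        return self.minus[chrom][start:end][::-1].copy()


@dataclass(frozen=True)
class SpikeInControl:
    name: str          # FASTA record name
    sequence: str
    plus: np.ndarray   # state codes as in MethylLandscape
    minus: np.ndarray


@dataclass(frozen=True)
class SpikeInSet:
    """The three fiducial controls with exhaustive per-cytosine truth tables."""

    controls: dict[str, SpikeInControl]

    LABELS = ("C-control", "5mC-control", "5hmC-control")
    _ROW_STATE = {"C-control": STATE_C, "5mC-control": STATE_5MC,
                  "5hmC-control": STATE_5HMC}

    def __post_init__(self) -> None:
        if set(self.controls) != set(self.LABELS):
            raise InvalidParameterError(
                f"spike-in labels must be exactly {self.LABELS}"
            )

    def genome(self) -> Genome:
        return Genome({c.name: c.sequence for c in self.controls.values()})

    def landscape(self) -> MethylLandscape:
        return MethylLandscape(
            plus={c.name: c.plus.copy() for c in self.controls.values()},
            minus={c.name: c.minus.copy() for c in self.controls.values()},
        )

    def truth_cpg_sites(self, label: str) -> set[tuple[str, int, str]]:
        """Control CpG cytosines whose truth state matches the control's row."""
        ctrl = self.controls[label]
        want = self._ROW_STATE[label]
        sites: set[tuple[str, int, str]] = set()
        plus_cpg = cpg_positions_plus(ctrl.sequence)
        for pos in plus_cpg:
            if ctrl.plus[pos] == want:
                sites.add((ctrl.name, int(pos), "+"))
        for pos in plus_cpg + 1:
            if ctrl.minus[pos] == want:
                sites.add((ctrl.name, int(pos), "-"))
        return sites


# ---------------------------------------------------------------------------
# generators


def make_genome(
    seed: int,
    chromosome_lengths: Sequence[int],
    gc_fraction: float = 0.42,
    cpg_enrichment: float = 1.0,
) -> Genome:
    """Generate a random genome with i.i.d. bases plus a CpG planting pass.

    ``cpg_enrichment`` scales the expected CpG dinucleotide frequency relative
    to the i.i.d. expectation ``(gc/2)**2``; the i.i.d. GC fraction is adjusted
    so the realised overall GC stays close to ``gc_fraction``.
    """
    if not chromosome_lengths or any(l < 200 for l in chromosome_lengths):
        raise InvalidParameterError("chromosome lengths must all be >= 200")
    if not 0.0 < gc_fraction < 1.0:
        raise InvalidParameterError("gc_fraction must lie strictly in (0, 1)")
    if cpg_enrichment <= 0:
        raise InvalidParameterError("cpg_enrichment must be positive")

    rng = np.random.default_rng(seed)
    base_freq = (gc_fraction / 2.0) ** 2  # i.i.d. CpG frequency
    records: dict[str, str] = {}
    alphabet = np.array(list("ACGT"))
    for idx, length in enumerate(chromosome_lengths, start=1):
        plant_frac = 2.0 * max(cpg_enrichment - 1.0, 0.0) * base_freq
        gc_bg = (gc_fraction - plant_frac) / (1.0 - plant_frac)
        if not 0.0 < gc_bg < 1.0:
            raise InvalidParameterError(
                "cpg_enrichment too high for the requested gc_fraction"
            )
        probs = [(1 - gc_bg) / 2, gc_bg / 2, gc_bg / 2, (1 - gc_bg) / 2]
        arr = rng.choice(alphabet, size=length, p=probs)
        if cpg_enrichment > 1.0:
            n_plant = int(round((cpg_enrichment - 1.0) * base_freq * (length - 1)))
            if n_plant:
                pos = rng.choice(length - 1, size=min(n_plant, length - 1),
                                 replace=False)
                arr[pos] = "C"
                arr[pos + 1] = "G"
        elif cpg_enrichment < 1.0:
            # disrupt a fraction of existing CpGs to thin them out
            cg = np.nonzero((arr[:-1] == "C") & (arr[1:] == "G"))[0]
            n_kill = int(round((1.0 - cpg_enrichment) * len(cg)))
            if n_kill:
                kill = rng.choice(cg, size=n_kill, replace=False)
                arr[kill + 1] = "A"
        records[f"chr{idx}"] = "".join(arr.tolist())
    return Genome(records)


def _class_map(
    length: int,
    chrom: str,
    annotation: FeatureAnnotation | None,
    enhancers: EnhancerSet | None,
) -> tuple[np.ndarray, list[str]]:
    """Per-position annotation class; enhancer classes override mark labels."""
    classes = np.zeros(length, dtype=np.int16)  # 0 == background
    names = ["background"]
    if annotation is not None:
        for c, s, e, mark in annotation.intervals:
            if c != chrom or mark == "none":
                continue
            if mark not in names:
                names.append(mark)
            classes[s:min(e, length)] = names.index(mark)
    if enhancers is not None:
        for c, s, e, label in enhancers.intervals:
            if c != chrom:
                continue
            if label not in names:
                names.append(label)
            classes[s:min(e, length)] = names.index(label)
    return classes, names


def assign_methylation(
    genome: Genome,
    annotation: FeatureAnnotation | None,
    enhancers: EnhancerSet | None,
    presets: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    p_noncpg_5mc: float = 0.002,
    p_noncpg_5hmc: float = 0.0,
) -> MethylLandscape:
    """Draw a per-cytosine modification state for every position of the genome.

    Each CpG cytosine is Bernoulli-modified with its annotation class's
    (p_5mC, p_5hmC); non-CpG cytosines use a small background rate that feeds
    the ambiguous-modC channel downstream.  Both strands are independent.
    """
    presets = dict(DEFAULT_PRESETS if presets is None else presets)
    if "background" not in presets:
        raise InvalidParameterError("presets must include a 'background' class")
    for cls, (pm, ph) in presets.items():
        if pm < 0 or ph < 0 or pm + ph > 1.0:
            raise InvalidParameterError(
                f"preset for {cls!r} must satisfy p_5mC + p_5hmC <= 1"
            )
    if p_noncpg_5mc + p_noncpg_5hmc > 1.0:
        raise InvalidParameterError("non-CpG rates must sum to <= 1")

    needed = {"background"}
    if annotation is not None:
        needed |= {m for *_, m in annotation.intervals if m != "none"}
    if enhancers is not None:
        needed |= {lab for *_, lab in enhancers.intervals}
    missing = needed - set(presets)
    if missing:
        raise InvalidParameterError(f"presets missing classes: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    plus: dict[str, np.ndarray] = {}
    minus: dict[str, np.ndarray] = {}
    for chrom, seq in genome.records.items():
        L = len(seq)
        arr = seq_to_array(seq)
        classes, names = _class_map(L, chrom, annotation, enhancers)
        pm_by_class = np.array([presets[n][0] for n in names])
        ph_by_class = np.array([presets[n][1] for n in names])

        for strand, out in (("+", plus), ("-", minus)):
            states = np.full(L, STATE_NONE, dtype=np.int8)
            is_c = arr == ("C" if strand == "+" else "G")
            states[is_c] = STATE_C
            if strand == "+":
                cpg = np.zeros(L, dtype=bool)
                cpg[:-1] = (arr[:-1] == "C") & (arr[1:] == "G")
            else:
                cpg = np.zeros(L, dtype=bool)
                cpg[1:] = (arr[:-1] == "C") & (arr[1:] == "G")
            u = rng.random(L)
            pm = np.where(cpg, pm_by_class[classes], p_noncpg_5mc)
            ph = np.where(cpg, ph_by_class[classes], p_noncpg_5hmc)
            states[is_c & (u < pm)] = STATE_5MC
            states[is_c & (u >= pm) & (u < pm + ph)] = STATE_5HMC
            out[chrom] = states
    return MethylLandscape(plus=plus, minus=minus, class_means=dict(presets))


# three fixed CpG offsets of the 80-nt oligo carry 5hmC; the rest stay C
_OLIGO_CPG_OFFSETS = (10, 22, 34, 46, 58, 70)
_OLIGO_HMC_OFFSETS = (10, 34, 58, 70)


def make_spikeins(
    seed: int = 0,
    c_control_length: int = 2000,
    mc_control_length: int = 3000,
) -> SpikeInSet:
    """Build the three fiducial controls with exhaustive truth tables.

    * ``C-control``: plasmid-like unmodified sequence (every C state C).
    * ``5mC-control``: phage-like sequence with every CpG cytosine (both
      strands) 5mC and every non-CpG cytosine unmodified.
    * ``5hmC-control``: an 80-nt oligo with six CpGs, hydroxymethylated at four
      designated positions (both strands) and unmodified at the others.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))

    def random_seq(length: int) -> str:
        return "".join(rng.choice(alphabet, size=length).tolist())

    def truth(seq: str, cpg_state: int, hmc_sites: set[int] | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
        arr = seq_to_array(seq)
        L = len(seq)
        plus = np.full(L, STATE_NONE, dtype=np.int8)
        minus = np.full(L, STATE_NONE, dtype=np.int8)
        plus[arr == "C"] = STATE_C
        minus[arr == "G"] = STATE_C
        cpg_plus = cpg_positions_plus(seq)
        for pos in cpg_plus:
            st = cpg_state
            if hmc_sites is not None:
                st = STATE_5HMC if int(pos) in hmc_sites else STATE_C
            plus[pos] = st
            minus[pos + 1] = st
        return plus, minus

    c_seq = random_seq(c_control_length)
    mc_seq = random_seq(mc_control_length)

    # oligo backbone without stray CpGs, then plant the six designed CpGs
    oligo = rng.choice(np.array(list("AT")), size=80).astype("U1")
    fill = rng.choice(alphabet, size=80)
    oligo = np.where(rng.random(80) < 0.5, oligo, fill)
    for off in _OLIGO_CPG_OFFSETS:
        oligo[off] = "C"
        oligo[off + 1] = "G"
    # remove accidental CpGs created by the random backbone
    for i in range(79):
        if oligo[i] == "C" and oligo[i + 1] == "G" and i not in _OLIGO_CPG_OFFSETS:
            oligo[i + 1] = "A"
    oligo_seq = "".join(oligo.tolist())

    c_plus, c_minus = truth(c_seq, STATE_C)
    m_plus, m_minus = truth(mc_seq, STATE_5MC)
    h_plus, h_minus = truth(oligo_seq, STATE_C, set(_OLIGO_HMC_OFFSETS))

    return SpikeInSet(
        {
            "C-control": SpikeInControl("pUC19_unmethylated", c_seq, c_plus, c_minus),
            "5mC-control": SpikeInControl("lambda_methylated", mc_seq, m_plus, m_minus),
            "5hmC-control": SpikeInControl("hmC_oligo", oligo_seq, h_plus, h_minus),
        }
    )


# ---------------------------------------------------------------------------
# merging and file output


def merge_reference(
    genome: Genome,
    landscape: MethylLandscape,
    spikeins: SpikeInSet | None,
) -> tuple[Genome, MethylLandscape]:
    """Append spike-in records to a genome/landscape pair (as extra records)."""
    if spikeins is None:
        return genome, landscape
    records = dict(genome.records)
    plus = {k: v.copy() for k, v in landscape.plus.items()}
    minus = {k: v.copy() for k, v in landscape.minus.items()}
    for ctrl in spikeins.controls.values():
        records[ctrl.name] = ctrl.sequence
        plus[ctrl.name] = ctrl.plus.copy()
        minus[ctrl.name] = ctrl.minus.copy()
    return Genome(records), MethylLandscape(plus, minus, landscape.class_means)


def write_fasta(path, genome: Genome) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="")
            for name, seq in genome.records.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_bed(path, intervals: Iterable[tuple]) -> None:
    """Write (chrom, start, end[, label]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_truth_tsv(path, genome: Genome, landscape: MethylLandscape) -> None:
    """chrom, 0-based position, strand, context (CpG/CpH), state for every C."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tstate\n")
        for chrom, seq in genome.records.items():
            sites = {"+": set(cpg_positions_plus(seq).tolist()),
                     "-": set((cpg_positions_plus(seq) + 1).tolist())}
            for strand, arr in (("+", landscape.plus[chrom]),
                                ("-", landscape.minus[chrom])):
                for pos in np.nonzero(arr != STATE_NONE)[0]:
                    ctx = "CpG" if int(pos) in sites[strand] else "CpH"
                    fh.write(
                        f"{chrom}\t{pos}\t{strand}\t{ctx}\t"
                        f"{STATE_NAMES[int(arr[pos])]}\n"
                    )
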