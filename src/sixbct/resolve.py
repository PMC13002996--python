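"""Resolution of trimmed pairs into single-end 6-letter reads.

Each trimmed pair carries the converted original strand (mate1) and the
converted copy strand (mate2).  Reverse-complementing mate2 puts it in the
original-strand frame, so column i of both strings reports the same duplex
position.  The decode table below follows from the conversion chemistry:

* an unmodified original C is deaminated while its copy partner G is
  untouched, giving the column (T, C) -> genetic C, unmodified;
* a modified original C is protected, giving (C, C); the copy-strand CpG
  channel in the next column distinguishes 5mC (MT methylated and protected
  the copy CpG cytosine -> (G, G)) from 5hmC (glucosylation blocked MT, the
  copy cytosine deaminated -> (G, A));
* a modified C without a 3' G on the original strand (CpH context, or the
  read's last column) cannot be subtyped -> ambiguous modC;
* A/T/G columns pass through as (A, A), (T, T), (G, G)/(G, A);
* every other combination is inconsistent -> genetic N.

Reads whose N-column fraction exceeds a threshold are discarded.  Placement
is by unique exact match of the genetic sequence on the reference (forward or
reverse-complement); multi-mapping or zero-hit reads stay unplaced, mirroring
a multimapper/secondary-alignment filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dna import revcomp, seq_to_array
from .readproc import RETAINED, TrimmedPair
from .reference import Genome

logger = logging.getLogger(__name__)

#: resolved modification-state symbols, aligned to the genetic sequence
STATE_UNMOD = "U"      # unmodified C
STATE_MC = "M"         # 5mC
STATE_HMC = "H"        # 5hmC
STATE_AMBIG = "X"      # modified C that cannot be subtyped
NO_STATE = "."


@dataclass
class ResolvedRead:
    read_id: str
    genetic: str            # over {A, C, G, T, N}
    states: str             # over {., U, M, H, X}, aligned to genetic
    chrom: str | None = None
    start: int | None = None
    strand: str | None = None

    @property
    def placed(self) -> bool:
        return self.chrom is not None

    def __len__(self) -> int:
        return len(self.genetic)


def resolve_pair(
    pair: TrimmedPair,
    max_n_fraction: float = 0.1,
    length_tolerance: int = 3,
) -> ResolvedRead | None:
    """Decode one trimmed pair; returns None when the pair is rejected.

    Mates whose lengths differ by more than ``length_tolerance`` are rejected;
    smaller differences are reconciled by truncating both to the shorter
    length.  A decoded read with more than ``max_n_fraction`` inconsistent
    (N) columns is discarded.
    """
    if pair.status != RETAINED:
        return None
    m1, m2 = pair.mate1, pair.mate2
    if abs(len(m1) - len(m2)) > length_tolerance:
        logger.debug("pair %s rejected: irreconcilable lengths %d/%d",
                     pair.pair_id, len(m1), len(m2))
        return None
    L = min(len(m1), len(m2))
    if L == 0:
        return None
    # mate2 reads the insert from the far end: when one mate is short a few
    # 3' bases the shared columns are mate1's last L against rc(mate2)'s
    # first L (mate1 longer), or mate1 against the head of rc(mate2)
    o = seq_to_array(m1[len(m1) - L:] if len(m1) > L else m1)
    k = seq_to_array(revcomp(m2)[:L])

    genetic = np.full(L, "N", dtype="U1")
    states = np.full(L, NO_STATE, dtype="U1")

    tt = (o == "T") & (k == "T")
    genetic[tt] = "T"
    aa = (o == "A") & (k == "A")
    genetic[aa] = "A"
    gg = (o == "G") & ((k == "G") | (k == "A"))
    genetic[gg] = "G"
    tc = (o == "T") & (k == "C")
    genetic[tc] = "C"
    states[tc] = STATE_UNMOD
    cc = (o == "C") & (k == "C")
    genetic[cc] = "C"
    for i in np.nonzero(cc)[0]:
        if i + 1 < L and o[i + 1] == "G":
            if k[i + 1] == "G":
                states[i] = STATE_MC
            elif k[i + 1] == "A":
                states[i] = STATE_HMC
            else:
                states[i] = STATE_AMBIG
        else:
            states[i] = STATE_AMBIG

    n_frac = float(np.mean(genetic == "N"))
    if n_frac > max_n_fraction:
        logger.debug("pair %s discarded: N fraction %.3f", pair.pair_id, n_frac)
        return None
    return ResolvedRead(pair.pair_id, "".join(genetic.tolist()),
                        "".join(states.tolist()))


def resolve_pairs(pairs: Iterable[TrimmedPair], **kwargs) -> list[ResolvedRead]:
    out = []
    for p in pairs:
        r = resolve_pair(p, **kwargs)
        if r is not None:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# placement


def _find_all(haystack: str, needle: str, limit: int) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i >= 0 and len(hits) < limit:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def place_read(read: ResolvedRead, genome: Genome) -> ResolvedRead:
    """Place by unique exact match (either orientation); ambiguous -> unplaced.

    ``start`` is the top-strand coordinate of the leftmost matched base; for a
    reverse-strand placement the read's position j maps to top coordinate
    ``start + len - 1 - j``.
    """
    seq = read.genetic
    if len(seq) < 20 or "N" in seq:
        return read
    rc = revcomp(seq)
    hits: list[tuple[str, int, str]] = []
    for chrom, ref in genome.records.items():
        for s in _find_all(ref, seq, 2 - len(hits)):
            hits.append((chrom, s, "+"))
            if len(hits) > 1:
                return read
        for s in _find_all(ref, rc, 2 - len(hits)):
            hits.append((chrom, s, "-"))
            if len(hits) > 1:
                return read
    if len(hits) == 1:
        read.chrom, read.start, read.strand = hits[0]
    return read


def place_reads(reads: Iterable[ResolvedRead], genome: Genome
                ) -> list[ResolvedRead]:
    return [place_read(r, genome) for r in reads]


# ---------------------------------------------------------------------------
# external alignments


def import_alignments(sam_path, reads: Sequence[ResolvedRead]
                      ) -> list[ResolvedRead]:
    """Attach placements from a SAM file of externally aligned genetic reads.

    Only primary alignments are used; secondary and supplementary records are
    filtered out.  State strings are carried through unchanged.  Records whose
    identifier has no matching resolved read raise a warning and are skipped.
    """
    import pysam

    by_id = {r.read_id: r for r in reads}
    placed: list[ResolvedRead] = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            read = by_id.get(rec.query_name)
            if read is None:
                warnings.warn(f"SAM record {rec.query_name!r} has no resolved "
                              "read; skipped")
                continue
            read.chrom = rec.reference_name
            read.start = rec.reference_start
            read.strand = "-" if rec.is_reverse else "+"
            placed.append(read)
    return placed


# ---------------------------------------------------------------------------
# output


def write_resolved_tsv(reads: Sequence[ResolvedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tstrand\tgenetic\tstates\n")
        for r in reads:
            fh.write(f"{r.read_id}\t{r.chrom or '.'}\t"
                     f"{-1 if r.start is None else r.start}\t{r.strand or '.'}\t"
                     f"{r.genetic}\t{r.states}\n")


def write_resolved_fasta(reads: Sequence[ResolvedRead], path) -> None:
    """Genetic sequences only, for external alignment."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.genetic}\n")
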