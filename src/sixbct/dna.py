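"""Small DNA string utilities used throughout the package.

Coordinates are 0-based, half-open, on the top (reference) strand everywhere.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer codes for per-cytosine modification states
STATE_NONE = -1   # position is not a cytosine on that strand
STATE_C = 0       # unmodified cytosine
STATE_5MC = 1     # 5-methylcytosine
STATE_5HMC = 2    # 5-hydroxymethylcytosine

STATE_NAMES = {STATE_C: "C", STATE_5MC: "5mC", STATE_5HMC: "5hmC"}


def complement(seq: str) -> str:
    """Element-wise Watson-Crick complement (no reversal)."""
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_array(seq: str) -> np.ndarray:
    """Return a 1-char unicode numpy view of ``seq`` for vectorised ops."""
    return np.frombuffer(seq.encode("ascii"), dtype="S1").astype("U1")


def array_to_seq(arr: np.ndarray) -> str:
    return "".join(arr.tolist())


def cpg_positions_plus(seq: str) -> np.ndarray:
    """Top-strand cytosine positions in CpG context (i where seq[i:i+2] == CG)."""
    arr = seq_to_array(seq)
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    hits = (arr[:-1] == "C") & (arr[1:] == "G")
    return np.nonzero(hits)[0]


def cpg_positions_minus(seq: str) -> np.ndarray:
    """Bottom-strand CpG cytosines, reported as top-strand coordinates.

    The bottom-strand cytosine of a CpG sits opposite the G, i.e. at top
    coordinate ``i + 1`` for every top-strand CG at ``(i, i + 1)``.
    """
    return cpg_positions_plus(seq) + 1
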