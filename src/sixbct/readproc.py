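"""Scar validation, adaptor and gap trimming of 6-base read pairs.

USER digestion of the uracil-containing hairpin mosaic-end adaptor leaves
diagnostic "scar" prefixes on both mates of a bona fide double-hairpin
fragment: AAGAGATAG (R1) / AAAAAACAA (R2) for the ME2U dialect, and
8 arbitrary bases followed by AGATGTGTATAAGAGATAG (R1) /
AAATATATATAAAAAACAA (R2) for the single-uracil ME1U dialect used by
whole-genome 6-base-seq.  Pairs lacking either scar are discarded.  After the
5' scar trim, the 3' adaptor (deaminated mosaic-end hairpin sequence) is cut
at its first seeded occurrence, and a further 9 bases are removed from each
3' end to drop the Tn5 target-site-duplication gap fill.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .errors import InvalidInputError

if TYPE_CHECKING:  # pragma: no cover
    from .chemistry import ReadPair

#: deaminated 19-nt Tn5 mosaic-end sequence, the head of the 3' hairpin adaptor
DEAMINATED_ME = "AGATGTGTATAAGAGATAG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ScarDialect:
    """Scar/adaptor geometry of one hairpin adaptor chemistry."""

    name: str
    r1_prefix: str          # 'N' positions match any base
    r2_prefix: str
    adaptor3p: str = DEAMINATED_ME
    gap_trim: int = 9

    def __post_init__(self) -> None:
        if not self.r1_prefix or not self.r2_prefix:
            raise InvalidInputError("scar prefixes must be non-empty")
        if self.gap_trim < 0:
            raise InvalidInputError("gap_trim must be >= 0")

    def _instantiate(self, prefix: str, rng: np.random.Generator) -> str:
        if "N" not in prefix:
            return prefix
        chars = [str(_BASES[rng.integers(0, 4)]) if c == "N" else c
                 for c in prefix]
        return "".join(chars)

    def instantiate_r1(self, rng: np.random.Generator) -> str:
        return self._instantiate(self.r1_prefix, rng)

    def instantiate_r2(self, rng: np.random.Generator) -> str:
        return self._instantiate(self.r2_prefix, rng)


ME2U = ScarDialect("ME2U", "AAGAGATAG", "AAAAAACAA")
ME1U = ScarDialect(
    "ME1U",
    "NNNNNNNN" + DEAMINATED_ME,
    "NNNNNNNN" + "AAATATATATAAAAAACAA",
)

_DIALECTS = {"me2u": ME2U, "me1u": ME1U}


def get_dialect(name: str) -> ScarDialect:
    try:
        return _DIALECTS[name.lower()]
    except KeyError:
        raise InvalidInputError(f"unknown dialect {name!r}") from None


RETAINED = "retained"
NO_SCAR = "discarded-no-scar"
TOO_SHORT = "discarded-too-short"


@dataclass
class TrimmedPair:
    pair_id: str
    status: str
    mate1: str = ""
    mate2: str = ""
    trim5: int = 0          # 5' scar bases removed from each mate
    trim3_1: int = 0        # 3' bases removed from mate1 (adaptor + gap)
    trim3_2: int = 0


def _prefix_matches(read: str, prefix: str, max_mismatch: int) -> bool:
    if len(read) < len(prefix):
        return False
    mism = sum(
        1 for a, b in zip(read, prefix) if b != "N" and a != b
    )
    return mism <= max_mismatch


def validate_and_trim(
    pair: "ReadPair",
    dialect: ScarDialect,
    max_mismatch: int = 0,
    min_length: int = 20,
    adaptor_seed_len: int = 12,
) -> TrimmedPair:
    """Validate the scar pair, then trim scar, 3' adaptor and gap duplication.

    Both 5' prefixes must match their scar within ``max_mismatch`` mismatches
    (wildcard N positions always match) or the pair is discarded.  On
    retention the scar is removed, the 3' adaptor is cut at the first exact
    occurrence of its ``adaptor_seed_len``-base seed, and ``gap_trim`` further
    bases are removed from each 3' end.
    """
    if not pair.mate1 or not pair.mate2:
        raise InvalidInputError("mates must be non-empty")
    ok1 = _prefix_matches(pair.mate1, dialect.r1_prefix, max_mismatch)
    ok2 = _prefix_matches(pair.mate2, dialect.r2_prefix, max_mismatch)
    if not (ok1 and ok2):
        return TrimmedPair(pair.pair_id, NO_SCAR)

    seed = dialect.adaptor3p[:adaptor_seed_len]
    out = []
    trims3 = []
    for mate, prefix in ((pair.mate1, dialect.r1_prefix),
                         (pair.mate2, dialect.r2_prefix)):
        body = mate[len(prefix):]
        n0 = len(body)
        idx = body.find(seed)
        if idx >= 0:
            body = body[:idx]
        if dialect.gap_trim:
            body = body[:max(0, len(body) - dialect.gap_trim)]
        out.append(body)
        trims3.append(n0 - len(body))

    if min(len(out[0]), len(out[1])) < min_length:
        return TrimmedPair(pair.pair_id, TOO_SHORT)
    return TrimmedPair(
        pair.pair_id, RETAINED, mate1=out[0], mate2=out[1],
        trim5=len(dialect.r1_prefix), trim3_1=trims3[0], trim3_2=trims3[1],
    )


def has_both_scars(pair: "ReadPair", dialect: ScarDialect,
                   max_mismatch: int = 0) -> bool:
    return (_prefix_matches(pair.mate1, dialect.r1_prefix, max_mismatch)
            and _prefix_matches(pair.mate2, dialect.r2_prefix, max_mismatch))


def scarred_fraction(pairs: Sequence["ReadPair"], dialect: ScarDialect,
                     max_mismatch: int = 0) -> float:
    """Fraction of pairs carrying both scars (pre-trim test only)."""
    if len(pairs) == 0:
        raise InvalidInputError("scarred_fraction of an empty collection")
    n = sum(1 for p in pairs if has_both_scars(p, dialect, max_mismatch))
    return n / len(pairs)


def trim_pairs(
    pairs: Iterable["ReadPair"],
    dialect: ScarDialect,
    max_mismatch: int = 0,
    min_length: int = 20,
) -> tuple[list[TrimmedPair], dict[str, int]]:
    """Trim a collection; returns (retained pairs, per-status counts)."""
    counts = {RETAINED: 0, NO_SCAR: 0, TOO_SHORT: 0}
    retained = []
    for p in pairs:
        tp = validate_and_trim(p, dialect, max_mismatch, min_length)
        counts[tp.status] += 1
        if tp.status == RETAINED:
            retained.append(tp)
    return retained, counts


def write_retention_report(counts: dict[str, int], path) -> None:
    total = sum(counts.values())
    with open(path, "w") as fh:
        fh.write("status\tcount\tfraction\n")
        for status, n in counts.items():
            frac = n / total if total else 0.0
            fh.write(f"{status}\t{n}\t{frac:.4f}\n")
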