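"""Per-CpG call accumulation, coverage filtering, fractions and track export.

Calls from placed resolved reads are tallied per reference CpG cytosine
(top- and bottom-strand sites are kept separate; each sequenced molecule
reports one strand).  Per-site 5mC/5hmC percentages use the subtype
denominator n_U + n_M + n_H — ambiguous modC calls are excluded from the
subtype fractions but reported, and count towards total modification
(%modC).  Global values are unweighted means over retained sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidParameterError
from .resolve import ResolvedRead
from .reference import Genome

logger = logging.getLogger(__name__)

COUNT_COLS = ["n_U", "n_M", "n_H", "n_X"]
_STATE_COL = {"U": "n_U", "M": "n_M", "H": "n_H", "X": "n_X"}


@dataclass
class MethylTable:
    """Per-CpG call counts with sample metadata.

    ``df`` is indexed by (chrom, pos, strand) with integer columns
    n_U, n_M, n_H, n_X; ``coverage`` is their sum.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    noncpg_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            raise InvalidInputError("duplicate site keys in MethylTable")

    @property
    def coverage(self) -> pd.Series:
        return self.df[COUNT_COLS].sum(axis=1)

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @staticmethod
    def empty(metadata: dict | None = None) -> "MethylTable":
        idx = pd.MultiIndex.from_arrays([[], [], []],
                                        names=["chrom", "pos", "strand"])
        df = pd.DataFrame(0, index=idx, columns=COUNT_COLS, dtype=np.int64)
        return MethylTable(df, metadata or {})


def accumulate_calls(
    reads: Iterable[ResolvedRead],
    genome: Genome,
    metadata: dict | None = None,
) -> MethylTable:
    """Tally U/M/H/X calls of placed reads onto reference CpG sites.

    Each read contributes at most one call per site (one column per site per
    read by construction).  Calls at non-CpG reference cytosines are tallied
    separately for QC only; reads extending outside the reference are skipped
    with a warning.
    """
    cpg_sets: dict[str, dict[str, set[int]]] = {}
    for chrom in genome.records:
        sites = genome.cpg_sites(chrom)
        cpg_sets[chrom] = {"+": set(sites["+"].tolist()),
                           "-": set(sites["-"].tolist())}

    counts: dict[tuple, np.ndarray] = {}
    noncpg = {"U": 0, "M": 0, "H": 0, "X": 0}
    n_skipped = 0
    for read in reads:
        if not read.placed:
            continue
        L = len(read)
        chrom_len = len(genome.records.get(read.chrom, ""))
        if read.chrom not in cpg_sets or read.start + L > chrom_len:
            n_skipped += 1
            logger.warning("read %s placed outside reference bounds; skipped",
                           read.read_id)
            continue
        states = np.frombuffer(read.states.encode("ascii"), dtype="S1")
        for j in np.nonzero(states != b".")[0]:
            sym = read.states[j]
            if sym == "X" and j == L - 1:
                # the subtype channel (next column) is truncated at the read
                # end: no modification information, not a chemistry ambiguity
                continue
            if read.strand == "+":
                coord, sstrand = read.start + int(j), "+"
            else:
                coord, sstrand = read.start + L - 1 - int(j), "-"
            if coord in cpg_sets[read.chrom][sstrand]:
                key = (read.chrom, coord, sstrand)
                if key not in counts:
                    counts[key] = np.zeros(4, dtype=np.int64)
                counts[key]["UMHX".index(sym)] += 1
            else:
                noncpg[sym] += 1

    if counts:
        keys = sorted(counts)
        idx = pd.MultiIndex.from_tuples(keys, names=["chrom", "pos", "strand"])
        data = np.vstack([counts[k] for k in keys])
        df = pd.DataFrame(data, index=idx, columns=COUNT_COLS)
    else:
        df = MethylTable.empty().df
    table = MethylTable(df, metadata or {}, noncpg_counts=noncpg)
    if n_skipped:
        table.metadata["n_reads_skipped"] = n_skipped
    return table


def filter_coverage(table: MethylTable, min_cov: int) -> MethylTable:
    """Drop sites with coverage below ``min_cov`` (20 analysis / 10 browser)."""
    if min_cov < 0:
        raise InvalidParameterError("min_cov must be >= 0")
    if table.n_sites == 0 or min_cov == 0:
        return MethylTable(table.df.copy(), dict(table.metadata),
                           dict(table.noncpg_counts))
    keep = table.coverage >= min_cov
    return MethylTable(table.df[keep].copy(), dict(table.metadata),
                       dict(table.noncpg_counts))


def site_fractions(table: MethylTable) -> pd.DataFrame:
    """Per-site percentages: %5mC, %5hmC (subtype denominator) and %modC.

    Sites whose subtype denominator is zero (all-X) have undefined subtype
    percentages (NaN) and are excluded from global means.
    """
    df = table.df
    denom = df["n_U"] + df["n_M"] + df["n_H"]
    cov = df[COUNT_COLS].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_m = 100.0 * df["n_M"] / denom.replace(0, np.nan)
        pct_h = 100.0 * df["n_H"] / denom.replace(0, np.nan)
        pct_u = 100.0 * df["n_U"] / denom.replace(0, np.nan)
        pct_mod = 100.0 * (df["n_M"] + df["n_H"] + df["n_X"]) / cov
    out = pd.DataFrame({
        "coverage": cov, "subtype_denom": denom,
        "pct_5mc": pct_m, "pct_5hmc": pct_h, "pct_unmod": pct_u,
        "pct_modc": pct_mod,
    })
    return out


def global_fractions(table: MethylTable) -> dict[str, float]:
    """Unweighted site means of the per-site percentages."""
    fr = site_fractions(table)
    defined = fr["subtype_denom"] > 0
    return {
        "pct_5mc": float(fr.loc[defined, "pct_5mc"].mean()),
        "pct_5hmc": float(fr.loc[defined, "pct_5hmc"].mean()),
        "pct_modc": float(fr["pct_modc"].mean()),
        "n_sites": int(defined.sum()),
    }


def modification_fractions(table: MethylTable
                           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-site table and global unweighted means, as one call."""
    return site_fractions(table), global_fractions(table)


# ---------------------------------------------------------------------------
# region aggregation


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Parse a BED file into (chrom, start, end, label) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError("start >= end")
            except (IndexError, ValueError) as exc:
                raise InvalidInputError(
                    f"{path}: malformed BED line {lineno}: {exc}") from None
            label = parts[3] if len(parts) > 3 else "."
            out.append((chrom, start, end, label))
    return out


def aggregate_regions(
    table: MethylTable,
    regions: Sequence[tuple] | str,
) -> pd.DataFrame:
    """Unweighted mean state fractions over the CpG sites inside each region.

    ``regions`` is a BED path or (chrom, start, end[, label]) tuples.  Regions
    with zero qualifying CpGs are flagged ``empty`` and carry NaN fractions.
    """
    if isinstance(regions, (str, bytes)) or hasattr(regions, "read"):
        regions = read_bed(regions)
    fr = site_fractions(table)
    rows = []
    for region in regions:
        chrom, start, end = region[0], int(region[1]), int(region[2])
        label = region[3] if len(region) > 3 else "."
        if table.n_sites:
            idx = fr.index
            in_region = (
                (idx.get_level_values("chrom") == chrom)
                & (idx.get_level_values("pos") >= start)
                & (idx.get_level_values("pos") < end)
            )
            sub = fr[in_region & (fr["subtype_denom"] > 0)]
        else:
            sub = fr
        rows.append({
            "chrom": chrom, "start": start, "end": end, "label": label,
            "n_cpgs": len(sub),
            "empty": len(sub) == 0,
            "pct_5mc": float(sub["pct_5mc"].mean()) if len(sub) else np.nan,
            "pct_5hmc": float(sub["pct_5hmc"].mean()) if len(sub) else np.nan,
            "pct_modc": float(sub["pct_modc"].mean()) if len(sub) else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# track export


def write_methyl_bedgraph(table: MethylTable, path, state: str = "5mc") -> None:
    """One line per retained CpG: chrom, pos, pos+1, percentage (0-based)."""
    col = {"5mc": "pct_5mc", "5hmc": "pct_5hmc"}.get(state.lower())
    if col is None:
        raise InvalidParameterError(f"unknown state {state!r}")
    fr = site_fractions(table)
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=pct_{state}\n")
        for (chrom, pos, _), row in fr.iterrows():
            if np.isnan(row[col]):
                continue
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{row[col]:g}\n")


def write_coverage_bedgraph(
    reads: Sequence[ResolvedRead],
    genome: Genome,
    path,
    bin_size: int = 10,
) -> None:
    """Fragment-coverage track in fixed bins, counts-per-million normalised.

    A fragment is assigned to the bin containing its leftmost placed base;
    CPM = count / total placed fragments * 1e6.
    """
    if bin_size <= 0:
        raise InvalidParameterError("bin_size must be positive")
    placed = [r for r in reads if r.placed]
    total = len(placed)
    bins: dict[tuple[str, int], int] = {}
    for r in placed:
        key = (r.chrom, (r.start // bin_size) * bin_size)
        bins[key] = bins.get(key, 0) + 1
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=coverage_cpm binSize={bin_size}\n")
        for (chrom, start), n in sorted(bins.items()):
            cpm = n / total * 1e6 if total else 0.0
            end = min(start + bin_size, len(genome.records[chrom]))
            fh.write(f"{chrom}\t{start}\t{end}\t{cpm:g}\n")
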