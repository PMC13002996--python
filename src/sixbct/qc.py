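"""Spike-in call-rate matrix and replicate reproducibility statistics.

The call-rate matrix measures, for each fiducial control, the rate at which
the pipeline calls each modification state when the true state is known: rows
are true states (C / 5mC / 5hmC, one per control), columns are called states
(C / 5mC / 5hmC / ambiguous), and entries are row-normalised percentages over
the bases whose genetic call is C and which align to CpGs of the control
whose truth matches the row.  A fourth ambiguous column keeps rows summing to
100 when subtype resolution fails; a three-column view that drops it and
renormalises is also provided.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .quant import MethylTable, filter_coverage, site_fractions
from .reference import SpikeInSet

ROW_ORDER = ["C", "5mC", "5hmC"]
COL_ORDER = ["C", "5mC", "5hmC", "ambiguous"]
_ROW_OF_CONTROL = {"C-control": "C", "5mC-control": "5mC",
                   "5hmC-control": "5hmC"}
_COL_OF_COUNT = {"n_U": "C", "n_M": "5mC", "n_H": "5hmC", "n_X": "ambiguous"}


def call_rate_matrix(
    table: MethylTable,
    spikeins: SpikeInSet,
    include_ambiguous: bool = True,
) -> pd.DataFrame:
    """Row-normalised called-vs-true percentages over the three controls.

    ``table`` holds the accumulated calls of reads placed on the spike-in
    records (every tallied call has genetic call C by construction of the
    resolver).  Site membership comes from the control truth tables, not from
    the reads.  A control with zero qualifying calls yields a NaN row.
    """
    mat = pd.DataFrame(0.0, index=ROW_ORDER, columns=COL_ORDER)
    for label, row in _ROW_OF_CONTROL.items():
        sites = spikeins.truth_cpg_sites(label)
        if table.n_sites:
            mask = [key in sites for key in table.df.index]
            sub = table.df[mask]
        else:
            sub = table.df
        totals = sub[list(_COL_OF_COUNT)].sum()
        grand = float(totals.sum())
        if grand == 0:
            mat.loc[row] = np.nan
            continue
        for count_col, call_col in _COL_OF_COUNT.items():
            mat.loc[row, call_col] = 100.0 * float(totals[count_col]) / grand
    if not include_ambiguous:
        return three_column_view(mat)
    return mat


def three_column_view(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop the ambiguous column and renormalise rows to 100."""
    sub = matrix[ROW_ORDER].copy()
    sums = sub.sum(axis=1)
    return sub.div(sums / 100.0, axis=0)


def replicate_correlation(
    table_a: MethylTable,
    table_b: MethylTable,
    min_cov: int = 20,
) -> dict[str, float]:
    """Pearson r of per-site subtype fractions over shared retained sites.

    Sites must pass the coverage filter in both replicates; fewer than 10
    shared sites raises.  A state with zero variance in either replicate has
    an undefined correlation, reported as NaN.
    """
    fa = site_fractions(filter_coverage(table_a, min_cov))
    fb = site_fractions(filter_coverage(table_b, min_cov))
    shared = fa.index.intersection(fb.index)
    if len(shared) < 10:
        raise InsufficientDataError(
            f"only {len(shared)} shared sites at coverage >= {min_cov}"
        )
    out: dict[str, float] = {"n_shared_sites": int(len(shared))}
    for state, col in (("5mc", "pct_5mc"), ("5hmc", "pct_5hmc")):
        x = fa.loc[shared, col].to_numpy()
        y = fb.loc[shared, col].to_numpy()
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 10 or np.std(x) == 0 or np.std(y) == 0:
            out[state] = float("nan")
        else:
            out[state] = float(stats.pearsonr(x, y).statistic)
    return out


def qc_summary(
    scarred_fraction: float | None = None,
    placement_rate: float | None = None,
    global_fractions: Mapping[str, float] | None = None,
    matrix: pd.DataFrame | None = None,
    correlations: Mapping[str, float] | None = None,
) -> dict:
    """Assemble the run-level QC report as a plain dict (JSON/TSV friendly)."""
    report: dict = {}
    if scarred_fraction is not None:
        report["scarred_fraction"] = scarred_fraction
    if placement_rate is not None:
        report["placement_rate"] = placement_rate
    if global_fractions is not None:
        report["global_fractions"] = dict(global_fractions)
    if matrix is not None:
        report["call_rate_matrix"] = {
            row: {col: float(matrix.loc[row, col]) for col in matrix.columns}
            for row in matrix.index
        }
    if correlations is not None:
        report["replicate_correlation"] = dict(correlations)
    return report


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.3f",
                  index_label="true_state")
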