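"""Differential (hydroxy)methylation between two sample groups.

Units are single CpG sites or tiled windows (default 100 bp window / 100 bp
step).  Each unit is tested with a binomial likelihood-ratio test of the
group term (1 degree of freedom, the same null/alternative contrast as a
two-group logistic regression); q-values are Benjamini-Hochberg.  A unit is
flagged differentially (hydroxy)methylated when p < 0.05, |log2FC| >= 0.5
and the absolute percentage difference is >= 15, each threshold configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .quant import COUNT_COLS, MethylTable

LOG2FC_EPS = 1e-3  # guard for zero fractions in the fold change


def tile_counts(table: MethylTable, window: int = 100, step: int = 100
                ) -> pd.DataFrame:
    """Sum U/M/H/X counts over tiling windows (both strands pooled).

    Windows start at multiples of ``step``; a site at position p contributes
    to every window [s, s + window) with s <= p < s + window.  Only windows
    containing at least one site are emitted.
    """
    if not window >= step >= 1:
        raise InvalidParameterError("need window >= step >= 1")
    if table.n_sites == 0:
        idx = pd.MultiIndex.from_arrays([[], []], names=["chrom", "start"])
        return pd.DataFrame(0, index=idx, columns=COUNT_COLS, dtype=np.int64)
    frames = []
    df = table.df.reset_index()
    n_offsets = -(-window // step)  # ceil
    for j in range(n_offsets):
        s = (df["pos"] // step - j) * step
        ok = (s >= 0) & (df["pos"] < s + window)
        sub = df[ok].copy()
        sub["start"] = s[ok]
        frames.append(sub)
    merged = pd.concat(frames)
    out = merged.groupby(["chrom", "start"])[COUNT_COLS].sum()
    return out.sort_index()


def _binom_ll(m: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) = 0 convention."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return m * np.log(p) + (n - m) * np.log1p(-p)


def test_differential(counts_a: tuple, counts_b: tuple) -> float:
    """Two-sided p-value for a difference in modification proportion.

    ``counts_a``/``counts_b`` are (modified, total).  Likelihood-ratio test of
    a binomial model with vs without a group term (1 df).  Zero totals give
    NaN (unit skipped).
    """
    p = test_differential_many(
        np.array([counts_a[0]]), np.array([counts_a[1]]),
        np.array([counts_b[0]]), np.array([counts_b[1]]),
    )
    return float(p[0])


def test_differential_many(
    m_a: np.ndarray, n_a: np.ndarray, m_b: np.ndarray, n_b: np.ndarray
) -> np.ndarray:
    """Vectorised binomial LRT over many units; returns p-values."""
    m_a, n_a = np.asarray(m_a, float), np.asarray(n_a, float)
    m_b, n_b = np.asarray(m_b, float), np.asarray(n_b, float)
    valid = (n_a >= 1) & (n_b >= 1)
    p1 = np.divide(m_a, n_a, out=np.zeros_like(m_a), where=n_a > 0)
    p2 = np.divide(m_b, n_b, out=np.zeros_like(m_b), where=n_b > 0)
    p0 = np.divide(m_a + m_b, n_a + n_b,
                   out=np.zeros_like(m_a), where=(n_a + n_b) > 0)
    stat = 2.0 * (
        _binom_ll(m_a, n_a, p1) + _binom_ll(m_b, n_b, p2)
        - _binom_ll(m_a, n_a, p0) - _binom_ll(m_b, n_b, p0)
    )
    stat = np.maximum(stat, 0.0)
    pvals = stats.chi2.sf(stat, df=1)
    pvals[~valid] = np.nan
    return pvals


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-aware)."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    n = len(ps)
    if n == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q


def compare_groups(
    tables_a: list[MethylTable],
    tables_b: list[MethylTable],
    state: str = "5mc",
    window: int | None = None,
    step: int | None = None,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Site- or window-level differential test between two replicate groups.

    Counts are pooled within each group (summed over replicates); a unit must
    reach ``min_cov`` pooled subtype coverage in both groups.  ``state``
    selects 5mC (DMC calling) or 5hmC (DHMC calling).  When ``window`` is
    given, sites are tiled first.  Returns one row per unit with mu1, mu2,
    diff (percentage points), log2fc, p and BH q.
    """
    mod_col = {"5mc": "n_M", "5hmc": "n_H"}.get(state.lower())
    if mod_col is None:
        raise InvalidParameterError(f"unknown state {state!r}")

    def pooled(tables: list[MethylTable]) -> pd.DataFrame:
        dfs = [t.df for t in tables]
        merged = pd.concat(dfs).groupby(level=[0, 1, 2]).sum()
        pooled_table = MethylTable(merged)
        if window is not None:
            return tile_counts(pooled_table, window, step or window)
        return merged

    a, b = pooled(tables_a), pooled(tables_b)
    shared = a.index.intersection(b.index)
    a, b = a.loc[shared], b.loc[shared]

    tot_a = (a["n_U"] + a["n_M"] + a["n_H"]).to_numpy(float)
    tot_b = (b["n_U"] + b["n_M"] + b["n_H"]).to_numpy(float)
    mod_a = a[mod_col].to_numpy(float)
    mod_b = b[mod_col].to_numpy(float)
    keep = (tot_a >= min_cov) & (tot_b >= min_cov)

    mu1 = np.divide(mod_a, tot_a, out=np.full_like(mod_a, np.nan),
                    where=tot_a > 0)
    mu2 = np.divide(mod_b, tot_b, out=np.full_like(mod_b, np.nan),
                    where=tot_b > 0)
    pvals = test_differential_many(mod_a, tot_a, mod_b, tot_b)
    out = pd.DataFrame({
        "mu1": mu1, "mu2": mu2,
        "diff": 100.0 * (mu1 - mu2),
        "log2fc": np.log2((mu1 + LOG2FC_EPS) / (mu2 + LOG2FC_EPS)),
        "p": pvals,
    }, index=shared)
    out = out[keep]
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out


def call_dmrs(
    results: pd.DataFrame,
    p_max: float = 0.05,
    min_log2fc: float = 0.5,
    min_diff: float = 15.0,
) -> pd.DataFrame:
    """Flag units meeting all three thresholds; direction is recorded.

    Defaults follow the published rule: p < 0.05, |log2FC| >= 0.5 and an
    absolute methylation difference >= 15 percentage points.
    """
    if p_max <= 0 or min_log2fc < 0 or min_diff < 0:
        raise InvalidParameterError("thresholds must be positive")
    if len(results) == 0:
        out = results.copy()
        out["direction"] = pd.Series(dtype=str)
        return out
    flagged = results[
        (results["p"] < p_max)
        & (results["log2fc"].abs() >= min_log2fc)
        & (results["diff"].abs() >= min_diff)
    ].copy()
    flagged["direction"] = np.where(flagged["diff"] > 0, "higher", "lower")
    return flagged


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", float_format="%.6g")


def write_dmr_bed(flagged: pd.DataFrame, path, window: int | None = None
                  ) -> None:
    """Flagged units as BED; site units span one base, windows span window."""
    with open(path, "w") as fh:
        for key, row in flagged.iterrows():
            if len(key) == 3:
                chrom, pos, _strand = key
                start, end = pos, pos + 1
            else:
                chrom, start = key
                end = start + (window or 100)
            fh.write(f"{chrom}\t{start}\t{end}\t{row['direction']}\t"
                     f"{row['p']:.3g}\n")
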